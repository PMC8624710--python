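"""Compound registry and active-moiety dose equivalence.

An ion-pair derivative carries the active moiety plus a counterion; dosing
arithmetic converts between the mass of the salt that is weighed into a
formulation and the mass of active moiety it delivers.

Units: masses in g, molar masses in g/mol.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd

from .errors import DomainError, InvalidCompoundError

__all__ = [
    "Compound",
    "FormulationSpec",
    "CompoundRegistry",
    "active_fraction",
    "equivalent_active_mass",
    "salt_mass_for_dose",
    "default_registry",
    "default_formulations",
]

_REGISTRY_COLUMNS = ["acronym", "name", "M_pair", "M_active", "chain_length", "branched"]


@dataclass(frozen=True)
class Compound:
    """One registry entry: an active moiety, optionally paired with a counterion.

    ``M_pair`` is the molar mass used for dose arithmetic; ``M_pair_display``
    may carry an alternative literature value for display when sources
    disagree in the last digit.  The free acid has ``M_pair == M_active``.
    ``chain_length`` counts carbons in the counterion ester alkyl chain
    (0 for the free acid); ``branched`` flags non-linear chains.
    """

    acronym: str
    name: str
    M_pair: float
    M_active: float
    chain_length: int
    branched: bool = False
    M_pair_display: float | None = None

    def __post_init__(self) -> None:
        if not (self.M_active > 0.0) or not (self.M_pair > 0.0):
            raise InvalidCompoundError(
                f"{self.acronym}: molar masses must be positive "
                f"(M_pair={self.M_pair}, M_active={self.M_active})"
            )
        if self.M_pair < self.M_active:
            raise InvalidCompoundError(
                f"{self.acronym}: M_pair ({self.M_pair}) < M_active ({self.M_active})"
            )
        if self.chain_length < 0:
            raise InvalidCompoundError(f"{self.acronym}: negative chain_length")

    @property
    def is_free_acid(self) -> bool:
        return self.M_pair == self.M_active


@dataclass(frozen=True)
class FormulationSpec:
    """Composition of one cream: vehicle + weighed compound + cosolvent."""

    compound: Compound
    vehicle_mass: float
    compound_mass: float
    cosolvent_mass: float
    total_mass: float
    active_mass_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        parts = self.vehicle_mass + self.compound_mass + self.cosolvent_mass
        if abs(parts - self.total_mass) > 1e-6:
            raise DomainError(
                f"{self.compound.acronym}: component masses sum to {parts:.6f} g, "
                f"total_mass is {self.total_mass:.6f} g"
            )
        frac = equivalent_active_mass(self.compound_mass, self.compound) / self.total_mass
        if not (0.0 < frac < 1.0):
            raise DomainError(
                f"{self.compound.acronym}: active mass fraction {frac} outside (0, 1)"
            )
        object.__setattr__(self, "active_mass_fraction", frac)

    @property
    def active_mass(self) -> float:
        """Mass of active moiety delivered by the weighed compound, g."""
        return equivalent_active_mass(self.compound_mass, self.compound)


class CompoundRegistry:
    """Ordered collection of :class:`Compound` with unique acronyms."""

    def __init__(self, compounds: list[Compound]):
        acronyms = [c.acronym for c in compounds]
        dupes = {a for a in acronyms if acronyms.count(a) > 1}
        if dupes:
            raise InvalidCompoundError(f"duplicate acronyms in registry: {sorted(dupes)}")
        self._by_acronym: dict[str, Compound] = {c.acronym: c for c in compounds}

    def __len__(self) -> int:
        return len(self._by_acronym)

    def __iter__(self) -> Iterator[Compound]:
        return iter(self._by_acronym.values())

    def __contains__(self, acronym: str) -> bool:
        return acronym in self._by_acronym

    def __getitem__(self, acronym: str) -> Compound:
        try:
            return self._by_acronym[acronym]
        except KeyError:
            raise InvalidCompoundError(f"unknown compound acronym: {acronym!r}") from None

    @property
    def acronyms(self) -> list[str]:
        return list(self._by_acronym)

    @property
    def free_acid(self) -> Compound:
        """The control compound (chain length 0)."""
        for c in self:
            if c.chain_length == 0:
                return c
        raise InvalidCompoundError("registry has no free-acid (chain_length 0) entry")

    @classmethod
    def from_csv(cls, source: str | Path | io.TextIOBase) -> "CompoundRegistry":
        df = pd.read_csv(source)
        missing = set(_REGISTRY_COLUMNS) - set(df.columns)
        if missing:
            raise InvalidCompoundError(f"registry file missing columns: {sorted(missing)}")
        compounds = []
        for row in df.itertuples(index=False):
            display = getattr(row, "M_pair_display", None)
            compounds.append(
                Compound(
                    acronym=str(row.acronym),
                    name=str(row.name),
                    M_pair=float(row.M_pair),
                    M_active=float(row.M_active),
                    chain_length=int(row.chain_length),
                    branched=_as_bool(row.branched),
                    M_pair_display=None if display is None or pd.isna(display) else float(display),
                )
            )
        return cls(compounds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "acronym": c.acronym,
                    "name": c.name,
                    "M_pair": c.M_pair,
                    "M_active": c.M_active,
                    "chain_length": c.chain_length,
                    "branched": c.branched,
                    "M_pair_display": c.M_pair_display,
                }
                for c in self
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in {"true", "1", "yes"}


def active_fraction(compound: Compound) -> float:
    """Mass fraction of the active moiety in the (salt) compound.

    Returns M_active / M_pair, in (0, 1]; 1.0 for the free acid.
    """
    return compound.M_active / compound.M_pair


def equivalent_active_mass(salt_mass: float, compound: Compound) -> float:
    """Active-moiety mass (g) delivered by ``salt_mass`` g of the compound."""
    if salt_mass < 0:
        raise DomainError(f"salt_mass must be >= 0, got {salt_mass}")
    return salt_mass * active_fraction(compound)


def salt_mass_for_dose(active_dose: float, compound: Compound) -> float:
    """Compound mass (g) to weigh in for a target active-moiety dose (g).

    Exact inverse of :func:`equivalent_active_mass`.
    """
    if active_dose < 0:
        raise DomainError(f"active_dose must be >= 0, got {active_dose}")
    return active_dose * compound.M_pair / compound.M_active


def default_registry() -> CompoundRegistry:
    """The shipped ten-compound registry (free acid + nine alkyl-ester ion pairs)."""
    with resources.files("ivperm.data").joinpath("registry.csv").open("r") as fh:
        return CompoundRegistry.from_csv(fh)


def default_formulations(registry: CompoundRegistry | None = None) -> list[FormulationSpec]:
    """The shipped cream compositions (one per registry compound, ~50 mg active each)."""
    registry = registry or default_registry()
    with resources.files("ivperm.data").joinpath("formulations.csv").open("r") as fh:
        df = pd.read_csv(fh)
    return [
        FormulationSpec(
            compound=registry[row.compound],
            vehicle_mass=float(row.vehicle_mass_g),
            compound_mass=float(row.compound_mass_g),
            cosolvent_mass=float(row.cosolvent_mass_g),
            total_mass=float(row.total_mass_g),
        )
        for row in df.itertuples(index=False)
    ]
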