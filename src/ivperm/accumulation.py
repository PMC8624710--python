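"""Drug deposition in the membrane from the end-of-study extraction assay."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .compounds import Compound, CompoundRegistry, active_fraction
from .errors import DomainError, SchemaError

__all__ = [
    "AccumulationRecord",
    "membrane_accumulation",
    "express_as_active",
    "process_accumulation_table",
]

_REQUIRED_COLUMNS = [
    "cell_id",
    "compound",
    "membrane",
    "conc_supernatant_ug_per_ml",
    "V_extract_ml",
    "membrane_mass_g",
]


@dataclass(frozen=True)
class AccumulationRecord:
    """One extraction measurement: supernatant assay → µg drug per g membrane."""

    cell_id: str
    compound: str
    membrane: str
    C_supernatant: float  # µg/mL
    V_extract: float  # mL
    m_membrane: float  # g
    accumulation: float  # µg/g


def membrane_accumulation(C_supernatant: float, V_extract: float, m_membrane: float) -> float:
    """Accumulated drug per membrane mass: C·V / m, µg/g."""
    if m_membrane <= 0:
        raise DomainError(f"membrane mass must be positive, got {m_membrane}")
    if C_supernatant < 0 or V_extract < 0:
        raise DomainError("supernatant concentration and extract volume must be >= 0")
    return C_supernatant * V_extract / m_membrane


def express_as_active(accumulation_salt_basis: float, compound: Compound) -> float:
    """Convert a salt-basis accumulation to active-moiety basis (µg active / g)."""
    return accumulation_salt_basis * active_fraction(compound)


def process_accumulation_table(
    df: pd.DataFrame,
    registry: CompoundRegistry | None = None,
    salt_basis: bool = False,
) -> pd.DataFrame:
    """Add an ``accumulation_ug_per_g`` column to an extraction-assay table.

    With ``salt_basis=True`` the assay is assumed to quantify the intact salt
    and results are converted to active-moiety equivalents via the registry;
    the default treats inputs as already active-basis.
    """
    missing = set(_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"accumulation table missing columns: {sorted(missing)}")
    out = df.copy()
    values = []
    for row in out.itertuples(index=False):
        acc = membrane_accumulation(
            float(row.conc_supernatant_ug_per_ml),
            float(row.V_extract_ml),
            float(row.membrane_mass_g),
        )
        if salt_basis:
            if registry is None:
                raise SchemaError("salt_basis=True requires a compound registry")
            acc = express_as_active(acc, registry[row.compound])
        values.append(acc)
    out["accumulation_ug_per_g"] = values
    return out
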