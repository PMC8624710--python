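"""Cumulative-permeation profiles and steady-state kinetics.

Turns raw receptor concentrations into dilution-corrected cumulative
amounts per area, fits the linear (steady-state) regime by ordinary least
squares over an automatically selected window, and aggregates replicate
cells into per-compound summaries and inter-membrane flux ratios.

Units: time h, Q µg/cm², flux µg·cm⁻²·h⁻¹, K_p cm/h.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError, GroupingError, InputError, NoSteadyStateError
from .synthetic import CellConfig, RawSeries

__all__ = [
    "PermeationProfile",
    "SteadyStateFit",
    "CompoundSummary",
    "cumulative_amount",
    "interval_flux",
    "fit_steady_state",
    "permeability_coefficient",
    "aggregate_cells",
    "permeation_ratio",
    "round_half_up",
]

MIN_WINDOW_POINTS = 4


@dataclass(frozen=True)
class PermeationProfile:
    """Cumulative amount permeated per unit area vs time, one cell."""

    cell_id: str
    compound: str
    membrane: str
    times: tuple[float, ...]
    Q: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.Q):
            raise InputError(f"{self.cell_id}: times and Q lengths differ")


@dataclass(frozen=True)
class SteadyStateFit:
    """OLS fit of Q vs t over the steady-state window.

    ``window`` is a half-open (start, stop) index range into the profile;
    ``L_T`` is the x-axis intercept −intercept/J_ss; ``K_p = J_ss / C_donor``.
    """

    cell_id: str
    compound: str
    membrane: str
    J_ss: float
    intercept: float
    L_T: float
    K_p: float
    r2_fit: float
    window: tuple[int, int]


@dataclass(frozen=True)
class CompoundSummary:
    """Replicate-aggregated kinetics for one compound on one membrane.

    SDs use the n−1 denominator and are None for a single cell.
    ``Kp_e3`` entries are K_p scaled by 10³ for reporting.
    """

    compound: str
    membrane: str
    n: int
    J_ss_mean: float
    J_ss_sd: float | None
    Kp_e3_mean: float
    Kp_e3_sd: float | None
    L_T_mean: float
    L_T_sd: float | None
    Q24_mean: float | None = None
    Q24_sd: float | None = None


def cumulative_amount(raw: RawSeries, cell: CellConfig) -> PermeationProfile:
    """Dilution-corrected cumulative amount per area.

    Each withdrawn sample removes drug that must be added back:

        Q_n = ( c_n·V_receptor + V_sample·Σ_{i<n} c_i ) / area
    """
    c = np.asarray(raw.concentrations, dtype=float)
    t = np.asarray(raw.times, dtype=float)
    if len(c) != len(t):
        raise InputError(f"{raw.cell_id}: misaligned times/concentrations")
    if np.any(c < 0):
        raise InputError(f"{raw.cell_id}: negative concentration in input")
    prior = np.concatenate(([0.0], np.cumsum(c)[:-1]))
    Q = (c * cell.V_receptor + cell.V_sample * prior) / cell.area
    return PermeationProfile(
        cell_id=raw.cell_id,
        compound=raw.compound,
        membrane=raw.membrane,
        times=tuple(t),
        Q=tuple(Q),
    )


def interval_flux(profile: PermeationProfile) -> np.ndarray:
    """Per-interval permeation rate, with (t=0, Q=0) prepended.

    rate_n = (Q_n − Q_{n−1}) / (t_n − t_{n−1}), µg·cm⁻²·h⁻¹.
    """
    t = np.concatenate(([0.0], np.asarray(profile.times, dtype=float)))
    Q = np.concatenate(([0.0], np.asarray(profile.Q, dtype=float)))
    if len(t) < 2:
        raise InputError("need at least one timepoint")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise InputError(f"{profile.cell_id}: duplicate or non-increasing times")
    return np.diff(Q) / dt


def _ols_line(t: np.ndarray, q: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and r² of q on t (plain OLS)."""
    res = sps.linregress(t, q)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_steady_state(
    profile: PermeationProfile,
    cell: CellConfig,
    strategy: str = "max-r2",
    min_points: int = MIN_WINDOW_POINTS,
) -> SteadyStateFit:
    """Estimate J_ss, lag time and K_p from the linear regime of the profile.

    ``strategy`` selects the regression window:

    - ``"max-r2"`` (default): exhaustive search over all contiguous windows of
      at least ``min_points`` points with positive slope; picks the window
      maximizing r², breaking exact ties by longer window then earlier start.
    - ``"last4"``: the final ``min_points`` points (no search).

    Raises :class:`NoSteadyStateError` when every candidate slope is ≤ 0.
    A negative lag time is reported as-is, with a warning.
    """
    t = np.asarray(profile.times, dtype=float)
    q = np.asarray(profile.Q, dtype=float)
    n = len(t)
    if n < min_points:
        raise InputError(f"{profile.cell_id}: need >= {min_points} timepoints, got {n}")

    if strategy == "last4":
        candidates = [(n - min_points, n)]
    elif strategy == "max-r2":
        candidates = [
            (i, j)
            for i in range(n - min_points + 1)
            for j in range(i + min_points, n + 1)
        ]
    else:
        raise DomainError(f"unknown window strategy: {strategy!r}")

    best: tuple[int, int] | None = None
    best_fit: tuple[float, float, float] | None = None
    for i, j in candidates:
        slope, intercept, r2 = _ols_line(t[i:j], q[i:j])
        if slope <= 0:
            continue
        if best is None:
            better = True
        else:
            b_r2 = best_fit[2]
            if r2 != b_r2:
                better = r2 > b_r2
            elif (j - i) != (best[1] - best[0]):
                better = (j - i) > (best[1] - best[0])
            else:
                better = i < best[0]
        if better:
            best, best_fit = (i, j), (slope, intercept, r2)

    if best is None:
        raise NoSteadyStateError(
            f"{profile.cell_id}: no candidate window has a positive slope"
        )

    slope, intercept, r2 = best_fit
    lag = -intercept / slope
    if lag < 0:
        warnings.warn(
            f"{profile.cell_id}: negative fitted lag time ({lag:.3g} h)",
            stacklevel=2,
        )
    return SteadyStateFit(
        cell_id=profile.cell_id,
        compound=profile.compound,
        membrane=profile.membrane,
        J_ss=slope,
        intercept=intercept,
        L_T=lag,
        K_p=permeability_coefficient(slope, cell.C_donor),
        r2_fit=r2,
        window=best,
    )


def permeability_coefficient(J_ss: float, C_donor: float) -> float:
    """K_p = J_ss / C_donor, cm/h."""
    if C_donor <= 0:
        raise DomainError(f"C_donor must be positive, got {C_donor}")
    return J_ss / C_donor


def _mean_sd(values: Sequence[float]) -> tuple[float, float | None]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) >= 2 else None
    return mean, sd


def aggregate_cells(
    fits: Sequence[SteadyStateFit],
    profiles: Sequence[PermeationProfile] | None = None,
) -> CompoundSummary:
    """Mean ± SD of J_ss, K_p·10³ and L_T over replicate cells.

    All fits (and profiles, if given) must share one compound and membrane;
    profiles contribute the end-of-study cumulative mass (last timepoint).
    """
    if not fits:
        raise GroupingError("no fits to aggregate")
    compounds = {f.compound for f in fits}
    membranes = {f.membrane for f in fits}
    if profiles:
        compounds |= {p.compound for p in profiles}
        membranes |= {p.membrane for p in profiles}
    if len(compounds) != 1 or len(membranes) != 1:
        raise GroupingError(
            f"mixed groups in aggregate: compounds={sorted(compounds)}, "
            f"membranes={sorted(membranes)}"
        )

    j_mean, j_sd = _mean_sd([f.J_ss for f in fits])
    kp_mean, kp_sd = _mean_sd([f.K_p * 1e3 for f in fits])
    lt_mean, lt_sd = _mean_sd([f.L_T for f in fits])
    q24_mean = q24_sd = None
    if profiles:
        q24_mean, q24_sd = _mean_sd([p.Q[-1] for p in profiles])

    return CompoundSummary(
        compound=compounds.pop(),
        membrane=membranes.pop(),
        n=len(fits),
        J_ss_mean=j_mean,
        J_ss_sd=j_sd,
        Kp_e3_mean=kp_mean,
        Kp_e3_sd=kp_sd,
        L_T_mean=lt_mean,
        L_T_sd=lt_sd,
        Q24_mean=q24_mean,
        Q24_sd=q24_sd,
    )


def permeation_ratio(summary_a: CompoundSummary, summary_b: CompoundSummary) -> float:
    """Ratio of mean steady-state fluxes A/B for the same compound.

    Returned unrounded; reports round to 2 decimals via :func:`round_half_up`.
    """
    if summary_a.compound != summary_b.compound:
        raise GroupingError(
            f"ratio across different compounds: {summary_a.compound} vs {summary_b.compound}"
        )
    if summary_b.J_ss_mean == 0:
        raise DomainError("denominator flux is zero")
    return summary_a.J_ss_mean / summary_b.J_ss_mean


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero, as used in report tables."""
    factor = 10.0**ndigits
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x))


def fits_to_frame(fits: Sequence[SteadyStateFit]) -> pd.DataFrame:
    """Per-cell fit table (one row per diffusion cell)."""
    return pd.DataFrame(
        [
            {
                "cell_id": f.cell_id,
                "compound": f.compound,
                "membrane": f.membrane,
                "Jss": f.J_ss,
                "intercept": f.intercept,
                "LT_h": f.L_T,
                "Kp_cm_per_h": f.K_p,
                "r2_fit": f.r2_fit,
                "window": f"{f.window[0]}:{f.window[1]}",
            }
            for f in fits
        ]
    )
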