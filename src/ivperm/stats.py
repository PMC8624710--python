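"""Comparative statistics: Tukey HSD with compact letters, Pearson
correlation between membranes, and hierarchical clustering of profiles."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import InputError, UndefinedCorrelationError

__all__ = [
    "TukeyResult",
    "CorrelationResult",
    "ClusterResult",
    "pearson_profile_correlation",
    "anova_tukey_cld",
    "compact_letter_display",
    "cluster_penetration_profiles",
]


@dataclass(frozen=True)
class CorrelationResult:
    label: str
    r: float
    r2: float
    n: int
    p_value: float


@dataclass(frozen=True)
class TukeyResult:
    """One-way ANOVA + all-pairs Tukey HSD + compact letter display.

    ``letters`` maps each group to its letter string; groups sharing any
    letter are not significantly different at ``alpha``.  Letters run from
    'a' upward with 'a' attached to the lowest-mean groups.
    """

    groups: tuple[str, ...]  # ordered by ascending mean
    means: Mapping[str, float]
    p_values: Mapping[tuple[str, str], float]
    reject: Mapping[tuple[str, str], bool]
    letters: Mapping[str, str]
    anova_F: float
    anova_p: float
    alpha: float


@dataclass(frozen=True)
class ClusterResult:
    labels: tuple[str, ...]
    linkage: np.ndarray
    assignments: pd.Series  # label -> cluster id 1..k (1 = highest mass)
    k: int


def pearson_profile_correlation(
    profile_a: Sequence[float],
    profile_b: Sequence[float],
    label: str = "pooled",
) -> CorrelationResult:
    """Pearson r between two matched cumulative series (e.g. two membranes)."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("profiles must be 1-D and of equal length")
    if len(a) < 3:
        raise InputError(f"need >= 3 matched points, got {len(a)}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError(f"{label}: zero variance in a series")
    res = sps.pearsonr(a, b)
    r = float(res.statistic)
    return CorrelationResult(label=label, r=r, r2=r * r, n=len(a), p_value=float(res.pvalue))


def _absorb(sets: list[set[str]]) -> list[set[str]]:
    """Drop duplicates and any set contained in another (the absorb step)."""
    unique: list[set[str]] = []
    for s in sets:
        if s and s not in unique:
            unique.append(s)
    return [
        s1
        for i, s1 in enumerate(unique)
        if not any(i != j and s1 < s2 for j, s2 in enumerate(unique))
    ]


def compact_letter_display(
    groups: Sequence[str],
    means: Mapping[str, float],
    reject: Mapping[tuple[str, str], bool],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``reject[(g1, g2)]`` is True when the pair differs significantly.  The
    returned letters satisfy: two groups share a letter iff their pair is not
    rejected.  Letter 'a' goes to the set containing the lowest-mean group.
    """
    order = sorted(groups, key=lambda g: (means[g], g))

    def rejected(g1: str, g2: str) -> bool:
        return reject.get((g1, g2), reject.get((g2, g1), False))

    letter_sets: list[set[str]] = [set(order)]
    for g1, g2 in combinations(order, 2):
        if not rejected(g1, g2):
            continue
        offending = [s for s in letter_sets if g1 in s and g2 in s]
        for s in offending:
            letter_sets.remove(s)
            letter_sets.extend([s - {g1}, s - {g2}])
        letter_sets = _absorb(letter_sets)

    rank = {g: i for i, g in enumerate(order)}
    letter_sets.sort(key=lambda s: (min(rank[g] for g in s), -len(s)))
    letters: dict[str, list[str]] = {g: [] for g in order}
    for i, s in enumerate(letter_sets):
        symbol = chr(ord("a") + i)
        for g in s:
            letters[g].append(symbol)
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def anova_tukey_cld(
    values: Sequence[float],
    groups: Sequence[str],
    alpha: float = 0.05,
) -> TukeyResult:
    """One-way ANOVA F-test plus all-pairs Tukey HSD and compact letters.

    Requires at least two groups, each with at least two observations.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if len(values) != len(groups):
        raise InputError("values and groups must be the same length")
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise InputError("need at least 2 groups")
    by_group = {g: values[groups == g] for g in labels}
    for g, v in by_group.items():
        if len(v) < 2:
            raise InputError(f"group {g!r} has fewer than 2 observations")

    F, p = sps.f_oneway(*(by_group[g] for g in labels))
    tk = pairwise_tukeyhsd(values, groups, alpha=alpha)
    uniq = [str(g) for g in tk.groupsunique]
    p_values: dict[tuple[str, str], float] = {}
    reject: dict[tuple[str, str], bool] = {}
    for (g1, g2), pv, rej in zip(combinations(uniq, 2), tk.pvalues, tk.reject):
        p_values[(g1, g2)] = float(pv)
        reject[(g1, g2)] = bool(rej)

    means = {g: float(by_group[g].mean()) for g in labels}
    letters = compact_letter_display(labels, means, reject)
    ordered = tuple(sorted(labels, key=lambda g: (means[g], g)))
    return TukeyResult(
        groups=ordered,
        means=means,
        p_values=p_values,
        reject=reject,
        letters=letters,
        anova_F=float(F),
        anova_p=float(p),
        alpha=alpha,
    )


def cluster_penetration_profiles(
    features: pd.DataFrame,
    k: int = 3,
    order_by: pd.Series | None = None,
) -> ClusterResult:
    """Ward/Euclidean agglomerative clustering of per-compound profiles.

    ``features``: rows = compounds, columns = concatenated mean cumulative
    series (both membranes).  Columns are standardized to zero mean and unit
    SD; constant columns are dropped with a warning.  The tree is cut at
    ``k`` groups and cluster ids 1..k are ordered by descending cluster mean
    of ``order_by`` (default: each compound's end-of-study cumulative mass,
    taken as the row mean of the raw feature matrix).
    """
    if features.isna().any().any():
        raise InputError("feature matrix contains missing values")
    if not 1 <= k <= len(features):
        raise InputError(f"k must be in [1, {len(features)}], got {k}")

    X = features.astype(float)
    sd = X.std(ddof=0)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(f"dropping constant feature columns: {list(constant)}", stacklevel=2)
        X = X.drop(columns=constant)
        sd = sd.drop(constant)
    if X.shape[1] == 0:
        raise InputError("no non-constant feature columns left")
    Z = (X - X.mean()) / sd[X.columns]

    linkage = hierarchy.linkage(Z.to_numpy(), method="ward")
    raw_ids = hierarchy.fcluster(linkage, t=k, criterion="maxclust")

    mass = order_by if order_by is not None else features.mean(axis=1)
    mass = mass.reindex(features.index)
    cluster_mass = (
        pd.Series(mass.to_numpy(), index=raw_ids).groupby(level=0).mean().sort_values(ascending=False)
    )
    remap = {old: new for new, old in enumerate(cluster_mass.index, start=1)}
    assignments = pd.Series(
        [remap[i] for i in raw_ids], index=features.index, name="cluster"
    )
    return ClusterResult(
        labels=tuple(features.index),
        linkage=linkage,
        assignments=assignments,
        k=k,
    )
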