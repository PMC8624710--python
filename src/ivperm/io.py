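"""File I/O, study configuration, manifests, and the analysis orchestration
that ties the pipeline stages together.

All tables are comma-separated UTF-8 with '.' decimals and mandatory
headers; units are embedded in column names.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accumulation import process_accumulation_table
from .compounds import CompoundRegistry, default_registry
from .errors import InputError, ResolutionError, SchemaError
from .permeation import (
    CompoundSummary,
    aggregate_cells,
    cumulative_amount,
    fit_steady_state,
    fits_to_frame,
    permeation_ratio,
)
from .stats import (
    anova_tukey_cld,
    cluster_penetration_profiles,
    pearson_profile_correlation,
)
from .synthetic import CellConfig, RawSeries, SamplingSchedule, StudyDataset

RAW_COLUMNS = ["cell_id", "compound", "membrane", "time_h", "conc_ug_per_ml"]


@dataclass
class StudyConfig:
    """Everything needed to simulate and analyze one study."""

    registry_path: str | None = None
    cell: CellConfig = field(default_factory=CellConfig)
    schedule: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 8.0, 24.0)
    membranes: tuple[str, ...] = ("skin", "strat-m")
    n_cells: int = 3
    noise_cv: float = 0.05
    window_strategy: str = "max-r2"
    alpha: float = 0.05
    k_clusters: int = 3
    ratio_membranes: tuple[str, str] = ("strat-m", "skin")  # numerator, denominator
    ndigits: int = 2
    seed: int = 0

    def load_registry(self) -> CompoundRegistry:
        if self.registry_path is None:
            return default_registry()
        return CompoundRegistry.from_csv(self.registry_path)

    def sampling_schedule(self) -> SamplingSchedule:
        return SamplingSchedule(tuple(self.schedule))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        cfg = cls()
        cell_block = raw.pop("cell", None)
        if cell_block:
            cfg.cell = CellConfig(**cell_block)
        analysis = raw.pop("analysis", None) or {}
        for key in ("window_strategy", "alpha", "k_clusters", "ndigits"):
            if key in analysis:
                setattr(cfg, key, analysis[key])
        if "ratio" in analysis:
            cfg.ratio_membranes = tuple(analysis["ratio"])
        mapping = {
            "registry": "registry_path",
            "schedule": "schedule",
            "membranes": "membranes",
            "n_cells": "n_cells",
            "noise_cv": "noise_cv",
            "seed": "seed",
        }
        for key, attr in mapping.items():
            if key in raw and raw[key] is not None:
                value = raw[key]
                if attr in ("schedule", "membranes"):
                    value = tuple(value)
                setattr(cfg, attr, value)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["cell"] = asdict(self.cell)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def sha256_file(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(
    out_dir: Path,
    config: StudyConfig,
    inputs: Mapping[str, str | Path] = (),
    extra: Mapping[str, Any] | None = None,
) -> Path:
    """Record package version, seed, config hash and input hashes."""
    manifest = {
        "package": "ivperm",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.content_hash(),
        "config": config.to_dict(),
        "inputs": {str(name): sha256_file(p) for name, p in dict(inputs).items()},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path


def read_raw_dataset(path: str | Path) -> pd.DataFrame:
    """Read and validate the long-format concentration table."""
    df = pd.read_csv(path)
    missing = set(RAW_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"dataset missing columns: {sorted(missing)}")
    if df.empty:
        raise InputError(f"dataset {path} is empty")
    for cell_id, grp in df.groupby("cell_id"):
        t = grp["time_h"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise InputError(f"non-monotone timestamps for cell {cell_id!r}")
    return df


def frame_to_series(df: pd.DataFrame) -> list[RawSeries]:
    series = []
    for (cell_id, compound, membrane), grp in df.groupby(
        ["cell_id", "compound", "membrane"], sort=True
    ):
        grp = grp.sort_values("time_h")
        series.append(
            RawSeries(
                cell_id=str(cell_id),
                compound=str(compound),
                membrane=str(membrane),
                times=tuple(grp["time_h"].astype(float)),
                concentrations=tuple(grp["conc_ug_per_ml"].astype(float)),
            )
        )
    return series


def write_dataset(dataset: StudyDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write concentrations.csv + ground_truth.csv for a simulated study."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    conc = out_dir / "concentrations.csv"
    truth = out_dir / "ground_truth.csv"
    dataset.to_frame().to_csv(conc, index=False)
    dataset.ground_truth.to_csv(truth, index=False)
    return {"concentrations": conc, "ground_truth": truth}


@dataclass
class AnalysisResult:
    """All tables produced by one analysis run."""

    profiles: pd.DataFrame
    fits: pd.DataFrame
    parameters: pd.DataFrame
    cumulative24: pd.DataFrame
    ratios: pd.DataFrame
    correlations: pd.DataFrame
    clusters: pd.DataFrame
    accumulation: pd.DataFrame | None = None

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in (
            "profiles",
            "fits",
            "parameters",
            "cumulative24",
            "ratios",
            "correlations",
            "clusters",
            "accumulation",
        ):
            df = getattr(self, name)
            if df is None:
                continue
            path = out_dir / f"{name}.csv"
            df.to_csv(path, index=False)
            paths[name] = path
        return paths


def analyze_dataset(
    df: pd.DataFrame,
    config: StudyConfig,
    registry: CompoundRegistry | None = None,
    accumulation_df: pd.DataFrame | None = None,
) -> AnalysisResult:
    """Run the full pipeline on a long-format concentration table."""
    registry = registry or config.load_registry()

    unknown = sorted(set(df["compound"]) - set(registry.acronyms))
    if unknown:
        raise ResolutionError(f"unknown compound acronyms in dataset: {unknown}")

    series = frame_to_series(df)
    if not series:
        raise InputError("dataset contains no series")

    cell = config.cell
    profiles = [cumulative_amount(s, cell) for s in series]
    fits = [
        fit_steady_state(p, cell, strategy=config.window_strategy) for p in profiles
    ]

    profiles_df = pd.DataFrame(
        [
            {
                "cell_id": p.cell_id,
                "compound": p.compound,
                "membrane": p.membrane,
                "time_h": t,
                "Q_ug_per_cm2": q,
            }
            for p in profiles
            for t, q in zip(p.times, p.Q)
        ]
    )
    fits_df = fits_to_frame(fits)

    # replicate aggregation per compound × membrane
    summaries: dict[tuple[str, str], CompoundSummary] = {}
    for key in sorted({(p.compound, p.membrane) for p in profiles}):
        grp_fits = [f for f in fits if (f.compound, f.membrane) == key]
        grp_profiles = [p for p in profiles if (p.compound, p.membrane) == key]
        summaries[key] = aggregate_cells(grp_fits, grp_profiles)

    letters = _tukey_letters(fits, profiles, alpha=config.alpha)

    parameters_df = pd.DataFrame(
        [
            {
                "compound": s.compound,
                "membrane": s.membrane,
                "n": s.n,
                "Jss_mean": s.J_ss_mean,
                "Jss_sd": s.J_ss_sd,
                "Kp_e3_mean": s.Kp_e3_mean,
                "Kp_e3_sd": s.Kp_e3_sd,
                "LT_mean": s.L_T_mean,
                "LT_sd": s.L_T_sd,
                "r2_fit_mean": float(
                    np.mean([f.r2_fit for f in fits if (f.compound, f.membrane) == key])
                ),
                "window": _modal_window(fits, key),
                "letters_Jss": letters["Jss"].get(key, ""),
                "letters_LT": letters["LT"].get(key, ""),
            }
            for key, s in summaries.items()
        ]
    )

    cumulative24_df = pd.DataFrame(
        [
            {
                "compound": s.compound,
                "membrane": s.membrane,
                "n": s.n,
                "Q24_mean_ug_per_cm2": s.Q24_mean,
                "Q24_sd_ug_per_cm2": s.Q24_sd,
                "letters": letters["Q24"].get(key, ""),
            }
            for key, s in summaries.items()
        ]
    )

    num_mem, den_mem = config.ratio_membranes
    ratio_rows = []
    for compound in sorted({c for c, _ in summaries}):
        a, b = summaries.get((compound, num_mem)), summaries.get((compound, den_mem))
        if a is None or b is None:
            continue
        ratio_rows.append(
            {
                "compound": compound,
                "numerator_membrane": num_mem,
                "denominator_membrane": den_mem,
                "ratio": permeation_ratio(a, b),
            }
        )
    ratios_df = pd.DataFrame(ratio_rows)

    correlations_df, mean_profiles = _membrane_correlations(
        profiles_df, num_mem, den_mem
    )

    clusters_df = _cluster_table(mean_profiles, cumulative24_df, config.k_clusters)

    accumulation_out = None
    if accumulation_df is not None:
        accumulation_out = process_accumulation_table(accumulation_df, registry)

    return AnalysisResult(
        profiles=profiles_df,
        fits=fits_df,
        parameters=parameters_df,
        cumulative24=cumulative24_df,
        ratios=ratios_df,
        correlations=correlations_df,
        clusters=clusters_df,
        accumulation=accumulation_out,
    )


def _modal_window(fits, key) -> str:
    windows = [f"{f.window[0]}:{f.window[1]}" for f in fits if (f.compound, f.membrane) == key]
    return max(sorted(set(windows)), key=windows.count)


def _tukey_letters(fits, profiles, alpha: float) -> dict[str, dict[tuple[str, str], str]]:
    """Compact letters per membrane for Jss, LT and 24 h cumulative mass."""
    out: dict[str, dict[tuple[str, str], str]] = {"Jss": {}, "LT": {}, "Q24": {}}
    membranes = sorted({f.membrane for f in fits})
    for membrane in membranes:
        mem_fits = [f for f in fits if f.membrane == membrane]
        mem_profiles = [p for p in profiles if p.membrane == membrane]
        counts = pd.Series([f.compound for f in mem_fits]).value_counts()
        if len(counts) < 2 or counts.min() < 2:
            continue  # letters need >= 2 groups with >= 2 cells
        for name, values, groups in (
            ("Jss", [f.J_ss for f in mem_fits], [f.compound for f in mem_fits]),
            ("LT", [f.L_T for f in mem_fits], [f.compound for f in mem_fits]),
            ("Q24", [p.Q[-1] for p in mem_profiles], [p.compound for p in mem_profiles]),
        ):
            result = anova_tukey_cld(values, groups, alpha=alpha)
            for compound, letter in result.letters.items():
                out[name][(compound, membrane)] = letter
    return out


def _membrane_correlations(
    profiles_df: pd.DataFrame, mem_a: str, mem_b: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-compound and pooled Pearson correlations between membrane mean profiles.

    Also returns the compound × (membrane, time) matrix of mean profiles used
    downstream for clustering.
    """
    mean_profiles = (
        profiles_df.groupby(["compound", "membrane", "time_h"])["Q_ug_per_cm2"]
        .mean()
        .unstack(["membrane", "time_h"])
        .sort_index(axis=1)
    )
    rows = []
    pooled_a: list[float] = []
    pooled_b: list[float] = []
    for compound, row in mean_profiles.iterrows():
        try:
            qa, qb = row[mem_a].to_numpy(), row[mem_b].to_numpy()
        except KeyError:
            continue
        res = pearson_profile_correlation(qa, qb, label=str(compound))
        rows.append(
            {"compound": compound, "r": res.r, "r2": res.r2, "n": res.n, "p_value": res.p_value}
        )
        pooled_a.extend(qa)
        pooled_b.extend(qb)
    if len(pooled_a) >= 3:
        res = pearson_profile_correlation(pooled_a, pooled_b, label="pooled")
        rows.append(
            {"compound": "pooled", "r": res.r, "r2": res.r2, "n": res.n, "p_value": res.p_value}
        )
    return pd.DataFrame(rows), mean_profiles


def _cluster_table(
    mean_profiles: pd.DataFrame, cumulative24_df: pd.DataFrame, k: int
) -> pd.DataFrame:
    if len(mean_profiles) < max(k, 2):
        return pd.DataFrame(columns=["compound", "cluster"])
    q24 = cumulative24_df.groupby("compound")["Q24_mean_ug_per_cm2"].mean()
    result = cluster_penetration_profiles(
        mean_profiles, k=k, order_by=q24.reindex(mean_profiles.index)
    )
    return pd.DataFrame(
        {"compound": result.assignments.index, "cluster": result.assignments.to_numpy()}
    )
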