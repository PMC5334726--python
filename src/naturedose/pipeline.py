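"""Configured, reproducible end-to-end pipeline.

Stages: simulate (synthetic survey) -> score (dose encodings) -> intensity
(vegetation cover merge) -> fit (all-subsets AICc model averaging per
outcome and model set) -> dose-response (threshold scans + plots) -> aaf
(average attributable fractions).  A JSON run manifest records the config
hash, package version, seed, per-stage row counts and warnings; outputs are
deterministic for a fixed config and seed (CSV floats use a fixed format
and no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, scales
from . import attributable as af
from . import dose_response as dr
from . import model_averaging as ma
from . import synthetic as syn
from .dose_response import RiskFactor
from .vegetation import classify_vegetation, cover_for_points, read_ascii_grid

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "default_aaf_factors",
    "run_simulate",
    "run_score",
    "run_intensity",
    "run_fit",
    "run_dose_response",
    "run_aaf",
    "run_all",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def default_aaf_factors() -> tuple[RiskFactor, ...]:
    """The six default removable risk factors: three socio-demographic cuts
    plus one per nature dose (minimum-dose-not-met indicators)."""
    return dr.default_risk_factors() + (
        RiskFactor("freq_below_once_per_week", "freq_visits_per_week", 1.0,
                   "below", note="higher risk < once per week"),
        RiskFactor("duration_below_5h_per_week", "duration_min_per_week", 300.0,
                   "below", note="higher risk < five hours per week"),
        RiskFactor("intensity_below_15pct", "vegetation_cover_pct", 15.0,
                   "below", note="higher risk < 15% vegetation cover"),
    )


@dataclass
class PipelineConfig:
    """Declarative configuration for a full pipeline run."""

    seed: int = 0
    n_respondents: int = 1000
    output_dir: str = "naturedose_out"
    survey_csv: str | None = None  # external survey; None -> simulate
    ndvi_grid: str | None = None
    height_grid: str | None = None
    points_csv: str | None = None
    buffer_radius_m: float = 250.0
    candidate_blocks: tuple[str, ...] = (
        "age", "gender", "income", "education", "time_outdoors",
    )
    include_outcome_predictors: bool = False
    responses: tuple[str, ...] = tuple(ma.OUTCOME_FAMILIES)
    delta_aicc_max: float = 6.0
    plateau_tol: float = 0.05
    depression_cutoff: int = scales.DASS_MILD_CUTOFF
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("candidate_blocks", "responses"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def outdir(self) -> Path:
        p = Path(self.output_dir)
        p.mkdir(parents=True, exist_ok=True)
        return p


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    row_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    outputs: list = field(default_factory=list)

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        with tmp.open("w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, path)


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    manifest.outputs.append(path.name)


def _load_survey(config: PipelineConfig) -> syn.SurveyTable:
    if config.survey_csv is not None:
        return syn.SurveyTable.read_csv(config.survey_csv)
    gen = syn.default_config(config.n_respondents, config.seed)
    return syn.generate_survey(gen)


def run_simulate(config: PipelineConfig) -> Path:
    """Generate the synthetic survey and write it (plus provenance)."""
    if config.n_respondents < 1:
        raise ValueError("n_respondents must be >= 1")
    table = syn.generate_survey(syn.default_config(config.n_respondents, config.seed))
    out = config.outdir() / "survey.csv"
    table.write_csv(out)
    return out


def run_score(config: PipelineConfig, survey: pd.DataFrame | None = None) -> pd.DataFrame:
    """Ensure encoded dose columns exist, deriving them from categories."""
    df = survey if survey is not None else _load_survey(config).data.copy()
    if "freq_visits_per_week" not in df.columns and "freq_category" in df.columns:
        df["freq_visits_per_week"] = df["freq_category"].map(scales.encode_frequency)
    if "duration_min_per_week" not in df.columns and "duration_category" in df.columns:
        df["duration_min_per_week"] = df["duration_category"].map(
            scales.encode_duration_midpoint
        )
    return df


def run_intensity(config: PipelineConfig) -> Path:
    """Compute per-respondent percent vegetation cover from raster inputs."""
    if not (config.ndvi_grid and config.height_grid and config.points_csv):
        raise ValueError(
            "intensity stage needs ndvi_grid, height_grid and points_csv"
        )
    ndvi = read_ascii_grid(config.ndvi_grid)
    height = read_ascii_grid(config.height_grid)
    mask = classify_vegetation(ndvi, height)
    points = pd.read_csv(config.points_csv)
    cover = cover_for_points(mask, points, radius_m=config.buffer_radius_m)
    out = config.outdir() / "vegetation_cover.csv"
    cover.to_csv(out, index=False, float_format=_FLOAT_FMT)
    return out


def run_fit(
    config: PipelineConfig,
    survey: pd.DataFrame | None = None,
    manifest: RunManifest | None = None,
) -> dict[str, dict[str, Path]]:
    """All-subsets AICc model averaging for every response and model set."""
    df = run_score(config, survey)
    manifest = manifest or RunManifest(config.config_hash(), __version__, config.seed)
    have_intensity = (
        "vegetation_cover_pct" in df.columns
        and df["vegetation_cover_pct"].notna().any()
    )
    specs = ma.build_model_sets(
        covariate_block_names=config.candidate_blocks,
        include_outcome_predictors=config.include_outcome_predictors,
        responses=config.responses,
    )
    outdir = config.outdir()
    written: dict[str, dict[str, Path]] = {}
    for response, sets in specs.items():
        written[response] = {}
        for label, spec in sets.items():
            if label == "iv" and not have_intensity:
                msg = f"{response}: intensity column missing; skipping set (iv)"
                logger.warning(msg)
                manifest.warnings.append(msg)
                continue
            cand = ma.all_subsets(spec, df, delta_max=config.delta_aicc_max)
            manifest.row_counts[f"fit:{response}:{label}"] = {
                "input": len(df),
                "used": len(df) - cand.n_dropped_rows,
                "dropped": cand.n_dropped_rows,
            }
            avg = ma.averaged_table(cand, df)
            path = outdir / f"averaged_{response}_{label}.csv"
            _write_csv(avg, path, manifest)
            _write_csv(
                ma.ranking_table(cand), outdir / f"ranking_{response}_{label}.csv",
                manifest,
            )
            written[response][label] = path
    return written


def run_dose_response(
    config: PipelineConfig,
    survey: pd.DataFrame | None = None,
    manifest: RunManifest | None = None,
) -> dict[str, dr.DoseResponseCurve]:
    """Threshold scans for the three doses, with CSV (and plot) outputs."""
    df = run_score(config, survey)
    manifest = manifest or RunManifest(config.config_hash(), __version__, config.seed)
    adjusters = dr.default_risk_factors()
    outdir = config.outdir()
    curves: dict[str, dr.DoseResponseCurve] = {}
    for dose, grid in dr.default_grids().items():
        if grid.column not in df.columns or df[grid.column].isna().all():
            msg = f"dose-response: {grid.column} missing; skipping {dose}"
            logger.warning(msg)
            manifest.warnings.append(msg)
            continue
        curve = dr.scan_thresholds(df, grid, adjusters)
        curve.optimal_dose = (
            dr.find_optimal_dose(curve, config.plateau_tol)
            if curve.minimum_dose is not None else None
        )
        frame = curve.to_frame()
        frame["minimum_dose"] = curve.minimum_dose
        frame["optimal_dose"] = curve.optimal_dose
        _write_csv(frame, outdir / f"dose_response_{dose}.csv", manifest)
        if config.make_plots:
            _plot_curve(curve, outdir / f"dose_response_{dose}.png")
        curves[dose] = curve
    return curves


def _plot_curve(curve: dr.DoseResponseCurve, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    t = [r.threshold for r in curve.results]
    orr = [r.odds_ratio for r in curve.results]
    lo = [r.odds_ratio - r.ci_low for r in curve.results]
    hi = [r.ci_high - r.odds_ratio for r in curve.results]
    ax.errorbar(t, orr, yerr=[lo, hi], fmt="o-", capsize=3)
    ax.axhline(1.0, color="grey", ls="--", lw=1)
    if curve.minimum_dose is not None:
        ax.axvline(curve.minimum_dose, color="tab:green", ls=":",
                   label="minimum dose")
    if curve.optimal_dose is not None:
        ax.axvline(curve.optimal_dose, color="tab:orange", ls=":",
                   label="optimal dose")
    ax.set_xlabel(f"{curve.dose} threshold")
    ax.set_ylabel("adjusted odds ratio (dose not met)")
    if curve.minimum_dose is not None or curve.optimal_dose is not None:
        ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_aaf(
    config: PipelineConfig,
    survey: pd.DataFrame | None = None,
    manifest: RunManifest | None = None,
    use_permutation: bool = False,
) -> af.AAFTable:
    """Fit the binary risk model and decompose the attributable fraction."""
    df = run_score(config, survey)
    manifest = manifest or RunManifest(config.config_hash(), __version__, config.seed)
    factors = [
        f for f in default_aaf_factors()
        if f.column in df.columns and df[f.column].notna().any()
    ]
    skipped = set(f.name for f in default_aaf_factors()) - set(f.name for f in factors)
    for name in sorted(skipped):
        msg = f"aaf: source column missing for factor {name}; dropped"
        logger.warning(msg)
        manifest.warnings.append(msg)
    work = df.copy()
    for f in factors:
        work[f.name] = f.apply(df)
    names = tuple(f.name for f in factors)
    model = af.fit_risk_model(work, names, outcome="depression")
    table = (
        af.average_af_permutation(model) if use_permutation
        else af.average_af_shapley(model)
    )
    outdir = config.outdir()
    _write_csv(table.to_frame(), outdir / "aaf_table.csv", manifest)
    # scenario audit: expected cases for each single- and all-factor removal
    audit_rows = [{"removed": "(none)",
                   "expected_cases": af.expected_cases(model, frozenset())}]
    for name in names:
        audit_rows.append(
            {"removed": name,
             "expected_cases": af.expected_cases(model, frozenset({name}))}
        )
    audit_rows.append(
        {"removed": "(all)",
         "expected_cases": af.expected_cases(model, frozenset(names))}
    )
    _write_csv(pd.DataFrame(audit_rows), outdir / "aaf_scenarios.csv", manifest)
    return table


def run_all(config: PipelineConfig) -> RunManifest:
    """Run simulate/score -> fit -> dose-response -> aaf and write a manifest."""
    manifest = RunManifest(config.config_hash(), __version__, config.seed)
    if config.survey_csv is None:
        survey_path = run_simulate(config)
        manifest.outputs.append(survey_path.name)
        df = pd.read_csv(survey_path)
    else:
        df = _load_survey(config).data
    df = run_score(config, df)
    manifest.row_counts["survey"] = {"input": len(df)}
    run_fit(config, df, manifest)
    run_dose_response(config, df, manifest)
    run_aaf(config, df, manifest)
    manifest.write(config.outdir() / "manifest.json")
    return manifest
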