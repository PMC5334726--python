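"""Synthetic survey and raster generation with known ground truth.

This module emulates the kind of respondent-level lifestyle survey the
analysis pipeline consumes: ~1000 adults with socio-demographic covariates,
three nature-dose variables (frequency and duration of garden visits, and
neighbourhood vegetation intensity), and five health outcomes (binary
depression, 5-level ordinal self-rated health, continuous 0–12 social
cohesion, 0–7 weekly exercise days, continuous nature relatedness).

Every generative parameter is recorded in the table's provenance so
downstream stages can be tested against known truth:

* frequency and duration categories are drawn from a Gaussian copula whose
  correlation is calibrated analytically so the *population* Spearman rank
  correlation of the discretised pair equals the configured target (default
  0.67), after enforcing the logical constraint that respondents who never
  visit report no garden time;
* vegetation cover is Gaussian with mean 24% and SD 9.1% (clipped to
  [0, 100]);
* depression is Bernoulli(inverse-logit(linear predictor)), with optional
  step-shaped dose effects for dose-response experiments; ordinal health
  follows a proportional-odds model; exercise days are Poisson capped at 7;
  the continuous outcomes are Gaussian.

The marginal category probabilities of the doses and covariates are
plausible defaults, not survey-reported values; see docs/methods.md.

Randomness uses one global integer seed feeding named substreams (one per
variable), so adding a variable does not perturb the draws of the others.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import multivariate_normal, norm

from . import scales
from .terms import default_blocks, design_matrix
from .vegetation import RasterGrid

__all__ = [
    "DoseSpec",
    "IntensitySpec",
    "StepEffect",
    "OutcomeSpec",
    "CovariateSpec",
    "GenerativeConfig",
    "SurveyTable",
    "generate_survey",
    "generate_raster_scene",
    "default_config",
]

OUTCOME_ORDER = (
    "self_health",
    "social_cohesion",
    "exercise_days",
    "nature_relatedness",
    "depression",
)


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent, named RNG substream derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def _check_probs(p, name: str, n: int) -> tuple[float, ...]:
    p = tuple(float(x) for x in p)
    if len(p) != n:
        raise ValueError(f"{name}: expected {n} probabilities, got {len(p)}")
    if any(x < 0 for x in p):
        raise ValueError(f"{name}: probabilities must be non-negative")
    if abs(sum(p) - 1.0) > 1e-8:
        raise ValueError(f"{name}: probabilities must sum to 1, got {sum(p)}")
    return p


@dataclass(frozen=True)
class DoseSpec:
    """Marginal dose-category probabilities and the rank-correlation target."""

    frequency_probs: tuple[float, ...] = (0.15, 0.10, 0.15, 0.25, 0.20, 0.15)
    duration_probs: tuple[float, ...] = (
        0.15, 0.10, 0.10, 0.20, 0.15, 0.12, 0.08, 0.10,
    )
    rank_correlation: float = 0.67

    def __post_init__(self) -> None:
        _check_probs(self.frequency_probs, "frequency_probs", 6)
        _check_probs(self.duration_probs, "duration_probs", 8)
        if not -1.0 <= self.rank_correlation <= 1.0:
            raise ValueError(
                f"rank_correlation must lie in [-1, 1], got {self.rank_correlation}"
            )


@dataclass(frozen=True)
class IntensitySpec:
    """Percent vegetation-cover distribution across neighbourhoods."""

    mean: float = 24.0
    sd: float = 9.1


@dataclass(frozen=True)
class StepEffect:
    """A threshold-shaped dose effect on an outcome's linear predictor.

    Adds ``size`` to the linear predictor for respondents whose encoded dose
    is at or above ``threshold``.
    """

    dose_column: str
    threshold: float
    size: float


@dataclass(frozen=True)
class OutcomeSpec:
    """Generative model for one health outcome.

    ``coefficients`` are keyed by design-matrix column names (see
    :func:`naturedose.terms.default_blocks`), e.g. ``"age"``,
    ``"gender[female]"``, ``"freq_visits_per_week"``.
    """

    family: str  # binomial | ordinal | gaussian | poisson
    intercept: float = 0.0
    coefficients: Mapping[str, float] = field(default_factory=dict)
    step_effects: tuple[StepEffect, ...] = ()
    sd: float = 1.0  # gaussian only
    cutpoints: tuple[float, ...] = ()  # ordinal only
    clip: tuple[float, float] | None = None  # gaussian only
    max_count: int = 7  # poisson only

    def __post_init__(self) -> None:
        if self.family not in ("binomial", "ordinal", "gaussian", "poisson"):
            raise ValueError(f"unknown outcome family {self.family!r}")
        if self.family == "ordinal":
            cp = self.cutpoints
            if len(cp) < 1 or any(b <= a for a, b in zip(cp, cp[1:])):
                raise ValueError(
                    f"ordinal cutpoints must be strictly increasing, got {cp}"
                )
        if self.family == "gaussian" and self.sd <= 0:
            raise ValueError(f"gaussian sd must be positive, got {self.sd}")


@dataclass(frozen=True)
class CovariateSpec:
    """Socio-demographic covariate distributions (plausible defaults)."""

    age_mean: float = 45.0
    age_sd: float = 15.0
    age_min: float = 18.0
    age_max: float = 90.0
    p_female: float = 0.5
    children_probs: tuple[float, ...] = (0.45, 0.25, 0.20, 0.08, 0.02)  # 0..4
    p_other_language: float = 0.08
    workdays_probs: tuple[float, ...] = (
        0.18, 0.04, 0.05, 0.08, 0.10, 0.35, 0.12, 0.08,
    )  # 0..7
    income_probs: tuple[float, ...] = (0.15, 0.25, 0.25, 0.20, 0.15)  # bands 1..5
    education_probs: tuple[float, ...] = (0.30, 0.30, 0.25, 0.15)
    time_outdoors_probs: tuple[float, ...] = (0.25, 0.50, 0.25)

    def __post_init__(self) -> None:
        _check_probs(self.children_probs, "children_probs", 5)
        _check_probs(self.workdays_probs, "workdays_probs", 8)
        _check_probs(self.income_probs, "income_probs", 5)
        _check_probs(self.education_probs, "education_probs", 4)
        _check_probs(self.time_outdoors_probs, "time_outdoors_probs", 3)


def default_outcomes() -> dict[str, OutcomeSpec]:
    """Default generative models for the five outcomes.

    Dose effects are protective for depression (more nature, lower odds) and
    positive for cohesion, exercise and nature relatedness, with magnitudes
    giving realistic outcome distributions (~30% depression prevalence).
    """
    return {
        "depression": OutcomeSpec(
            family="binomial",
            intercept=1.6,
            coefficients={
                "age": -0.023,
                "gender[female]": -0.15,
                "time_outdoors[same]": -0.5,
                "time_outdoors[more]": -0.9,
                "freq_visits_per_week": -0.15,
                "vegetation_cover_pct": -0.02,
            },
        ),
        "self_health": OutcomeSpec(
            family="ordinal",
            coefficients={"age": -0.012, "income": 0.15},
            cutpoints=(-3.0, -1.8, -0.3, 1.2),
        ),
        "social_cohesion": OutcomeSpec(
            family="gaussian",
            intercept=4.5,
            coefficients={"income": 0.3, "freq_visits_per_week": 0.12},
            sd=2.0,
            clip=(0.0, 12.0),
        ),
        "exercise_days": OutcomeSpec(
            family="poisson",
            intercept=0.5,
            coefficients={
                "freq_visits_per_week": 0.06,
                "time_outdoors[more]": 0.2,
            },
        ),
        "nature_relatedness": OutcomeSpec(
            family="gaussian",
            intercept=2.4,
            coefficients={
                "age": 0.004,
                "freq_visits_per_week": 0.06,
                "time_outdoors[more]": 0.15,
            },
            sd=0.7,
            clip=(1.0, 5.0),
        ),
    }


@dataclass(frozen=True)
class GenerativeConfig:
    """Full generative specification of a synthetic survey."""

    n_respondents: int = 1000
    seed: int = 0
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    dose: DoseSpec = field(default_factory=DoseSpec)
    intensity: IntensitySpec = field(default_factory=IntensitySpec)
    outcomes: Mapping[str, OutcomeSpec] = field(default_factory=default_outcomes)

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError(
                f"n_respondents must be >= 1, got {self.n_respondents}"
            )
        unknown = set(self.outcomes) - set(OUTCOME_ORDER)
        if unknown:
            raise ValueError(f"unknown outcome names: {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_config(n_respondents: int = 1000, seed: int = 0) -> GenerativeConfig:
    return GenerativeConfig(n_respondents=n_respondents, seed=seed)


@dataclass
class SurveyTable:
    """A respondent table plus the provenance needed to reproduce it."""

    data: pd.DataFrame
    provenance: dict

    def write_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        with sidecar.open("w") as fh:
            json.dump(self.provenance, fh, indent=1, sort_keys=True, default=str)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SurveyTable":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        prov = {"source": "external file"}
        if sidecar.exists():
            with sidecar.open() as fh:
                prov = json.load(fh)
        return cls(data=df, provenance=prov)


# ---------------------------------------------------------------------------
# Gaussian-copula calibration for the frequency/duration rank correlation
# ---------------------------------------------------------------------------

def _bvn_cdf_grid(x_cuts: np.ndarray, y_cuts: np.ndarray, rho: float) -> np.ndarray:
    """CDF of the standard bivariate normal at a grid of cut points."""
    mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]],
                              allow_singular=True)
    C = np.zeros((len(x_cuts), len(y_cuts)))
    for i, x in enumerate(x_cuts):
        for j, y in enumerate(y_cuts):
            if np.isneginf(x) or np.isneginf(y):
                C[i, j] = 0.0
            elif np.isposinf(x) and np.isposinf(y):
                C[i, j] = 1.0
            elif np.isposinf(x):
                C[i, j] = norm.cdf(y)
            elif np.isposinf(y):
                C[i, j] = norm.cdf(x)
            else:
                C[i, j] = float(mvn.cdf([x, y]))
    return C


def _joint_cell_probs(
    freq_probs: tuple[float, ...], dur_probs: tuple[float, ...], rho: float
) -> np.ndarray:
    """Joint category probabilities of the discretised Gaussian-copula pair,
    after enforcing frequency "never" => duration "no time"."""
    fx = np.concatenate([[-np.inf], norm.ppf(np.cumsum(freq_probs))[:-1], [np.inf]])
    fy = np.concatenate([[-np.inf], norm.ppf(np.cumsum(dur_probs))[:-1], [np.inf]])
    C = _bvn_cdf_grid(fx, fy, rho)
    P = np.diff(np.diff(C, axis=0), axis=1)
    P = np.clip(P, 0.0, None)
    # logical consistency: never visiting implies no garden time
    P[0, 0] += P[0, 1:].sum()
    P[0, 1:] = 0.0
    return P / P.sum()


def _population_spearman(P: np.ndarray) -> float:
    """Spearman rank correlation (midrank grades) of a discrete joint."""
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    gx = np.cumsum(px) - px / 2.0
    gy = np.cumsum(py) - py / 2.0
    mx = float(px @ gx)
    my = float(py @ gy)
    cov = float(gx @ P @ gy) - mx * my
    vx = float(px @ (gx - mx) ** 2)
    vy = float(py @ (gy - my) ** 2)
    if vx <= 0 or vy <= 0:
        raise ValueError("degenerate dose marginal: zero rank variance")
    return cov / np.sqrt(vx * vy)


@lru_cache(maxsize=64)
def _calibrate_copula_rho(
    freq_probs: tuple[float, ...], dur_probs: tuple[float, ...], target: float
) -> float:
    """Copula correlation whose discretised pair has the target Spearman."""

    def f(rho: float) -> float:
        return _population_spearman(_joint_cell_probs(freq_probs, dur_probs, rho)) - target

    lo, hi = -0.999, 0.999
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        achievable = (flo + target, fhi + target)
        raise ValueError(
            f"rank-correlation target {target} is unachievable for these "
            f"marginals; achievable range is about [{achievable[0]:.3f}, "
            f"{achievable[1]:.3f}]"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-6))


# ---------------------------------------------------------------------------
# Survey generation
# ---------------------------------------------------------------------------

def _draw_categorical(rng: np.random.Generator, probs, n: int) -> np.ndarray:
    return rng.choice(len(probs), size=n, p=np.asarray(probs, dtype=float))


def _generate_covariates(cfg: GenerativeConfig) -> pd.DataFrame:
    n = cfg.n_respondents
    cv = cfg.covariates
    seed = cfg.seed

    age = _substream(seed, "age").normal(cv.age_mean, cv.age_sd, size=n)
    age = np.clip(np.round(age), cv.age_min, cv.age_max)

    gender = np.where(
        _substream(seed, "gender").random(n) < cv.p_female, "female", "male"
    )
    children = _draw_categorical(_substream(seed, "children"), cv.children_probs, n)
    language = np.where(
        _substream(seed, "language").random(n) < cv.p_other_language,
        "other",
        "english",
    )
    workdays = _draw_categorical(_substream(seed, "workdays"), cv.workdays_probs, n)
    income = 1 + _draw_categorical(_substream(seed, "income"), cv.income_probs, n)
    edu_levels = ("gcse", "alevel", "undergrad", "postgrad")
    education = np.array(edu_levels)[
        _draw_categorical(_substream(seed, "education"), cv.education_probs, n)
    ]
    out_levels = ("less", "same", "more")
    time_outdoors = np.array(out_levels)[
        _draw_categorical(
            _substream(seed, "time_outdoors"), cv.time_outdoors_probs, n
        )
    ]
    return pd.DataFrame(
        {
            "respondent_id": np.arange(1, n + 1),
            "age": age,
            "gender": gender,
            "children": children,
            "language": language,
            "workdays": workdays,
            "income": income,
            "education": education,
            "time_outdoors": time_outdoors,
        }
    )


def _generate_doses(cfg: GenerativeConfig, df: pd.DataFrame) -> float:
    """Draw dose categories into df; returns the calibrated copula rho."""
    n = cfg.n_respondents
    rho = _calibrate_copula_rho(
        cfg.dose.frequency_probs, cfg.dose.duration_probs, cfg.dose.rank_correlation
    )
    rng = _substream(cfg.seed, "doses")
    z = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n, method="cholesky"
    )
    u = norm.cdf(z)
    f_idx = np.searchsorted(np.cumsum(cfg.dose.frequency_probs), u[:, 0], side="left")
    d_idx = np.searchsorted(np.cumsum(cfg.dose.duration_probs), u[:, 1], side="left")
    f_idx = np.clip(f_idx, 0, 5)
    d_idx = np.clip(d_idx, 0, 7)
    d_idx[f_idx == 0] = 0  # never visits => no garden time

    f_cats = np.array(scales.FREQUENCY_CATEGORIES)[f_idx]
    d_cats = np.array(scales.DURATION_CATEGORIES)[d_idx]
    df["freq_category"] = f_cats
    df["freq_visits_per_week"] = [scales.FREQUENCY_ENCODING[c] for c in f_cats]
    df["duration_category"] = d_cats
    df["duration_min_per_week"] = [scales.DURATION_ENCODING[c] for c in d_cats]

    cover = _substream(cfg.seed, "intensity").normal(
        cfg.intensity.mean, cfg.intensity.sd, size=n
    )
    df["vegetation_cover_pct"] = np.clip(cover, 0.0, 100.0)
    return rho


def _linear_predictor(spec: OutcomeSpec, design: pd.DataFrame, df: pd.DataFrame) -> np.ndarray:
    eta = np.full(len(df), float(spec.intercept))
    for col, beta in spec.coefficients.items():
        if col not in design.columns:
            raise ValueError(
                f"coefficient refers to unknown design column {col!r}; "
                f"known columns: {list(design.columns)}"
            )
        eta += beta * design[col].to_numpy(dtype=float)
    for step in spec.step_effects:
        dose = df[step.dose_column].to_numpy(dtype=float)
        eta += step.size * (dose >= step.threshold)
    return eta


def _invlogit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _generate_outcome(
    name: str, spec: OutcomeSpec, cfg: GenerativeConfig,
    design: pd.DataFrame, df: pd.DataFrame,
) -> np.ndarray:
    rng = _substream(cfg.seed, f"outcome:{name}")
    eta = _linear_predictor(spec, design, df)
    if spec.family == "binomial":
        return (rng.random(len(df)) < _invlogit(eta)).astype(int)
    if spec.family == "ordinal":
        u = rng.random(len(df))
        y = np.ones(len(df), dtype=int)
        for theta in spec.cutpoints:
            y += (u > _invlogit(theta - eta)).astype(int)
        return y
    if spec.family == "poisson":
        return np.minimum(rng.poisson(np.exp(eta)), spec.max_count)
    # gaussian
    y = rng.normal(eta, spec.sd)
    if spec.clip is not None:
        y = np.clip(y, *spec.clip)
    return y


def generate_survey(config: GenerativeConfig) -> SurveyTable:
    """Generate a complete synthetic survey table.

    Deterministic given ``config`` (including its seed).  The generative
    parameters, the calibrated copula correlation, and the configured
    targets are stored in the table's provenance.
    """
    df = _generate_covariates(config)
    rho = _generate_doses(config, df)

    blocks = default_blocks()
    for name in OUTCOME_ORDER:
        if name not in config.outcomes:
            continue
        spec = config.outcomes[name]
        # design columns may reference previously generated outcomes
        available = [
            b for b in blocks.values()
            if b.source in df.columns
        ]
        design = design_matrix(df, tuple(available), add_intercept=False)
        df[name] = _generate_outcome(name, spec, config, design, df)
        if name == "self_health":
            df[name] = df[name].astype(int)

    provenance = {
        "generator": "naturedose.synthetic.generate_survey",
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_respondents": config.n_respondents,
        "copula_rho": rho,
        "rank_correlation_target": config.dose.rank_correlation,
        "true_parameters": {
            name: asdict(spec) for name, spec in config.outcomes.items()
        },
    }
    return SurveyTable(data=df, provenance=provenance)


# ---------------------------------------------------------------------------
# Raster scenes
# ---------------------------------------------------------------------------

_VEG_NDVI, _VEG_HEIGHT = 0.6, 5.0
_BARE_NDVI, _BARE_HEIGHT = 0.05, 0.2


def generate_raster_scene(
    width_px: int,
    height_px: int,
    pixel_size_m: float = 2.0,
    pattern: str = "uniform_veg",
    seed: int = 0,
    p: float | None = None,
) -> tuple[RasterGrid, RasterGrid]:
    """Generate aligned NDVI and canopy-height rasters with exact geometry.

    Patterns: ``uniform_veg`` (every pixel tall vegetation), ``uniform_bare``,
    ``half_plane`` (left half of the scene vegetated), ``checkerboard``
    (alternating single pixels), ``random`` (i.i.d. Bernoulli(p) per pixel).
    Vegetated pixels get NDVI 0.6 and height 5 m; bare pixels 0.05 and 0.2 m,
    so classification at the standard thresholds is unambiguous.
    """
    if width_px <= 0 or height_px <= 0:
        raise ValueError(
            f"raster dimensions must be positive, got {width_px}x{height_px}"
        )
    if pixel_size_m <= 0:
        raise ValueError(f"pixel size must be positive, got {pixel_size_m}")

    shape = (height_px, width_px)
    if pattern == "uniform_veg":
        veg = np.ones(shape, dtype=bool)
    elif pattern == "uniform_bare":
        veg = np.zeros(shape, dtype=bool)
    elif pattern == "half_plane":
        cols = np.arange(width_px)
        veg = np.broadcast_to(cols < width_px / 2.0, shape).copy()
    elif pattern == "checkerboard":
        r, c = np.indices(shape)
        veg = (r + c) % 2 == 0
    elif pattern == "random":
        if p is None or not 0.0 <= p <= 1.0:
            raise ValueError("random pattern requires p in [0, 1]")
        veg = _substream(seed, "raster").random(shape) < p
    else:
        raise ValueError(f"unknown raster pattern {pattern!r}")

    ndvi = np.where(veg, _VEG_NDVI, _BARE_NDVI)
    hgt = np.where(veg, _VEG_HEIGHT, _BARE_HEIGHT)
    return (
        RasterGrid(ndvi, pixel_size=pixel_size_m),
        RasterGrid(hgt, pixel_size=pixel_size_m),
    )
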