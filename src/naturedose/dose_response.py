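"""Threshold-scan dose-response analysis for binary depression.

Each nature dose (visit frequency, garden time, vegetation intensity) is
recoded at a ladder of incrementally higher thresholds into a binary risk
indicator — 1 when the dose is *not* met (dose < threshold), 0 when it is.
At every threshold an adjusted logistic regression of depression on the
risk indicator plus binary adjuster covariates is fitted; the dose
coefficient exponentiates to an odds ratio with a Wald 95% CI.  An odds
ratio above one means depression is more likely where the dose is not met.

Two summary points are read off the resulting curve:

* minimum dose — the smallest threshold whose CI strictly excludes 1;
* optimal dose — the smallest significant threshold beyond which no later
  significant odds ratio is more than a relative tolerance higher (a
  plateau rule; the notion of "optimum" is operationalised here, since a
  rising curve through the final threshold means the optimum has not been
  reached and is reported as undefined).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RiskFactor",
    "ThresholdGrid",
    "ThresholdResult",
    "DoseResponseCurve",
    "binarize_dose_at_threshold",
    "scan_thresholds",
    "find_minimum_dose",
    "find_optimal_dose",
    "default_grids",
    "default_risk_factors",
]

logger = logging.getLogger(__name__)

_Z95 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class RiskFactor:
    """A named binary high-risk (1) / low-risk (0) recoding of a variable."""

    name: str
    column: str
    cut: float | str
    direction: str = "below"  # high risk when value is below/equals the cut
    note: str = ""

    def apply(self, data: pd.DataFrame) -> np.ndarray:
        col = data[self.column]
        if self.direction == "below":
            return (col.to_numpy(dtype=float) < float(self.cut)).astype(int)
        if self.direction == "equals":
            return (col.astype(str) == str(self.cut)).to_numpy().astype(int)
        raise ValueError(f"unknown risk direction {self.direction!r}")


@dataclass(frozen=True)
class ThresholdGrid:
    """Ascending exposure thresholds on one dose's encoded scale."""

    dose: str  # frequency | duration | intensity
    column: str
    thresholds: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = self.thresholds
        if len(t) < 2:
            raise ValueError(f"grid for {self.dose!r} needs >= 2 thresholds")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError(f"thresholds must be strictly increasing: {t}")
        if self.labels and len(self.labels) != len(t):
            raise ValueError("labels and thresholds differ in length")


@dataclass
class ThresholdResult:
    threshold: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_high_risk: int
    n_low_risk: int
    converged: bool
    label: str = ""

    @property
    def significant(self) -> bool:
        """CI strictly excludes OR = 1 (in either direction)."""
        return self.converged and (self.ci_low > 1.0 or self.ci_high < 1.0)


@dataclass
class DoseResponseCurve:
    dose: str
    results: list[ThresholdResult]
    minimum_dose: float | None = None
    optimal_dose: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": [r.threshold for r in self.results],
                "label": [r.label for r in self.results],
                "odds_ratio": [r.odds_ratio for r in self.results],
                "ci_low": [r.ci_low for r in self.results],
                "ci_high": [r.ci_high for r in self.results],
                "n_high_risk": [r.n_high_risk for r in self.results],
                "n_low_risk": [r.n_low_risk for r in self.results],
                "converged": [r.converged for r in self.results],
                "significant": [r.significant for r in self.results],
            }
        )


def binarize_dose_at_threshold(
    dose_values: np.ndarray | pd.Series, threshold: float
) -> np.ndarray:
    """High-risk coding: 1 where dose < threshold (dose not met), else 0.

    Raises if the coding is degenerate (all respondents on one side).
    """
    v = np.asarray(dose_values, dtype=float)
    risk = (v < threshold).astype(int)
    if risk.all() or not risk.any():
        raise ValueError(
            f"threshold {threshold} is degenerate: all respondents are "
            f"{'high' if risk.all() else 'low'} risk"
        )
    return risk


def scan_thresholds(
    data: pd.DataFrame,
    grid: ThresholdGrid,
    adjusters: tuple[RiskFactor, ...] = (),
    outcome: str = "depression",
) -> DoseResponseCurve:
    """Fit the adjusted logistic model at every threshold of a grid.

    Degenerate or non-converged thresholds are recorded with NaN odds
    ratios and the scan continues.  Minimum and optimal doses are attached
    to the returned curve.
    """
    y = data[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    adj_cols = {a.name: a.apply(data).astype(float) for a in adjusters}
    dose = data[grid.column]
    results = []
    for i, thr in enumerate(grid.thresholds):
        label = grid.labels[i] if grid.labels else f"{thr:g}"
        try:
            risk = binarize_dose_at_threshold(dose, thr)
        except ValueError as exc:
            logger.warning("dose %s: %s", grid.dose, exc)
            results.append(
                ThresholdResult(thr, np.nan, np.nan, np.nan,
                                0, 0, converged=False, label=label)
            )
            continue
        X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
        for name, col in adj_cols.items():
            X[name] = col
        X["dose_risk"] = risk.astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
                beta = float(res.params["dose_risk"])
                se = float(res.bse["dose_risk"])
                ok = bool(res.converged) and np.isfinite(beta) and np.isfinite(se) \
                    and abs(beta) < 1e3
            except Exception as exc:  # non-convergence, singular design
                logger.warning("dose %s at %s: %s", grid.dose, thr, exc)
                ok = False
        if not ok:
            results.append(
                ThresholdResult(thr, np.nan, np.nan, np.nan,
                                int(risk.sum()), int((1 - risk).sum()),
                                converged=False, label=label)
            )
            continue
        results.append(
            ThresholdResult(
                threshold=thr,
                odds_ratio=float(np.exp(beta)),
                ci_low=float(np.exp(beta - _Z95 * se)),
                ci_high=float(np.exp(beta + _Z95 * se)),
                n_high_risk=int(risk.sum()),
                n_low_risk=int((1 - risk).sum()),
                converged=True,
                label=label,
            )
        )
    curve = DoseResponseCurve(dose=grid.dose, results=results)
    curve.minimum_dose = find_minimum_dose(curve)
    if curve.minimum_dose is not None:
        curve.optimal_dose = find_optimal_dose(curve)
    return curve


def find_minimum_dose(curve: DoseResponseCurve) -> float | None:
    """Smallest threshold whose CI lies strictly above OR = 1.

    Under the high-risk coding a protective dose shows OR > 1 for "dose not
    met", so the minimum dose is the first threshold with CI low > 1.
    Returns None when no threshold is significant.
    """
    if not curve.results:
        raise ValueError("empty dose-response curve")
    for r in curve.results:
        if r.converged and r.ci_low > 1.0:
            return r.threshold
    return None


def find_optimal_dose(
    curve: DoseResponseCurve, plateau_tol: float = 0.05
) -> float | None:
    """Plateau detection: smallest significant threshold not later exceeded.

    Returns the smallest significant threshold ``t`` such that no later
    significant odds ratio exceeds ``OR(t) * (1 + plateau_tol)``.  If the
    only such threshold is the final significant one and the curve is still
    gaining there (its OR exceeds the previous significant OR by more than
    the tolerance), the optimum has not been reached and None is returned.
    """
    sig = [r for r in curve.results if r.converged and r.ci_low > 1.0]
    if not sig:
        return None
    for i, r in enumerate(sig):
        later_max = max((s.odds_ratio for s in sig[i + 1:]), default=-np.inf)
        if later_max <= r.odds_ratio * (1.0 + plateau_tol):
            if i == len(sig) - 1 and i > 0:
                prev = sig[i - 1]
                if r.odds_ratio > prev.odds_ratio * (1.0 + plateau_tol):
                    return None  # still rising at the last threshold
            return r.threshold
    return None


def default_grids() -> dict[str, ThresholdGrid]:
    """Standard threshold ladders for the three doses.

    Frequency: at least once / 2–3 / 4–5 / 6–7 visits per week (encoded
    mid-points).  Duration: the survey time-band boundaries in minutes.
    Intensity: 10–35% neighbourhood vegetation cover in 5-point steps.
    """
    return {
        "frequency": ThresholdGrid(
            dose="frequency",
            column="freq_visits_per_week",
            thresholds=(1.0, 2.5, 4.5, 6.5),
            labels=(">=once/wk", ">=2-3/wk", ">=4-5/wk", ">=6-7/wk"),
        ),
        "duration": ThresholdGrid(
            dose="duration",
            column="duration_min_per_week",
            thresholds=(30.0, 60.0, 180.0, 300.0, 420.0, 540.0),
            labels=(">=30min", ">=1h", ">=3h", ">=5h", ">=7h", ">=9h"),
        ),
        "intensity": ThresholdGrid(
            dose="intensity",
            column="vegetation_cover_pct",
            thresholds=(10.0, 15.0, 20.0, 25.0, 30.0, 35.0),
            labels=(">=10%", ">=15%", ">=20%", ">=25%", ">=30%", ">=35%"),
        ),
    }


def default_risk_factors() -> tuple[RiskFactor, ...]:
    """Default adjuster set: the binary socio-demographic risk recodings
    (younger age, below-average self-rated health, less time outdoors)."""
    return (
        RiskFactor("age_under_46", "age", 46.0, "below",
                   note="higher risk < 46 years"),
        RiskFactor("health_below_average", "self_health", 3.0, "below",
                   note="higher risk < average self-rated health"),
        RiskFactor("less_time_outdoors", "time_outdoors", "less", "equals",
                   note="higher risk when relatively less time outdoors"),
    )
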