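"""Average attributable fractions by sequential risk-factor removal.

A logistic model of depression on binary risk factors (plus any fixed
adjusters) is fitted once to the observed data.  "Removing" a set S of risk
factors means setting those columns to 0 (low risk) for every respondent
and summing the predicted probabilities under the *fixed* fitted
coefficients: E(S) is the expected case count had the factors in S been
absent.  With an intercept in the model, E(∅) equals the observed case
count exactly (the logistic score equations).

Removing the factors one at a time along an ordering credits factor
``ordering[j]`` with the incremental drop (E(S_{j-1}) − E(S_j))/C_obs; the
average attributable fraction (AAF) of a factor is the mean of its
increment over all K! orderings.  This is exactly a Shapley-value
decomposition of the total attributable fraction, so the production path
evaluates the subset-weighted Shapley sum

    AAF_k = Σ_{S ⊆ F∖{k}} |S|!(K−|S|−1)!/K! · (E(S) − E(S∪{k}))/C_obs

over 2^K memoised subset evaluations; exhaustive permutation enumeration is
retained as an oracle for small K.  Per-factor AAFs sum to the total
attributable fraction (E(∅) − E(all))/C_obs by telescoping.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RiskModel",
    "AAFRow",
    "AAFTable",
    "fit_risk_model",
    "expected_cases",
    "sequential_af",
    "average_af_permutation",
    "average_af_shapley",
    "aaf_table",
    "aaf_bootstrap_ci",
]

logger = logging.getLogger(__name__)

_Z95 = 1.959964
PERMUTATION_CAP = 8  # K! enumeration beyond this is redirected to Shapley


@dataclass
class RiskModel:
    """A fitted logistic risk model over binary removable risk factors."""

    factor_names: tuple[str, ...]
    params: pd.Series  # Intercept, factors, then fixed adjusters
    cov: pd.DataFrame
    design: pd.DataFrame  # one row per respondent, columns match params
    observed_cases: float
    converged: bool = True

    def __post_init__(self) -> None:
        for name in self.factor_names:
            col = self.design[name].to_numpy()
            if not set(np.unique(col)) <= {0.0, 1.0}:
                raise ValueError(f"risk factor {name!r} is not binary 0/1")

    def odds_ratios(self) -> pd.DataFrame:
        """Per-factor odds ratio with Wald 95% CI."""
        rows = []
        for name in self.factor_names:
            beta = float(self.params[name])
            se = float(np.sqrt(self.cov.loc[name, name]))
            rows.append(
                {
                    "factor": name,
                    "odds_ratio": math.exp(beta),
                    "ci_low": math.exp(beta - _Z95 * se),
                    "ci_high": math.exp(beta + _Z95 * se),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class AAFRow:
    factor: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    aaf: float


@dataclass
class AAFTable:
    rows: list[AAFRow]
    total_af: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([row.__dict__ for row in self.rows])
        total = pd.DataFrame(
            [{"factor": "TOTAL", "odds_ratio": np.nan, "ci_low": np.nan,
              "ci_high": np.nan, "aaf": self.total_af}]
        )
        return pd.concat([df, total], ignore_index=True)

    def aaf_of(self, factor: str) -> float:
        for row in self.rows:
            if row.factor == factor:
                return row.aaf
        raise KeyError(factor)


def fit_risk_model(
    data: pd.DataFrame,
    factor_columns: tuple[str, ...],
    outcome: str = "depression",
    adjuster_columns: tuple[str, ...] = (),
) -> RiskModel:
    """Fit the logistic risk model once on the observed data.

    ``factor_columns`` are binary 0/1 removable risk factors; adjusters stay
    at their observed values in every removal scenario.
    """
    cols = [outcome, *factor_columns, *adjuster_columns]
    cc = data.loc[:, cols].dropna()
    y = cc[outcome].to_numpy(dtype=float)
    X = pd.DataFrame({"Intercept": np.ones(len(cc))}, index=cc.index)
    for c in (*factor_columns, *adjuster_columns):
        X[c] = cc[c].astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    params = pd.Series(np.asarray(res.params, dtype=float), index=X.columns)
    cov = pd.DataFrame(np.asarray(res.cov_params(), dtype=float),
                       index=X.columns, columns=X.columns)
    converged = bool(res.converged) and np.all(np.isfinite(params)) \
        and float(np.max(np.abs(params))) < 1e3
    model = RiskModel(
        factor_names=tuple(factor_columns),
        params=params,
        cov=cov,
        design=X,
        observed_cases=float(y.sum()),
        converged=converged,
    )
    # MLE calibration identity: with an intercept, sum of fitted
    # probabilities equals the observed case count.
    calib = expected_cases(model, frozenset())
    if converged and abs(calib - model.observed_cases) > 1e-6 * max(1.0, model.observed_cases):
        raise AssertionError(
            f"logistic calibration identity violated: E(empty)={calib}, "
            f"observed={model.observed_cases}"
        )
    return model


def expected_cases(model: RiskModel, removed: frozenset[str] | set[str]) -> float:
    """Expected case count with the factors in ``removed`` set to low risk.

    Coefficients are not refit; the fitted model is evaluated on the
    counterfactual design.
    """
    if not model.converged:
        raise ValueError("risk model did not converge; expected cases undefined")
    unknown = set(removed) - set(model.factor_names)
    if unknown:
        raise ValueError(f"unknown risk factors: {sorted(unknown)}")
    X = model.design.to_numpy(dtype=float).copy()
    cols = list(model.design.columns)
    for name in removed:
        X[:, cols.index(name)] = 0.0
    eta = X @ model.params.to_numpy(dtype=float)
    return float(np.sum(1.0 / (1.0 + np.exp(-eta))))


def sequential_af(
    model: RiskModel, ordering: tuple[str, ...]
) -> dict[str, float]:
    """Per-factor incremental attributable fractions along one ordering."""
    if sorted(ordering) != sorted(model.factor_names):
        raise ValueError(
            f"ordering {ordering} is not a permutation of {model.factor_names}"
        )
    out: dict[str, float] = {}
    removed: frozenset[str] = frozenset()
    e_prev = expected_cases(model, removed)
    for name in ordering:
        removed = removed | {name}
        e_next = expected_cases(model, removed)
        out[name] = (e_prev - e_next) / model.observed_cases
        e_prev = e_next
    return out


def average_af_permutation(model: RiskModel) -> AAFTable:
    """AAFs by exhaustive K! permutation enumeration (oracle path)."""
    K = len(model.factor_names)
    if K > PERMUTATION_CAP:
        raise ValueError(
            f"{K} factors exceed the K! enumeration cap ({PERMUTATION_CAP}); "
            "use average_af_shapley"
        )
    sums = {name: 0.0 for name in model.factor_names}
    n_perm = 0
    cache: dict[frozenset[str], float] = {}

    def e_of(s: frozenset[str]) -> float:
        if s not in cache:
            cache[s] = expected_cases(model, s)
        return cache[s]

    for perm in itertools.permutations(model.factor_names):
        removed: frozenset[str] = frozenset()
        e_prev = e_of(removed)
        for name in perm:
            removed = removed | {name}
            e_next = e_of(removed)
            sums[name] += (e_prev - e_next) / model.observed_cases
            e_prev = e_next
        n_perm += 1
    aafs = {name: s / n_perm for name, s in sums.items()}
    return _assemble_table(model, aafs)


def average_af_shapley(model: RiskModel) -> AAFTable:
    """AAFs by the subset-weighted Shapley sum (production path).

    Memoises E(S) over the 2^K subsets; algebraically identical to the
    permutation average.
    """
    K = len(model.factor_names)
    if K > 20:
        raise ValueError(f"{K} factors exceed the 2^K subset enumeration limit")
    names = model.factor_names
    cache: dict[frozenset[str], float] = {}

    def e_of(s: frozenset[str]) -> float:
        if s not in cache:
            cache[s] = expected_cases(model, s)
        return cache[s]

    fact = [math.factorial(i) for i in range(K + 1)]
    aafs = {}
    others = {k: tuple(n for n in names if n != k) for k in names}
    for k in names:
        total = 0.0
        rest = others[k]
        for r in range(len(rest) + 1):
            w = fact[r] * fact[K - r - 1] / fact[K]
            for combo in itertools.combinations(rest, r):
                s = frozenset(combo)
                total += w * (e_of(s) - e_of(s | {k}))
        aafs[k] = total / model.observed_cases
    return _assemble_table(model, aafs)


def _assemble_table(model: RiskModel, aafs: dict[str, float]) -> AAFTable:
    ors = model.odds_ratios().set_index("factor")
    rows = [
        AAFRow(
            factor=name,
            odds_ratio=float(ors.loc[name, "odds_ratio"]),
            ci_low=float(ors.loc[name, "ci_low"]),
            ci_high=float(ors.loc[name, "ci_high"]),
            aaf=aafs[name],
        )
        for name in model.factor_names
    ]
    total = (
        expected_cases(model, frozenset())
        - expected_cases(model, frozenset(model.factor_names))
    ) / model.observed_cases
    return AAFTable(rows=rows, total_af=total)


def aaf_bootstrap_ci(
    data: pd.DataFrame,
    factor_columns: tuple[str, ...],
    outcome: str = "depression",
    adjuster_columns: tuple[str, ...] = (),
    B: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Respondent-level nonparametric bootstrap percentile CIs for the AAFs.

    Each replicate resamples rows with replacement, refits the risk model
    and recomputes the Shapley AAFs; replicates whose fit diverges are
    dropped and counted.
    """
    if B < 100:
        raise ValueError(f"need B >= 100 bootstrap replicates, got {B}")
    rng = np.random.default_rng(seed)
    n = len(data)
    draws: dict[str, list[float]] = {name: [] for name in factor_columns}
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = data.iloc[idx].reset_index(drop=True)
        try:
            model = fit_risk_model(boot, factor_columns, outcome, adjuster_columns)
            tab = average_af_shapley(model)
        except (ValueError, AssertionError):
            n_failed += 1
            continue
        for row in tab.rows:
            draws[row.factor].append(row.aaf)
    if n_failed:
        logger.warning("aaf_bootstrap_ci: %d of %d replicates failed", n_failed, B)
    rows = []
    for name in factor_columns:
        arr = np.array(draws[name])
        rows.append(
            {
                "factor": name,
                "aaf_ci_low": float(np.quantile(arr, alpha / 2)),
                "aaf_ci_high": float(np.quantile(arr, 1 - alpha / 2)),
                "n_replicates": len(arr),
                "n_failed": n_failed,
            }
        )
    return pd.DataFrame(rows)
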