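"""All-subsets regression with AICc ranking and full model averaging.

For each health outcome, four candidate-predictor sets are analysed:
(i) socio-demographic covariates only, then (ii) plus visit frequency,
(iii) plus garden-time duration, (iv) plus vegetation intensity.  Frequency
and duration never co-occur in one set because they are strongly rank
correlated.  Within a set, every subset of the candidate term blocks is
fitted (intercept always included; categorical dummy blocks enter or leave
as a unit), models are ranked by AICc, the models with ΔAICc below a cutoff
(default 6) are retained, and Akaike weights over the retained set drive
full ("shrinkage") model averaging: a term absent from a model contributes a
zero coefficient, and the unconditional standard error combines each model's
sampling variance with the between-model spread of the coefficient:

    SE_j = sqrt( Σ_i w_i [ var_i(β_j) + (β_ij − β̄_j)² ] ).

Families: binomial logit (depression), cumulative-link logit
(proportional-odds; 5-level self-rated health), Gaussian (social cohesion,
nature relatedness) and Poisson log (weekly exercise days).  Gaussian
log-likelihoods use the ML error variance, which also counts as a parameter
in k so AICc is comparable across families.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit
from scipy.stats import norm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .terms import TermBlock, default_blocks, design_matrix

__all__ = [
    "ModelSpec",
    "FittedModel",
    "CandidateSet",
    "AveragedEstimate",
    "build_model_sets",
    "fit_glm",
    "fit_cumulative_link",
    "fit_subset",
    "all_subsets",
    "compute_aicc",
    "rank_and_retain",
    "model_average",
    "mcfadden_r2",
    "averaged_table",
    "OUTCOME_FAMILIES",
]

logger = logging.getLogger(__name__)

#: Response family for each of the five health outcomes.
OUTCOME_FAMILIES = {
    "depression": "binomial",
    "self_health": "ordinal",
    "social_cohesion": "gaussian",
    "exercise_days": "poisson",
    "nature_relatedness": "gaussian",
}

#: Outcomes that may appear as predictors of the other outcomes, with the
#: term-block name they use.
_OUTCOME_PREDICTOR_BLOCKS = {
    "depression": None,  # binary depression is not used as a predictor
    "self_health": "self_health",
    "social_cohesion": "social_cohesion",
    "exercise_days": "exercise_days",
    "nature_relatedness": "nature_relatedness",
}

_DIVERGENCE_BOUND = 1e3  # |beta| beyond this flags separation/divergence
_SE_BOUND = 1e2  # a Wald SE beyond this flags a flat/separated likelihood


@dataclass(frozen=True)
class ModelSpec:
    """One response and its candidate term blocks for one model set."""

    response: str
    family: str
    candidate_blocks: tuple[TermBlock, ...]
    label: str = ""

    def __post_init__(self) -> None:
        for b in self.candidate_blocks:
            if b.source == self.response:
                raise ValueError(
                    f"{self.response!r} cannot be a predictor of itself"
                )
        if self.family not in ("binomial", "ordinal", "gaussian", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class FittedModel:
    """One converged (or flagged) regression fit."""

    response: str
    family: str
    blocks: tuple[TermBlock, ...]
    params: "pd.Series"
    cov: "pd.DataFrame"
    llf: float
    n: int
    k: int
    aicc: float
    converged: bool
    cutpoints: tuple[float, ...] = ()

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.blocks)


@dataclass
class CandidateSet:
    """All fitted subsets for one spec, with the ΔAICc-retained subset."""

    spec: ModelSpec
    models: list[FittedModel]
    retained: list[FittedModel]
    delta: np.ndarray  # ΔAICc of retained models
    weights: np.ndarray  # Akaike weights over retained models
    n_dropped_rows: int = 0

    @property
    def best(self) -> FittedModel:
        return self.retained[int(np.argmin(self.delta))]


@dataclass(frozen=True)
class AveragedEstimate:
    """Model-averaged coefficient for one design column."""

    term: str
    coefficient: float
    unconditional_se: float
    z: float
    p_value: float
    stars: str


def build_model_sets(
    covariate_block_names: tuple[str, ...] = (
        "age", "gender", "children", "language", "workdays", "income",
        "education", "time_outdoors",
    ),
    include_outcome_predictors: bool = True,
    responses: tuple[str, ...] = tuple(OUTCOME_FAMILIES),
) -> dict[str, dict[str, ModelSpec]]:
    """The four candidate sets (i)–(iv) for each response.

    Other health outcomes enter as candidate predictors except for the
    response itself (and binary depression, which is never a predictor).
    Returns ``{response: {"i": spec, "ii": spec, "iii": spec, "iv": spec}}``.
    """
    registry = default_blocks()
    specs: dict[str, dict[str, ModelSpec]] = {}
    for response in responses:
        family = OUTCOME_FAMILIES[response]
        base = [registry[name] for name in covariate_block_names]
        if include_outcome_predictors:
            for outcome, block_name in _OUTCOME_PREDICTOR_BLOCKS.items():
                if block_name is None or outcome == response:
                    continue
                base.append(registry[block_name])
        sets = {
            "i": tuple(base),
            "ii": tuple(base) + (registry["frequency"],),
            "iii": tuple(base) + (registry["duration"],),
            "iv": tuple(base) + (registry["intensity"],),
        }
        specs[response] = {
            lbl: ModelSpec(response, family, blocks, label=lbl)
            for lbl, blocks in sets.items()
        }
    return specs


def compute_aicc(lnL: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _complete_cases(data: pd.DataFrame, spec_response: str,
                    blocks: tuple[TermBlock, ...]) -> tuple[pd.DataFrame, int]:
    cols = {spec_response}
    for b in blocks:
        cols.add(b.source)
    sub = data.loc[:, sorted(cols)].dropna()
    return data.loc[sub.index], len(data) - len(sub)


def fit_glm(
    response: str,
    family: str,
    blocks: tuple[TermBlock, ...],
    data: pd.DataFrame,
) -> FittedModel:
    """Maximum-likelihood GLM/OLS fit for one term subset.

    ``k`` counts the intercept and, for the Gaussian family, the ML error
    variance; the Gaussian log-likelihood is the normal likelihood at the
    ML variance (RSS/n).
    """
    data, _ = _complete_cases(data, response, blocks)
    X = design_matrix(data, blocks, add_intercept=True)
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(
            f"design matrix for {response} ~ {[b.name for b in blocks]} "
            "is rank deficient"
        )
    extra_k = 0
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "gaussian":
            res = sm.OLS(y, X).fit()
            llf = float(res.llf)  # normal likelihood at ML variance RSS/n
            extra_k = 1
        elif family == "binomial":
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            llf = float(res.llf)
            converged = bool(res.converged)
        elif family == "poisson":
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=200)
            llf = float(res.llf)
            converged = bool(res.converged)
        else:
            raise ValueError(f"fit_glm does not handle family {family!r}")
    params = pd.Series(np.asarray(res.params, dtype=float), index=X.columns)
    cov = pd.DataFrame(
        np.asarray(res.cov_params(), dtype=float), index=X.columns, columns=X.columns
    )
    if (not np.all(np.isfinite(params))
            or not np.all(np.isfinite(cov.to_numpy()))
            or np.max(np.abs(params)) > _DIVERGENCE_BOUND
            or np.max(np.diag(cov.to_numpy())) > _SE_BOUND**2):
        converged = False
        logger.warning(
            "fit for %s ~ %s diverged (possible perfect separation)",
            response, [b.name for b in blocks],
        )
    k = X.shape[1] + extra_k
    return FittedModel(
        response=response, family=family, blocks=blocks, params=params,
        cov=cov, llf=llf, n=n, k=k, aicc=compute_aicc(llf, k, n),
        converged=converged,
    )


def _intercept_only_ordinal(y: np.ndarray) -> tuple[tuple[float, ...], float]:
    """Closed-form cutpoints and lnL for the intercept-only ordinal model."""
    levels = np.sort(np.unique(y))
    counts = np.array([(y == lv).sum() for lv in levels], dtype=float)
    p = counts / counts.sum()
    theta = tuple(float(logit(c)) for c in np.cumsum(p)[:-1])
    llf = float(np.sum(counts * np.log(p)))
    return theta, llf


def fit_cumulative_link(
    response: str,
    blocks: tuple[TermBlock, ...],
    data: pd.DataFrame,
) -> FittedModel:
    """Proportional-odds (cumulative logit) fit: P(Y <= k) = logit⁻¹(θ_k − xβ).

    Positive coefficients shift mass to higher categories.  ``k`` counts the
    slope coefficients plus the ordered cutpoints.
    """
    data, _ = _complete_cases(data, response, blocks)
    y = data[response].to_numpy()
    levels = np.sort(np.unique(y))
    if len(levels) < 2:
        raise ValueError(f"ordinal response {response!r} has a single level")
    n = len(y)
    if not blocks:
        theta, llf = _intercept_only_ordinal(y)
        k = len(theta)
        params = pd.Series(dtype=float)
        cov = pd.DataFrame(dtype=float)
        return FittedModel(
            response=response, family="ordinal", blocks=(), params=params,
            cov=cov, llf=llf, n=n, k=k, aicc=compute_aicc(llf, k, n),
            converged=True, cutpoints=theta,
        )
    X = design_matrix(data, blocks, add_intercept=False)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(
            f"design matrix for {response} ~ {[b.name for b in blocks]} "
            "is rank deficient"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(
            pd.Categorical(y, categories=levels, ordered=True), X, distr="logit"
        )
        res = model.fit(method="bfgs", maxiter=500, gtol=1e-10, disp=False)
    n_beta = X.shape[1]
    beta = np.asarray(res.params[:n_beta], dtype=float)
    theta = tuple(
        float(t) for t in model.transform_threshold_params(res.params)[1:-1]
    )
    params = pd.Series(beta, index=X.columns)
    cov_full = np.asarray(res.cov_params(), dtype=float)
    cov = pd.DataFrame(cov_full[:n_beta, :n_beta], index=X.columns, columns=X.columns)
    # BFGS can stop with a gradient above a very strict gtol while being at
    # the optimum for practical purposes; judge convergence from the score
    # norm and parameter magnitudes rather than the optimizer flag.
    score = np.asarray(model.score(res.params), dtype=float)
    converged = bool(np.all(np.isfinite(score)) and np.max(np.abs(score)) < 1e-2)
    if (not np.all(np.isfinite(beta))
            or not np.all(np.isfinite(cov.to_numpy()))
            or (len(beta) and np.max(np.abs(beta)) > _DIVERGENCE_BOUND)):
        converged = False
    k = n_beta + len(theta)
    return FittedModel(
        response=response, family="ordinal", blocks=tuple(blocks), params=params,
        cov=cov, llf=float(res.llf), n=n, k=k,
        aicc=compute_aicc(float(res.llf), k, n), converged=converged,
        cutpoints=theta,
    )


def fit_subset(
    spec: ModelSpec, blocks: tuple[TermBlock, ...], data: pd.DataFrame
) -> FittedModel:
    """Fit one subset of a spec's candidate blocks in the spec's family."""
    if spec.family == "ordinal":
        return fit_cumulative_link(spec.response, blocks, data)
    return fit_glm(spec.response, spec.family, blocks, data)


def all_subsets(
    spec: ModelSpec, data: pd.DataFrame, delta_max: float = 6.0
) -> CandidateSet:
    """Fit every subset of the candidate blocks and retain ΔAICc < delta_max.

    Rows incomplete for *any* candidate variable are dropped once for the
    whole set, so every subset model is fitted to the same rows and their
    AICc values are comparable.
    """
    data_cc, n_dropped = _complete_cases(data, spec.response, spec.candidate_blocks)
    if n_dropped:
        logger.info(
            "%s (%s): dropped %d incomplete rows of %d",
            spec.response, spec.label, n_dropped, len(data),
        )
    models = []
    for r in range(len(spec.candidate_blocks) + 1):
        for combo in itertools.combinations(spec.candidate_blocks, r):
            try:
                fm = fit_subset(spec, combo, data_cc)
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning(
                    "skipping %s ~ %s: %s",
                    spec.response, [b.name for b in combo], exc,
                )
                continue
            if fm.converged:
                models.append(fm)
            else:
                logger.warning(
                    "excluding non-converged fit %s ~ %s",
                    spec.response, [b.name for b in combo],
                )
    cs = rank_and_retain(models, delta_max=delta_max)
    cs.spec = spec
    cs.n_dropped_rows = n_dropped
    return cs


def rank_and_retain(
    models: list[FittedModel], delta_max: float = 6.0
) -> CandidateSet:
    """Rank models by AICc, keep ΔAICc < delta_max, compute Akaike weights."""
    if not models:
        raise ValueError("no converged models to rank")
    aiccs = np.array([m.aicc for m in models])
    delta_all = aiccs - aiccs.min()
    keep = delta_all < delta_max
    retained = [m for m, k in zip(models, keep) if k]
    delta = delta_all[keep]
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    order = np.argsort(delta, kind="stable")
    retained = [retained[i] for i in order]
    spec = ModelSpec(models[0].response, models[0].family, ())
    return CandidateSet(
        spec=spec, models=list(models), retained=retained,
        delta=delta[order], weights=w[order],
    )


def model_average(cand: CandidateSet) -> list[AveragedEstimate]:
    """Full model averaging with unconditional standard errors.

    A term absent from a retained model contributes coefficient 0 with
    variance 0.  The intercept is averaged like any other term.  Ordinal
    cutpoints are not averaged (they are nuisance thresholds).
    """
    if not cand.retained:
        raise ValueError("empty retained model set")
    columns: list[str] = []
    for m in cand.retained:
        for c in m.params.index:
            if c not in columns:
                columns.append(c)
    w = cand.weights
    out = []
    for col in columns:
        betas = np.array(
            [m.params.get(col, 0.0) for m in cand.retained], dtype=float
        )
        variances = np.array(
            [
                float(m.cov.loc[col, col]) if col in m.params.index else 0.0
                for m in cand.retained
            ]
        )
        beta_bar = float(w @ betas)
        se = float(np.sqrt(w @ (variances + (betas - beta_bar) ** 2)))
        if se > 0:
            z = beta_bar / se
            p = 2.0 * norm.sf(abs(z))
        else:
            z, p = math.inf if beta_bar else 0.0, 0.0 if beta_bar else 1.0
        out.append(
            AveragedEstimate(
                term=col, coefficient=beta_bar, unconditional_se=se,
                z=z, p_value=p, stars=_stars(p),
            )
        )
    return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def mcfadden_r2(llf: float, null_llf: float) -> float:
    """McFadden pseudo-R²: 1 − lnL(model)/lnL(intercept-only)."""
    if null_llf == 0:
        raise ValueError("null log-likelihood is zero; pseudo-R² undefined")
    return 1.0 - llf / null_llf


def best_model_pseudo_r2(cand: CandidateSet, data: pd.DataFrame) -> float | None:
    """McFadden pseudo-R² of the best retained model (None for ordinal)."""
    if cand.spec.family == "ordinal":
        return None
    best = cand.best
    null = fit_glm(best.response, best.family, (), data)
    return mcfadden_r2(best.llf, null.llf)


def averaged_table(
    cand: CandidateSet, data: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Results-table frame: term, averaged coefficient, SE, stars, pseudo-R²."""
    rows = [
        {
            "term": est.term,
            "coefficient": est.coefficient,
            "se": est.unconditional_se,
            "z": est.z,
            "p_value": est.p_value,
            "stars": est.stars,
        }
        for est in model_average(cand)
    ]
    df = pd.DataFrame(rows)
    if data is not None:
        r2 = best_model_pseudo_r2(cand, data)
        df["best_model_pseudo_r2"] = np.nan if r2 is None else r2
    return df


def ranking_table(cand: CandidateSet) -> pd.DataFrame:
    """Model-ranking frame: terms, k, lnL, AICc, ΔAICc, Akaike weight."""
    return pd.DataFrame(
        {
            "terms": ["+".join(m.term_names) or "(intercept)" for m in cand.retained],
            "k": [m.k for m in cand.retained],
            "lnL": [m.llf for m in cand.retained],
            "AICc": [m.aicc for m in cand.retained],
            "delta_AICc": cand.delta,
            "weight": cand.weights,
        }
    )
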