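# Methods

This note documents the statistical models implemented in `naturedose`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Scales and dose encodings

* **Depression** is scored from the 7 DASS-21 depression items (0–3 each)
  as twice the item sum (0–42), dichotomised at a configurable cutoff with
  default 10 — the conventional boundary between the "normal" (0–9) and
  "mild" (10–13) bands on the doubled scale.  The cutoff is a named
  constant (`scales.DASS_MILD_CUTOFF`), not hard-coded, because published
  severity bandings vary.
* **Social cohesion** is the sum of three subscale means (items 0–4),
  giving 0–12.  **Nature relatedness** reflects reverse-keyed items about
  the scale midpoint before averaging; the item scale (default 1–5) is a
  parameter.
* **Dose encodings** use category mid-points: frequency
  `never→0, <once→0.5, once→1, 2–3→2.5, 4–5→4.5, 6–7→6.5` visits/week;
  duration band mid-points in minutes with the open top band ("9 h or
  more") valued at 570 min = 9 h plus half the preceding band's width.
  Both tables are configurable so other survey dialects can be remapped;
  downstream regression coefficients are per encoded unit, so the open-band
  value is a sensitivity-analysis knob rather than a fixed truth.
* Missing items are not imputed; a record missing any input to a score
  gets a missing score and is removed by complete-case filtering in the
  modelling stages (dropped counts are logged and recorded in the run
  manifest).

## Vegetation intensity

A pixel is *tall vegetation* iff NDVI > 0.2 and height > 0.7 m — both
strict inequalities.  Cover within a buffer is the percentage of valid
(non-nodata) pixels whose **centres** lie within the radius
(centre-inclusion, the common zonal-statistics default; area-weighted
inclusion is out of scope).  Coordinates are assumed to be in a projected
metric CRS; no reprojection is performed.  The production path prefilters
pixels with a bounding box but is verified against an all-pixels Euclidean
distance oracle, with which it agrees exactly.  Raster I/O uses the ESRI
ASCII grid format, which is plain text and lossless for our scenes.

Whether "neighbourhood vegetation cover" should count all vegetation
(NDVI-only) or tall vegetation only is ambiguous in general use; the
classifier exposes both (an NDVI-only mask is obtained by setting the
height threshold below ground).

## All-subsets AICc model averaging

Families: binomial logit (depression), cumulative-link logit
(proportional odds, `P(Y≤k) = logit⁻¹(θ_k − xβ)`) for 5-level self-rated
health, Gaussian for the continuous scales, Poisson log for exercise days.
GLM/OLS fits are by IRLS/least squares (statsmodels); the ordinal model is
maximised by BFGS from statsmodels' cumulative-frequency start, with the
intercept-only ordinal fit done in closed form (θ_k = logit of cumulative
frequencies).  Convergence is judged by the score norm and finite,
bounded coefficients/SEs; perfectly separated fits blow up the Wald
covariance and are flagged and excluded from the candidate set with a
logged warning.

Parameter count *k* includes the intercept, all slope coefficients, the
ordinal cutpoints, and (Gaussian) the ML error variance, so AICc is
comparable across families.  Within one candidate set, all subset models
are fitted to the same complete-case rows so their likelihoods are
comparable.

Averaging is *full* (shrinkage) averaging: a term absent from a retained
model contributes β = 0 with variance 0, and the unconditional SE is the
revised weighted form `sqrt(Σ w_i [var_i + (β_i − β̄)²])` (not the older
squared-sum form).  Akaike weights are renormalised within the ΔAICc < 6
retained set; a `delta_max=inf` call averages over all models instead.
Categorical covariates enter as treatment-coded dummy blocks included or
excluded as a unit.  Continuous predictors stay on their encoded scales
(no standardisation), so coefficients read as "per year of age", "per
visit/week", "per percentage point of cover".

"Children in home" and "work days per week" are treated as continuous
counts; income as a continuous band index.  Binary depression is not
offered as a predictor of the other outcomes; the other outcomes are
candidate predictors wherever they are not the response.

## Threshold-scan dose response

Only the binary outcome (depression) supports a threshold scan.  At each
grid threshold t the dose is recoded as 1 = "dose not met" (dose < t); a
logistic model of depression on this indicator plus binary adjusters
(default: age < 46, self-rated health below average, relatively less time
outdoors — all three adjusted simultaneously at every threshold) yields
OR = exp(β) with Wald 95% CI `exp(β ± 1.959964·SE)`.  No multiplicity
correction is applied across thresholds (matching conventional reporting);
degenerate thresholds (all respondents on one side) and non-converged fits
are recorded and skipped without aborting the scan.

* **Minimum dose**: smallest threshold whose CI lies strictly above 1.
  A CI touching 1.0 exactly does not count.
* **Optimal dose**: "optimum" is not a standard estimand, so it is
  operationalised as a plateau rule — the smallest significant threshold t
  such that no later significant OR exceeds OR(t) by more than a relative
  tolerance (default 5%).  If that candidate is the last significant
  threshold and the curve is still gaining there (its OR exceeds the
  previous significant OR by more than the tolerance), the optimum is
  reported as not reached (`None`) — the expected behaviour when the
  scanned range ends before the response levels off.

Default grids: frequency {1, 2.5, 4.5, 6.5} visits/week (the encoded
category values from "once" upward); duration at the survey band
boundaries {30, 60, 180, 300, 420, 540} minutes/week; intensity
{10, 15, 20, 25, 30, 35}% cover.

## Average attributable fractions

The logistic risk model (intercept + binary risk factors + optional fixed
adjusters) is fitted **once** on observed data; counterfactual "removal"
of a factor set S evaluates the same coefficients on a design with those
columns zeroed.  Refitting under counterfactual exposure is deliberately
not done — the removal question is about the fitted population risk
surface, and refitting would change the estimand.  Because the model has
an intercept, the score equations force E(∅) = observed cases; this
identity is asserted on every fit (tolerance 1e-6 relative).

The average over all K! removal orders equals the Shapley value with
subset weights |S|!(K−|S|−1)!/K!; the production path enumerates the 2^K
subsets with memoised E(S), and the K! permutation enumeration (capped at
K = 8) is retained purely as a verification oracle.  Negative AAFs
(protective "risk" factors) are reported, not clipped.  The six default
factors are age < 46 years, self-rated health below average, relatively
less time outdoors, and the three minimum-dose-not-met indicators
(frequency < once/week, duration < 5 h/week, intensity < 15% cover);
all six are removed jointly in a single decomposition.  AAF uncertainty is
available through a respondent-level nonparametric bootstrap (percentile
intervals; failed replicates are dropped and counted) — an exact
delta-method variance is out of scope.

## Synthetic survey generator

The generator emulates the *structure* of a ~1000-adult lifestyle survey;
every generative parameter is recorded in the table's provenance.

* **Dose correlation.** Frequency and duration categories come from a
  Gaussian copula.  The joint cell probabilities of the discretised pair
  are computed analytically from bivariate-normal rectangle probabilities;
  the logical constraint "never visits ⇒ no garden time" is imposed on
  the joint; and the copula correlation is found by monotone root-finding
  so the *population* Spearman correlation (midrank grades) of the
  constrained pair equals the target, default 0.67.  The constraint
  slightly enlarges the realised "no time" marginal relative to the
  configured one; the configured marginals are otherwise honoured.
* **Intensity** is Gaussian (mean 24%, SD 9.1%) clipped to [0, 100].
* **Outcomes.** Depression is Bernoulli(logit⁻¹(η)) with η built from
  design-matrix coefficients and optional step-shaped dose effects
  (η gains a constant where dose ≥ threshold) for dose-response
  experiments.  Ordinal health follows a proportional-odds model at four
  strictly increasing cutpoints; exercise days are Poisson capped at 7
  (a 7-day week; excess mass goes to 7); the continuous scales are
  Gaussian, clipped to their instrument ranges.
* **Seeding.** One global integer seed feeds named substreams (seed ⊕
  CRC32 of the variable name), so adding a variable never perturbs the
  draws of existing ones; identical config + seed gives byte-identical
  CSV output.
* **Defaults are plausible, not survey-reported.**  The marginal category
  probabilities of doses and covariates, and the default outcome
  coefficients (e.g. depression: intercept 1.6, −0.023/year of age, −0.15
  per visit/week, −0.02 per % cover, giving ≈30% prevalence) are set once
  as realistic values for a UK adult panel; no published marginal tables
  exist for them.  In the default generative model each outcome depends
  only on covariates and doses (no outcome-on-outcome effects), which
  keeps generation acyclic; cross-outcome predictors in the fitted models
  are therefore null under the default truth.

**What passing tests show — and don't.**  The generator reproduces the
variable set, dose dependence structure and outcome families of a real
survey, so tests demonstrate correctness of the *estimators* (parameter
recovery, interval coverage, change-point detection, decomposition
identities).  It does not emulate item-level psychometrics, missing-data
patterns, response biases, spatial autocorrelation of vegetation, or
postcode geography, so passing tests say nothing about those aspects of
real data.

## Numerical choices and problem sizes

* Wald intervals use z = 1.959964 throughout; stars at 0.05/0.01/0.001.
* Copula calibration: Brent root-finding on [−0.999, 0.999], xtol 1e-6,
  with an explicit error when the target rank correlation is outside the
  achievable range of the discretised margins.
* Ordinal BFGS: gtol 1e-10, convergence accepted when max |score| < 1e-2.
* Divergence flags: |β| > 1e3 or Wald SE > 100.
* Test and acceptance problem sizes were chosen as the smallest that make
  the statistical assertions stable: interval coverage pools 50 surveys of
  n = 5000 (band 88–100% around the nominal 95%); change-point detection
  uses 100 surveys of n = 1000; the null calibration pools 200 surveys of
  n = 500 (rate asserted within 0.05 ± 0.025); AAF identities use exact
  tolerances (1e-12/1e-10) since they are algebraic.
* The pipeline's default candidate-block list (age, gender, income,
  education, relative time outdoors) keeps the all-subsets enumeration at
  32 models per set; `build_model_sets` exposes the full candidate roster
  (all socio-demographics plus cross-outcome predictors) for users who
  want the exhaustive version.

## Known limitations

* Proportional odds is assumed for the ordinal outcome; no test of the
  parallel-lines assumption is provided.
* No spatial structure: respondents are exchangeable, vegetation cover is
  independent across respondents.
* The optimal-dose plateau rule is one reasonable operationalisation of
  "optimum"; reported optimal doses should be read together with the full
  odds-ratio curve.
* Model-set AICc comparability relies on identical complete-case rows
  within a set; across sets (e.g. intensity's restricted subsample when
  cover is missing for some respondents) AICc values are not comparable.
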