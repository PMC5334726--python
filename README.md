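# naturedose

Tools for **nature dose–response epidemiology**: quantifying how the
*frequency*, *duration* and *intensity* of everyday exposure to nearby
nature (garden visits, time spent in green space, neighbourhood vegetation
cover) relate to population health, and how much ill health could be
attributed to insufficient nature exposure.

The package is aimed at environmental epidemiologists and urban-greening
researchers working with respondent-level lifestyle surveys (≈10³ adults)
optionally linked to vegetation rasters.  It implements the full analysis
chain as a tested, reproducible library plus a thin CLI:

1. **Scale scoring and dose encoding** (`naturedose.scales`) — DASS-21
   depression subscale (doubled sum, binary "mild or worse" cutoff at 10),
   0–12 social-cohesion scale (sum of three subscale means), reverse-keyed
   nature-relatedness mean, and mid-point encodings of the survey's
   visit-frequency (visits/week) and garden-time (minutes/week) categories.
2. **Vegetation intensity** (`naturedose.vegetation`) — percent *tall
   vegetation* (NDVI > 0.2 **and** canopy height > 0.7 m, both strict)
   within a 250-m buffer of a point, by centre-inclusion counting over
   2-m raster grids (ESRI ASCII format in/out).
3. **All-subsets AICc model averaging** (`naturedose.model_averaging`) —
   for each of five health outcomes (binomial depression, proportional-odds
   self-rated health, Gaussian social cohesion and nature relatedness,
   Poisson exercise days), four candidate sets are analysed: covariates
   only, plus frequency, plus duration, plus intensity (frequency and
   duration never co-occur; they are rank-correlated ≈ 0.67).  Every subset
   of candidate term blocks is fitted and ranked by

   `AICc = −2 ln L + 2k + 2k(k+1)/(n−k−1)`,

   models with ΔAICc < 6 are retained, and full ("shrinkage") model
   averaging over Akaike weights `w_i ∝ exp(−Δ_i/2)` yields averaged
   coefficients `β̄_j = Σ_i w_i β_ij` (absent terms contribute 0) with
   unconditional standard errors
   `SE_j = sqrt(Σ_i w_i [var_i(β_j) + (β_ij − β̄_j)²])`, plus McFadden's
   pseudo-R² of the best model.
4. **Threshold-scan dose response** (`naturedose.dose_response`) — each
   dose is recoded at incrementally higher thresholds into "dose not met"
   (1) vs "met" (0); adjusted logistic regressions of depression give an
   odds-ratio curve with Wald 95% CIs.  The **minimum dose** is the first
   threshold whose CI excludes 1; the **optimal dose** is found by a
   plateau rule (no later significant OR more than 5% higher), undefined
   while the curve is still rising.
5. **Average attributable fractions** (`naturedose.attributable`) — a
   logistic model of depression on binary risk factors is fitted once;
   removing a factor set S means predicting with those columns zeroed, and
   E(S) = Σ_i logit⁻¹(x_i(S)β) is the expected case count without them.
   The **average attributable fraction** of a factor is its mean
   incremental (E(S) − E(S∪{k}))/C_obs over *all K! removal orders* — a
   Shapley decomposition, computed exactly over 2^K memoised subsets (an
   exhaustive permutation oracle is kept for verification).  Per-factor
   AAFs sum exactly to the total attributable fraction.
6. **Synthetic surveys** (`naturedose.synthetic`) — a generator with known
   ground truth (Gaussian-copula dose correlation calibrated analytically
   to Spearman 0.67, vegetation cover 24% ± 9.1, configurable outcome
   models with linear or step dose effects) so every stage is testable
   without any survey data, plus analytic raster scenes.

## Worked example

A complete run on a synthetic 1000-respondent survey:

```sh
naturedose all --seed 1 --n 1000 --out results/run1
naturedose dose-response --seed 1 --out results/run1
```

prints the detected dose thresholds,

```
frequency: minimum dose = 1.0, optimal dose = 4.5
duration: minimum dose = 30.0, optimal dose = 30.0
intensity: minimum dose = 10.0, optimal dose = 10.0
```

i.e. respondents visiting their garden less than once a week have
significantly higher odds of depression (the minimum dose), with gains
plateauing at 4–5 visits/week (the optimal dose).  The attributable
fraction table (`results/run1/aaf_table.csv`):

```
factor                      odds_ratio  ci_low  ci_high   aaf
age_under_46                     1.891   1.417    2.523  0.206
health_below_average             1.095   0.724    1.656  0.007
less_time_outdoors               1.695   1.231    2.333  0.077
freq_below_once_per_week         1.484   1.050    2.097  0.054
duration_below_5h_per_week       1.308   0.943    1.815  0.105
intensity_below_15pct            1.594   1.101    2.308  0.045
TOTAL                                                    0.494
```

reads: averaging over every order in which the six risk factors could be
removed from the population, being under 46 accounts for ~21% of observed
depression cases, visiting a garden less than weekly for ~5%, and removing
all six factors would be expected to prevent ~49%.  The per-factor values
sum to the total exactly.  `results/run1/averaged_depression_ii.csv` holds
the Table-style averaged coefficients (e.g. visit frequency −0.17 per
visit/week on the log-odds scale, generating value −0.15), and
`dose_response_*.png` are the odds-ratio curve figures.

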