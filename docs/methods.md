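# Methods

This document describes the data model, algorithms and statistical methods
implemented in `ctg_interpret`, in the order the analysis runs.

## 1. Data model (`ctg_data`)

A CTG table has 21 numeric features plus the fetal-state label `NSP`
(1 normal, 2 suspicious, 3 pathology):

| Group | Features |
|---|---|
| Baseline / variability | LB, ASTV, MSTV, ALTV, MLTV |
| Accelerations / movement | AC, FM |
| Decelerations | DL, DS, DP |
| Contractions | UC |
| FHR histogram | Width, Min, Max, Nmax, Nzeros, Mode, Mean, Median, Variance, Tendency |

`CTGDataset` wraps a pandas frame with this exact column set.
`validate_records` checks physiological invariants (e.g. `Min ≤ Mode,
Mean, Median ≤ Max`, `Width = Max − Min`, non-negative rates, NSP in
{1, 2, 3}, `Tendency` in {−1, 0, 1}) and returns a `ValidationReport`
listing each violation with row indices; `level="warn"` collects,
`level="raise"` aborts. `read_ctg_table` / `write_ctg_table` round-trip
CSV with a fixed column order so written tables are byte-stable.

## 2. Synthetic cohorts (`synthetic_ctg`)

The generator draws the class label first from the published imbalance
(0.78 / 0.14 / 0.08 by default), then each feature from a per-class
truncated-normal or count distribution whose neutral locations and rates
encode the qualitative clinical pattern (e.g. higher ASTV and more severe
decelerations in pathology, more accelerations in normals). All feature
domains are respected by truncation, and generated tables always pass
`validate_records`.

Two ground-truth hooks make the generator a test oracle:

- **Planted rules.** `plant_rule(config, PlantedRule(...))` designates a
  target class, a purity, a region fraction, and a conjunction of
  feature intervals. The requested fraction of records is moved *into*
  the region (with the target class at the requested purity) and all
  remaining records are explicitly sampled *outside* at least one
  interval, so the planted region's class distribution is exact.
- **SEM sampling.** `generate_sem_sample(model, params, n, seed)` draws
  exact multivariate-normal samples from a model's implied covariance
  `Σ(θ)`, and `structural_true_params()` supplies the preset's true
  parameter vector, enabling parameter-recovery and coverage studies.

## 3. Spearman screening (`feature_screen`)

`spearman_matrix` computes the 22×22 Spearman matrix by ranking each
column with midranks (`scipy.stats.rankdata`) and taking the Pearson
correlation of the ranks — definitionally exact under ties. (The
implementation deliberately avoids `scipy.stats.spearmanr`, which can
collapse to a scalar for certain constant-column layouts.) p-values use
the t approximation `t = ρ√((n−2)/(1−ρ²))` with a two-sided tail, and a
Bonferroni column adjusts for the 21 feature-vs-NSP tests. Constant
columns produce NaN correlations and are flagged.

`correlated_groups` thresholds |ρ| ≥ 0.7 (configurable) over the 21
features and reports the non-singleton connected components of the
resulting graph — redundant measurement clusters such as the histogram
location features. `stacked_proportions` computes per-bin class
proportions over clinical landmark edges (ASTV: 0/18/80/100; LB:
100/111/120/180), the profiles clinicians read as risk gradients.

## 4. Discretization and rule mining (`discretize_ara`)

### Class-distribution-guided binning

`fit_class_distribution_bins` divides each feature's sorted values into
~n/200-sized blocks, labels each block by its majority class, places
candidate cut points where the majority class changes (refined to the
locally optimal split between the adjacent blocks), then merges adjacent
bins in two phases — first bins with near-identical class distributions,
then the most similar pair repeatedly — until at most `max_bins` remain
and every bin holds at least `min_frac` of the data. The result is a
`BinningScheme` whose edges track where the class mixture actually
changes, rather than equal-width or equal-frequency cuts.

### Forward-stepwise rule mining

`forward_stepwise_rule` greedily builds one high-confidence rule for a
chosen class. Each step scores, for every unused feature, all single
bins and unions of adjacent bins as interval conditions, and adds the
condition maximising the confidence of `antecedent → class` subject to a
minimum-support floor (default 5 matching records). Ties break by higher
support, then canonical feature order, then lower bin start, then
shorter span — making the search fully deterministic. The trace records
every step and the stopping reason (`confidence_1`, `no_improvement`,
`support_floor`, `feature_exhausted`).

Confidence-first search is the imbalance-aware design choice: with a
support floor instead of a support-ordered search, minority classes
(suspicious, pathology) receive their own pure rules instead of being
dominated by the 78% normal class.

### Boundary refinement

After selection, `_refine_conditions` polishes each antecedent twice
while holding the other conditions fixed:

1. a coarse coordinate descent over single bins and adjacent-bin unions
   of the feature's scheme, and
2. an exact boundary slide: for each interval endpoint, the conditional
   subsample is sorted and a cumulative scan evaluates every realisable
   cut, choosing the boundary maximising confidence (ties to higher
   support). Slid boundaries snap to the last included observed value —
   never to gap midpoints — and an equal-confidence, equal-support but
   strictly narrower interval is accepted, so reported intervals are as
   tight as the data supports.

`exhaustive_best_rule` provides a brute-force oracle (globally
confidence-maximal rule over all antecedents up to a length cap on the
bin grid) used by the tests to verify the greedy search.

## 5. SEM engine (`sem_engine`)

### Model and discrepancy

Models use the LISREL parameterisation: measurement `x = Λη + ε`,
structure `η = Bη + Γξ + ζ`, giving the implied covariance

Σ(θ) = Λ C(θ) Λᵀ + Θ,  with C the joint latent covariance from
(I − B)⁻¹ applied to Φ and Ψ.

Each latent is scaled by fixing its reference indicator's loading to 1.
`build_model` accepts a declarative spec (latents with indicators,
references, paths, covariances); `measurement_model()` and
`structural_model()` are presets over five clinical constructs (BCat,
VCat, ACat, DCat, UCat) plus the latent fetal status with single
indicator NSP. Fitting minimises the ML discrepancy

F_ML(θ) = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p,

which is 0 iff Σ(θ) = S.

### Optimisation

`fit_ml` runs L-BFGS-B from data-driven start values (regression-based
loadings, sample-moment latent variances). Non-positive-definite Σ is
penalised (a large constant plus a squared negative-eigenvalue term);
because that penalty region is nearly flat, a run that finishes at
penalty level is restarted once from a conservative fallback start
(moderate loadings, zero paths, half-variance unique errors) whose
implied Σ is positive definite by construction.

The quasi-Newton optimum is then polished with Newton steps using
**complex-step gradients**: F_ML is evaluated through an analytic
complex-symmetric LLᵀ Cholesky factorisation, so `Im F(θ + ih e_k)/h`
with h = 10⁻¹⁰⁰ gives machine-precision derivatives without subtractive
cancellation. Iterating against a finite-difference Hessian drives
max|∇F| below 10⁻¹³, which is what makes noiseless refits recover θ to
~10⁻⁶ and just-identified models reproduce S to ~10⁻⁸. Non-convergence
and Heywood cases (negative variance estimates) are flagged on the
returned `SEMFit`, never silenced.

### Inference and reporting

- **Wald statistics:** standard errors are `sqrt diag((2/(n−1)) H⁻¹)`
  with H the Hessian of F_ML at the optimum; z-ratios and two-sided
  normal p-values follow.
- **Standardized solution:** every coefficient is rescaled by
  sd(source)/sd(target) using *model-implied* standard deviations, so
  the solution is invariant to affine rescaling of any indicator. Each
  latent whose reference indicator would carry a negative standardized
  loading is sign-flipped together with all its loadings, paths and
  covariances (positive-reference-loading convention), making the
  solution unique under sign indeterminacy.
- **Effects:** total latent effects come from (I − A)⁻¹ − I over the
  combined path matrix; `effect_decomposition` reports standardized
  direct, indirect and total effects on an outcome indicator such as
  NSP.
- **Fit indices:** χ² = (n−1)F_ML with model df; CFI and TLI against the
  independence model; RMSEA with a 90% interval from noncentral-χ²
  inversion; SRMR on the correlation scale.

## 6. Pipeline (`pipeline`, `cli`)

`run_pipeline` executes screening, rule mining (one rule per class) and
both SEM presets on either a provided table or a synthetic
configuration, collecting every numeric table into an `AnalysisReport`.
`export_report` writes one CSV per table plus `manifest.json` containing
the configuration hash and SHA-256 hashes of each file. The report is a
pure function of the configuration, so reruns are byte-identical — the
property the determinism test checks. The `ctg-interpret` CLI exposes
`simulate`, `screen`, `mine-rules`, `fit-sem` and `run`.

## 7. Limitations

- The synthetic generator draws features conditionally independent
  within class (apart from derived histogram identities), so
  between-feature correlation is mixture-induced. Fitting the factor
  presets to such cohorts is deliberately misspecified and is reported
  as a poor fit (CFI ≈ 0) with convergence flags; parameter-recovery
  claims are made only on `generate_sem_sample` data.
- Spearman p-values use the large-sample t approximation, not the exact
  permutation null; for the n involved here the difference is
  negligible.
- The rule miner returns one rule per class by design (interpretability
  over coverage); it is not a complete rule-set inducer.
- SEM standard errors assume multivariate normality; no robust
  (sandwich) correction is implemented.
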