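# Methods

## The allometric model

`mothmass` models moth dry body mass as a power law of forewing length,
linear on natural-log axes, with taxonomic-family refinements and a species
random intercept:

ln(M) = (β₀ + β₀,f) + (β₁ + β₁,f)·ln(L) + u_s + ε,  u_s ~ N(0, σ²_s), ε ~ N(0, σ²_e)

- **Response**: ln dry mass (mg). **Predictor**: ln forewing length (mm).
- **Family grouping**: a family keeps its own (β₀,f, β₁,f) only if it
  contributed ≥ 5 distinct species to the training data (`family_threshold`,
  default 5); all other families share the pooled "other" reference. This
  guards against over-fitting sparsely sampled families, and the reference
  level doubles as the prediction for families absent from training entirely.
- **Species random intercept**: individuals of a species share a deviation
  u_s, absorbing species-level departures from the family allometry
  (body-plan, life-history). Predictions for unmeasured species use fixed
  effects only.
- **Estimation**: maximum likelihood, *not* REML, throughout. The package's
  model-selection workflow compares fixed-effect structures by BIC and tests
  fixed effects by likelihood-ratio tests; both are invalid under REML.
  Implementation: `statsmodels` `MixedLM` behind the `MothMassRegressor`
  estimator (scikit-learn `fit`/`predict` conventions, `get_params`/
  `set_params`, fitted attributes with trailing underscores).

### Candidate structures and selection

Three predictor transforms are supported, all with ln(mass) as response so
BICs are directly comparable:

1. `linear` — ln(M) ~ L × family
2. `loglog` — ln(M) ~ ln(L) × family (the allometric form)
3. `segmented` — as `linear` plus a hinge (L − ψ)₊ and its family
   interactions, one breakpoint ψ shared across families, estimated by
   profile-likelihood grid search over the observed unique lengths excluding
   the 3 smallest and 3 largest; ψ counts as one parameter in BIC.

BIC = −2·logL + k·ln(n) with k counting fixed effects, both variance
components, and the breakpoint when present. `select_structure` picks the
minimum, breaking ties toward fewer parameters, and refuses to compare fits
made on different observation sets (checked by fingerprint).

The family-by-length interaction is tested by LRT against a reduced model
that keeps family main effects (df = number of interaction coefficients;
with one group the models coincide and the test degenerates to χ²=0, p=1).
Marginal R² is the fixed-effects share of variance on the ln scale:
var(Xβ) / (var(Xβ) + σ²_s + σ²_e).

### Prediction

`extract_parameters` re-expresses the fixed effects as a reference
slope/intercept (the "other" group) plus per-family additive adjustments —
the layout users of the published parameter table expect — and the packaged
default parameter file (`data/uk_moths_2018.yaml`) carries the published
point estimates verbatim (slope 3.056, intercept −5.016, with refinements
for Crambidae, Erebidae, Geometridae, Noctuidae). Species-level expected
mass uses the arithmetic midpoint of the field guide's printed min–max
forewing range (midpoint taken before the log transform); sample biomass is
the count-weighted sum of species masses over all moths captured at one site
on one date. Unknown families map to the reference group with a logged
warning rather than an error, because historical abundance datasets
routinely contain families absent from any training sample.

## Validation machinery

- **Major Axis (model II) regression** compares predicted vs measured
  biomass; both quantities carry error, so the symmetric MA estimator is
  used (the slope of the leading eigenvector of the 2×2 covariance matrix).
  The 95% CI uses the classical angular construction,
  H = F(0.95; 1, n−2) / [(λ₁/λ₂ + λ₂/λ₁ − 2)(n−2)], limits
  (b ∓ A)/(1 ± bA) with A = √(H/(1−H)), infinite when H ≥ 1. The constant in
  H was verified by simulation (empirical coverage 0.943 at n=30, 0.948 at
  n=100 for bivariate normal data); the test suite asserts both the
  eigendecomposition identity and simulated coverage.
- **MA regressions run on the natural-log scale** at species and sample
  level. Measured masses span three orders of magnitude (≈1–750 mg); on the
  raw scale a handful of large species would dominate the fit, and the
  diagnostic behaviour of interest (small species pulling the slope below 1,
  recovered by excluding species ≤ 15 mg) only exists when small species
  carry leverage, i.e. on the log scale.
- **Permutation test**: y permuted against fixed x, statistic = Pearson
  correlation, one-tailed for positive association, add-one convention
  p = (1 + #{r* ≥ r}) / (n_perm + 1); with the default 100 permutations the
  minimum attainable p is 1/101 ≈ 0.0099.
- **Species-level validation** uses the arithmetic mean dry mass per species
  as the measured value; the ">15 mg" subset filters on measured mean
  strictly greater than 15 mg.
- **Train/test bootstrap**: each replicate draws `train_n` individuals
  without replacement, refits the simplified loglog model on the training
  subset — re-deriving the family grouping from that subset alone, so no
  information leaks from test to train; test-set species whose family was
  not retained in training are predicted through the reference parameters —
  predicts held-out individuals via their species' guide midpoints, and runs
  the species- and sample-level MA validations on the held-out data.
  Aggregates: % replicates with permutation p ≤ 0.05, % with slope CI
  excluding 1 (full and >15 mg subsets), mean and SE of R². Failed
  replicates (non-convergence, degenerate subsets) are logged and redrawn,
  never silently dropped. A single master seed spawns per-replicate
  substreams (`numpy` `SeedSequence`), so runs are reproducible and
  replicate-order-independent.
- **Prediction-error curve**: sets of individuals are resampled with
  replacement at a grid of sample sizes; each replicate's error is
  100·(predicted − measured)/measured minus the whole-dataset offset (so a
  sample erring exactly like the full dataset scores zero; the offset is
  computed, never hard-coded). Errors are summarized (mean, SE, range)
  within windows of 100 consecutive sizes.

## Synthetic communities

The generator (`simulate_community`) exists to give every statistic a known
truth. Defaults reproduce the motivating study's conditions:

| parameter | default | why |
|---|---|---|
| families × species | 11 families, (36,22,11,10,3,3,2,2,2,2,1) = 94 species | study layout: 4 speciose families, 7 below the grouping threshold |
| individuals | 600 (≥1 per species, remainder lognormal-weighted multinomial) | study size; lognormal weights give the skewed counts typical of light-trapping |
| true parameters | the published reference set | so synthetic and reference behaviour coincide |
| σ_s, σ_e | 0.2, 0.3 (ln scale) | gives marginal R² ≈ 0.8–0.9, matching the fitted study model |
| species mean lengths | log-uniform on 7–40 mm | the observed length range |
| within-species length CV | 0.10 | plausible intraspecific variation; not stated by any source, chosen once |
| guide half-width | 2 mm (optional mean-shift knob, default off) | typical printed range width; the shift knob can emulate guides that run large |
| sites × dates | 3 × 15 (≈44–45 samples) | study sampling grid |
| quantization | lengths to 1 mm (floor 1), masses to 0.01 mg, 0.005 mg detection floor | the study's measurement resolution; below-floor individuals are emitted as below-detection records so the exclusion filter is testable |

Masses are generated from the *unquantized* length, then measurement
quantization is applied — so fitting code faces realistically coarse data.
What the generator does **not** emulate: phenology, species–abundance-
distribution theory, sexual dimorphism, geographic or temporal size drift,
guide-range asymmetry. Passing tests therefore demonstrate statistical
correctness of the machinery under the model's own assumptions plus
measurement coarseness — not robustness to ecological structure the model
ignores.

### Calibration experiments and quantization

`recovery_experiment` simulates, refits, and reports per-coefficient bias,
RMSE and 95% Wald-CI coverage. Rounding the predictor to 1 mm is classical
measurement error and attenuates the fitted slope by just under 1% (≈−0.5%
to −0.9% at the default length range) — enough to be detectable against the
SEM of 200 replicate datasets. The recovery/coverage experiment therefore
runs on the continuous (unquantized) generating model, which is what the
Wald intervals assume, while the quantization attenuation is bounded
separately by a dedicated no-noise check (<1% relative slope bias). LRT
type-I calibration runs under the full quantized defaults (empirically
≈0.05–0.08 at α = 0.05).

## Numerical choices

- Optimizer: `MixedLM` ML with a fallback chain (lbfgs → bfgs → powell →
  cg/nm). A result counts as converged only if the log-likelihood, fixed
  effects and variance components are finite and the residual variance
  positive; optimizers occasionally report success at a degenerate point.
  Agreement with lme4 (ML) is ~1e−5 on fixed effects and log-likelihood
  (asserted at 1e−3 in the test oracle).
- Singular fits (σ²_s → 0) are accepted with a warning, not an error.
- Re-parameterizing the reference family leaves fitted values unchanged to
  ~1e−6 (optimizer tolerance), not machine precision.
- Degenerate MA inputs (zero covariance with equal variances; a vertical
  major axis) raise; perfectly collinear data get a point-mass CI.
- Ties in BIC selection go to the fit with fewer parameters.
- Below-detection masses are a sentinel (`<0.005`) in CSV, NaN + flag in
  memory — representable, hence testable, rather than silently zero.

## Problem sizes used by the automated checks

The acceptance script and test suite run the simulation experiments at 200
datasets (recovery, LRT calibration), 200 bootstrap replicates, 1,000
random datasets for the MA oracle, 500 seeds for permutation calibration,
and error-curve grids of sizes 10–300 × 100 replicates (10 seeds) — sizes
chosen so the full battery completes in a few minutes on one CPU while
keeping Monte-Carlo error well inside the asserted bands. The library
defaults remain the full-scale analyses (10,000 bootstrap replicates;
error-curve sizes 10–1,000 × 1,000 replicates).

## Known limitations

- Parameters extrapolate poorly outside the trained length range and fauna
  (night-flying UK macro-moths, 7–40 mm); day-flying families, micromoths,
  or tropical faunas warrant refitting on regional data.
- No sex covariate: recording schemes rarely note sex, so predictions are
  per-individual averages even for dimorphic species.
- Single-moth predictions carry no uncertainty intervals; uncertainty is
  quantified at the pipeline level (bootstrap, error curves).
- The species random intercept is not used for prediction, so species-level
  predictions for *measured* species are no better than for unmeasured ones.
- No phylogenetic imputation or subfamily refinement.
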