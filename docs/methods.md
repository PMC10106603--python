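# Methods

## Scope and data model

`yieldcast` operates on plot-level trait tables: one row per experimental
plot with design factors (genotype, germplasm class, experiment, water
regime, sowing date, replicate) and traits — grain yield GY (t ha⁻¹ at 12 %
moisture), NDVI at anthesis (dimensionless, [0, 1]), days to heading DH
(days from sowing to 50 % spike emergence), plant height PH (cm) and ear
density EARS (ears m⁻²). NDVI may alternatively be computed from per-plot
mean red/NIR reflectances via `(R_NIR − R_red)/(R_NIR + R_red)`; everything
upstream of plot-aggregated reflectance (flights, mosaicking, radiometric
calibration) is out of scope.

Missing trait values are empty CSV cells ⇔ `NaN`. A plot lacking a trait
required by a given model is excluded from that model's fit or validation
only (listwise per-model deletion), with exclusion observable through the
tables' completeness counts. The canonical on-disk form is comma-separated
UTF-8 with a header row; a column-name mapping absorbs foreign headers.
Round trips are value-preserving: floats are written as their shortest
exact decimal representation and re-parsed with Python's `float`, because
pandas' fast CSV float path can be one ulp off, which would break seeded
byte-for-byte reproducibility of downstream results.

## Ridge regression and model scoring

All yield models minimize ‖y − β₀ − Zβ‖² + λ‖β‖² with an unpenalized
intercept, where Z holds the predictors standardized to zero mean and unit
standard deviation. Conventions, pinned for reproducibility:

* Standardization uses the population (1/n) standard deviation.
* The fit is the closed-form SVD solution; coefficients are reported back
  on the original trait scale. At λ = 0 and full rank this is exactly OLS.
* Effective degrees of freedom: edf(λ) = Σᵢ dᵢ²/(dᵢ² + λ) over the singular
  values of Z (the trace of the ridge hat matrix); edf(0) = rank(Z).
* Model score: Gaussian-likelihood BIC = n·ln(RSS/n) + (edf + 1)·ln(n),
  the +1 counting the unpenalized intercept. Additive constants are
  dropped (they cancel in comparisons); the score reduces to the textbook
  BIC at λ = 0. A zero RSS (degenerate perfect fit) makes BIC undefined
  and is reported as an error rather than −∞.
* λ is selected per fit by k-fold cross-validation (default k = 10, folds
  from a seeded permutation, sizes differing by ≤ 1) over a data-adaptive
  grid of 100 log-spaced values on [10⁻⁴·λ_max, λ_max] with
  λ_max = max|Zᵀ(y − ȳ)|/n. The winner minimizes the mean held-out MSE;
  ties break toward the larger λ (more regularization under equal error).
  The NDVI-only benchmark is simply the p = 1 case of the same pipeline.

On pure-noise responses this CV prefers the largest grid value in
essentially every seed, and on noiseless linear responses the smallest, as
expected; both behaviors are regression-tested.

## Exhaustive subset search and selection

For p candidate traits, all 2ᵖ − 1 non-empty subsets are enumerated
(p ≤ 10 guard; 15 models for NDVI/PH/DH/EARS) in a deterministic order:
size descending, then lexicographic in the canonical trait order
(NDVI, PH, DH, EARS).

Calibration repeats `n_iter` (default 100) iterations. Each iteration draws
one seeded random subset of the configured size (20/50/100 by default) from
the plots complete for *all* candidate traits plus GY, and every combo is
fitted on that same subset — BIC comparisons across combos are therefore
paired, which removes subset-to-subset variance from the comparison. (The
standalone one-shot calibration op draws from its own combo's complete
cases instead.) A drawn subset on which any predictor has zero variance is
redrawn with a derived seed (≤ 10 retries), then the iteration is marked
skipped; a combo with > 20 % skipped iterations aborts the run.

The winning combo minimizes the **median BIC** across iterations (median =
lower-middle order statistic, so it is always an actually-fitted run; ties
break toward fewer traits, then canonical order). The representative model
carried to validation is the winning combo's median-BIC run. The mean BIC
per combo is also reported. An across-iteration aggregate is needed because
per-iteration winners vary; the median is robust to the occasional
ill-conditioned draw.

## Validation and benchmark comparison

Prediction accuracy is the squared Pearson correlation between observed and
predicted GY on held-out plots, with the two-sided t-test p-value (n − 2
df); p-values below 10⁻¹⁵ are floored there rather than printed as 0. RMSE
and the observed-on-predicted OLS slope/intercept are reported alongside.
Constant predictions leave R²/p/slope flagged undefined while RMSE is still
reported. Model-vs-benchmark improvements are relative percentages,
100·(best − benchmark)/benchmark for both R² and RMSE; when the benchmark
R² is zero the relative delta is undefined and absolute deltas are reported
instead.

## Saturation analysis

Plots are stratified at a GY threshold (default 8 t ha⁻¹; the boundary
value goes to "above") and the NDVI–GY squared correlation is computed per
stratum. A large below-minus-above gap is the saturation signature. A scan
over multiple thresholds flags under-populated strata (< 3 NDVI-complete
plots) as insufficient instead of failing. No automatic changepoint
estimation is attempted — the threshold is a configuration input.

## Heritability

For balanced replicated trials (every genotype with the same r ≥ 2
replicates), one-way ANOVA method of moments: σ²e = within-genotype mean
square, σ²g = (between MS − σ²e)/r truncated at 0 (with a warning), and
H² = σ²g/(σ²g + σ²e/r). Unbalanced replication is an error by design: the
formula presumes a single r, and a silently approximate fit (or a REML
machinery this package does not otherwise need) would misrepresent what is
computed. Unreplicated trials are refused rather than given a placeholder.

## Synthetic trial generator

The generator emulates the statistical structure the analysis assumes, per
experiment × germplasm-class cell:

* GY = cell mean + genotype effect N(0, σ²g) + plot error N(0, σ²e),
  floored at 0.1 t ha⁻¹. The variance split is configured directly, or
  derived from a target H² at the cell's r (σ²g = (S²/r)/(1/H² − 1 + 1/r)
  with S the cell SD), or defaults to 60/40.
* (DH, PH, EARS) are drawn jointly with GY through a Gaussian copula with
  a configurable 4×4 correlation matrix (defaults: GY–DH −0.60, GY–PH
  +0.70, GY–EARS +0.70, modest predictor intercorrelations), then mapped
  to per-class means/SDs (e.g. modern PH 85 ± 10 cm, landrace 120 ± 12 cm).
* NDVI responds to above-ground biomass = GY / harvest-index through a
  Beer–Lambert-like curve `soil + (ndvi_max − soil)(1 − e^(−k·biomass))`
  with soil baseline 0.15, asymptote 0.92 and k = 0.09 per t ha⁻¹ biomass —
  chosen so the noiseless curve passes ≈ 0.75 at 8 t ha⁻¹ grain yield for
  a modern harvest index, the regime where saturation is reported to set
  in. Gaussian measurement noise (SD 0.03) is added and the result clipped
  to [0, 1]. Setting `saturation_enabled=False` substitutes an affine ramp
  (reaching ndvi_max at 30 t ha⁻¹ biomass) as the non-saturating control.
* Harvest-index defaults: modern 0.48, landrace 0.30. The landrace value
  sits at the low end of the literature range for tall Mediterranean
  landraces; it makes landrace biomass — and hence NDVI — approach modern
  levels despite ~4 t ha⁻¹ lower yield, reproducing the "landrace paradox"
  in which NDVI-based models overpredict landrace yields.

Presets: `case1_2017`/`case1_2018` (unreplicated panel, 170 landrace + 184
modern plots, class means ≈ 5.1/9.5 and 5.6/9.9 t ha⁻¹) and `case2_2021`
(seven replicated experiments, 10–22 genotypes × 3 reps plus one 16 × 6
cell, cell means 4.14–11.87 t ha⁻¹, target H² 0.664–0.903). The preset
tables total 354 and 348 plots respectively.

`verify_generator` recomputes empirical cell moments (pass if within 3
standard errors of target), latent trait correlations (±0.1, checked only
at n ≥ 1000 where the tolerance is meaningful), per-cell H², and the
stratified NDVI–GY correlations from an emitted table.

What the generator does **not** emulate: spatial field trends, weather and
phenology dynamics, genotype-by-environment interaction beyond separate
cell means, non-Gaussian trait margins, or measurement error structure in
the agronomic traits. Passing tests therefore demonstrate that the pipeline
recovers structure *of this kind* correctly — not that a particular R² will
be attained on real field data.

## Pipeline, seeds and determinism

The end-to-end run generates or ingests a table, splits it (default: whole
experiments held out — the low- and high-yielding experiments as two
independent validation sets, the rest as the training pool), optionally
stratifies both sides at the saturation threshold, and fits an independent
ensemble per stratum × training size, always validating the best model next
to the NDVI benchmark. A (stratum, size) whose complete-case pool is
smaller than the requested size is skipped with a logged note. One master
seed fans out to every stochastic stage via SHA-256 hashes of the stage
name and indices (all derived seeds < 2³¹), so results are byte-identical
across repeats; outputs are sorted-key JSON/CSV/YAML without timestamps.
The default run (15 combos × 100 iterations × 3 sizes × 2 strata on a
348-plot table) takes well under a minute on one CPU.

Default problem sizes used by the test suite and the reproduction script —
50 replicates of the selection-consistency experiment, 20 seeds for the
saturation contrast, 200 simulations for heritability recovery, 100 seeds
for the training-size trend — were chosen to keep Monte-Carlo error
comfortably inside the asserted margins.

## Known limitations

* BIC is computed on the ridge fit itself (via edf), not on an unpenalized
  refit of each subset; at the λ values the CV typically selects the two
  agree closely, but they are not identical.
* The Case-1 convention (validation = stratified 20+20 draw, training
  draws from the remainder) and the shared-subset pairing across combos
  are fixed design choices; alternatives (independent subsets per combo)
  would increase comparison variance.
* Relative improvement percentages are unstable when the benchmark R² is
  near zero; the absolute-delta fallback engages only at exactly zero or
  undefined.
* Heritability supports balanced one-way layouts only — no spatial
  adjustment, no adjusted means for augmented designs.
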