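# yieldcast

In-season wheat grain-yield prediction from aerial NDVI and easy-to-measure
agronomic traits, for plant-breeding and agronomy teams who want to replace
(or triage) machine-harvest yield determination in experimental trials.

## The problem and the method

NDVI at anthesis, `NDVI = (R_NIR − R_red)/(R_NIR + R_red)`, tracks canopy
biomass and correlates with grain yield (GY) — but it saturates over dense
canopies, so high-yielding plots (roughly GY > 8 t ha⁻¹, NDVI > 0.75) become
indistinguishable, and tall landraces carry modern-variety NDVI at far lower
yields. `yieldcast` implements the multivariate remedy: combine NDVI with
days to heading (DH), plant height (PH) and ear density (EARS).

For candidate traits it fits **all 2ᵖ−1 = 15 predictor subsets** with ridge
regression (unpenalized intercept, predictors standardized, penalty λ chosen
per fit by 10-fold cross-validation), on **repeated random training draws**
(default 100 iterations of 20/50/100 plots), and selects the winning subset
by the lowest median **BIC**

    BIC = n·ln(RSS/n) + (edf + 1)·ln(n),   edf = Σᵢ dᵢ²/(dᵢ² + λ),

where edf is the effective degrees of freedom of the ridge hat matrix. The
representative model (the median-BIC run of the winning subset) is validated
on held-out plots — R², RMSE and regression p of observed vs predicted —
always side-by-side with the NDVI-only benchmark, reporting relative deltas
(e.g. R² 0.60 vs 0.40 ⇒ +50 % accuracy). Supporting analyses: stratified
NDVI–GY correlation below/above a yield threshold (saturation diagnostics),
and broad-sense heritability H² = σ²g/(σ²g + σ²e/r) from balanced replicated
trials.

Because raw field data of this kind is rarely shareable, the package ships a
synthetic trial generator (`yieldcast.simulate`) with genotype/error variance
components, landrace vs modern harvest-index classes, correlated traits, and
a Beer–Lambert-like saturating NDVI response — presets mirror a two-season
landrace/modern panel and a seven-experiment replicated multi-environment
set.

## Worked example

```python
from yieldcast.pipeline import RunConfig, run_case_study

cfg = RunConfig(training_sizes=(50,), n_iter=100, master_seed=42)
bundle = run_case_study(cfg)   # generates the multi-environment preset,
                               # splits by experiment, stratifies at 8 t/ha
print(f"{bundle.n_plots} plots; saturation r2 below/above 8 t/ha: "
      f"{bundle.saturation['r2_below']:.3f} / {bundle.saturation['r2_above']:.3f}")
for r in bundle.results:
    c = r.comparison
    print(f"[{r.stratum}, n_train={r.training_size}] "
          f"best model: {'+'.join(r.ensemble.best_combo).upper()}"
          f" | validation R2={c.best_model_metrics.r2:.3f}"
          f" RMSE={c.best_model_metrics.rmse:.3f}"
          f" | NDVI benchmark R2={c.benchmark_metrics.r2:.3f}"
          f" RMSE={c.benchmark_metrics.rmse:.3f}")
```

prints

```
348 plots; saturation r2 below/above 8 t/ha: 0.859 / 0.362
[below, n_train=50] best model: NDVI | validation R2=0.789 RMSE=0.614 | NDVI benchmark R2=0.789 RMSE=0.614
[above, n_train=50] best model: NDVI+PH+DH+EARS | validation R2=0.437 RMSE=1.634 | NDVI benchmark R2=0.211 RMSE=1.707
```

Reading: the NDVI–GY correlation collapses above 8 t ha⁻¹ (R² 0.86 → 0.36 —
saturation). Below the threshold NDVI alone is already the BIC-best model;
above it, adding agronomic traits roughly doubles the held-out prediction R²
over the NDVI benchmark (0.44 vs 0.21) and lowers the RMSE.

The same workflow is scriptable from the shell:

```bash
yieldcast generate --preset case2_2021 --seed 1 --out out/gen
yieldcast run --preset case2_2021 --seed 1 --out out/run
yieldcast saturation --input out/gen/trial.csv --out out/sat.json
yieldcast heritability --input out/gen/trial.csv --out out/h2.csv
```

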