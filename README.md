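# metanue

Meta-analysis of how agricultural management practices change the nitrogen
recovery efficiency (NUEr, %) of cereal cropping, and spatial upscaling of
those changes over covariate grids.

Field experiments comparing a management practice against conventional
management report paired group means of NUEr with dispersions and replicate
counts, plus the site conditions (N application rate, climate, soil) that
modulate the response. `metanue` implements the complete inference chain a
synthesis of such experiments needs:

1. **Ingestion and completion** of paired observation tables: validation,
   imputation of missing SDs from the database-wide coefficient of variation
   (`SD = CV × mean × 1.25`), default replicate counts, and unit-variance
   covariate scaling.
2. **Effect sizes** per observation — log ratio of means (ROM), raw mean
   difference (MD, NUEr percentage points) and standardized mean difference
   (SMD) — each with its analytic sampling variance, and conversions of all
   three onto the absolute NUEr-change scale.
3. **Inverse-variance pooling** of estimates from published meta-analyses
   (`x̄ = Σ(xᵢ/σᵢ²)/Σ(1/σᵢ²)`, `σ_x̄ = 1/√Σ(1/σᵢ²)`).
4. **Mixed-effects meta-regression** with moderators and interactions,

   `yᵢ = β₀ + β₁xᵢ₁ + β₂xᵢ₂ + β₃xᵢ₁xᵢ₂ + … + uᵢ + eᵢ`,

   where the true-effect deviations `uᵢ` are compound-symmetric within each
   study (variance τ², within-study correlation ρ) and `eᵢ ~ N(0, vᵢ)` with
   known sampling variances. Variance components are estimated by REML with
   analytic gradients; inference includes Wald moderator contrasts, the Q_E
   residual-heterogeneity test, AIC and McFadden pseudo-R².
5. **Scenario upscaling**: encode single practices or bundles as design-row
   contrasts, predict ΔNUEr per grid cell and crop with 1.96-based 95%
   confidence intervals from the fixed-effects covariance, and aggregate to
   cropland-area-weighted regional and global means.
6. A **synthetic-data generator** that draws study-clustered corpora with
   known coefficients, τ², ρ and covariate ranges matching global cereal
   trials, enabling full parameter-recovery experiments.

The estimator follows scikit-learn conventions (`fit`, `predict`,
`get_params`, trailing-underscore fitted attributes), so it composes with
sklearn tooling; module-level functions wrap it for script use, and a
`metanue` CLI drives the pipeline from the shell.

## Worked example

```python
import numpy as np
from metanue import (
    MetaRegression, SyntheticConfig, build_design, compute_effect_sizes,
    generate_observations, scale_covariates,
)

config = SyntheticConfig(missing_sd_fraction=0.0)   # 30 studies x 5 pairs
table, truth = generate_observations(config, seed=1)
eff = compute_effect_sizes(table, "MD")
merged = table.join(eff[["yi", "vi"]])
merged, _ = scale_covariates(merged, variables=list(truth.scaling.center),
                             params=truth.scaling)
y, v, X, ids = build_design(merged, config.spec)
model = MetaRegression().fit(X, y, v=v, study_ids=ids)
print({k: round(b, 2) for k, b in zip(model.column_names_, model.beta_)})
print("tau2", round(model.tau2_, 3), "rho", round(model.rho_, 3))
```

prints

```
{'intercept': 1.16, 'RFR': 9.62, 'EE': 7.01, 'crop_maize': 0.44,
 'crop_rice': -0.93, 'n_rate': -1.27, 'soc': 2.38, 'RFR:soc': 1.9}
tau2 3.276 rho 0.734
```

The fitted coefficients sit near the generating truth (intercept 2, RFR 8,
EE 6, crop_maize 1.5, crop_rice −1, n_rate −2, soc 2, RFR:soc 2 with
τ² = 4, ρ = 0.5): the RFR coefficient says adopting the right fertilizer
rate raises NUEr by about 9.6 percentage points at average soil carbon for
this draw, and the positive `RFR:soc` interaction says the gain grows on
carbon-richer soils.

The same chain from the shell:

```bash
metanue simulate --out obs.csv --seed 1
metanue ingest --observations obs.csv --out clean.csv
metanue effects --in clean.csv --method MD --out effects.csv
metanue run --config run.yaml     # full pipeline with manifest
```

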