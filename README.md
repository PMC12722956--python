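# socmap

Probabilistic geostatistical mapping of soil organic carbon (SOC) and
interpretable-ML identification of its nonlinear nutrient thresholds.

Croplands under contrasting pedoclimatic regimes store very different
amounts of topsoil organic carbon, and the controls are not linear:
nitrate, extractable iron, total nitrogen, phosphorus and cation
exchange capacity (CEC) act through *thresholds* — abrupt transitions in
the SOC response — and through interactions whose sign flips across
those thresholds. `socmap` implements, as a tested library, the full
analysis chain used to detect and map such behaviour from point soil
samples:

* **Geostatistics** — semivariogram estimation (Matheron), WLS variogram
  fitting of spherical/exponential/Gaussian models with leave-one-out
  kriging RMSE family selection, ordinary kriging with a moving
  neighborhood, normal-score sequential Gaussian simulation (SGS), and
  interval-probability maps of paired-ensemble differences (per pixel,
  the fraction of realization pairs whose difference ΔSOC falls in each
  interval of a partition).
* **Interpretable ML** — LR / random-forest / SVM-RBF / XGBoost with a
  70/30 region-stratified split and 10-fold grid-search CV; permutation
  importance; partial-dependence (PDP) curves; exact interventional
  Shapley values and pairwise interaction values.
* **Threshold analysis** — the two-stage procedure at the package's
  core: stage 1 locates candidate breakpoints from PDP extrema/curvature
  and SHAP sign shifts; stage 2 tests them with continuous
  piecewise-linear (segmented) regression on partial residuals built
  from 10-fold out-of-fold predictions, accepting a breakpoint only when
  it raises adjusted R² by ≥ 0.01 over a straight line. A decile-grid
  search over SHAP interaction values identifies *dual-threshold
  domains*: pairs (t₁, t₂) across which the interaction's sign pattern
  flips.
* **Synthetic soil landscapes** — a first-class generator that plants
  regional spatial structure (range, nugget) and threshold responses
  into covariate random fields, so every stage above can be scored
  against known truth. Two scenarios ship as defaults: `jiaodong`
  (short-range, high-nugget; a sharp nitrate step with plateaus
  13.5 → 16.0 g·kg⁻¹ at 10 mg·kg⁻¹ and an NO₃⁻-N × Fe domain at
  (10, 12) mg·kg⁻¹) and `southwest` (long-range, near-zero nugget; a TN
  ramp at 3.25 g·kg⁻¹ rising 2.0 g·kg⁻¹, a nitrate decline above
  27 mg·kg⁻¹, and TP/CEC step responses).

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

Generate a maritime-scenario dataset (500 sites), fit the tuned random
forest, and run the threshold analysis on nitrate:

```python
from socmap import (scenario, sample_scenario, train_models,
                    shap_decomposition, two_stage_thresholds,
                    dual_threshold_domain)

cfg = scenario("jiaodong", n_sites=500, seed=1)
table, truth = sample_scenario(cfg)

models = train_models(table, table.covariates, split_seed=1,
                      algorithms=("RF",))
print(models.summary())

rf = models.estimators["RF"]
shap = shap_decomposition(rf, models.X_train, models.predictors,
                          interactions=True, seed=1)
result = two_stage_thresholds(rf, models.X_train, models.predictors,
                              "no3n", shap=shap, y=models.y_train, seed=1)
print(result.fit.summary())

domain = dual_threshold_domain(shap, ("no3n", "fe"))
print(domain.summary())
```

Output:

```
Model comparison (70/30 split, 10-fold CV tuning)
algorithm  test_adj_r2  test_rmse  cv_mean_r2  max_features
       RF       0.8736     0.4987      0.8383             1

Segmented regression for 'no3n'
  breakpoints : 9.476, 10.47
  primary     : 9.973926651352574
  slopes      : -0.01546, 2.451, 0.01361
  RSS         : 88.4 (line: 304.1)
  adj-R2 gain : 0.3685  accepted: True

Dual-threshold domain (no3n, fe)
  thresholds: no3n = 9.652, fe = 12.55
  objective (between-quadrant variance): 0.03274
      no3n<t & fe<t      : mean interaction +0.1972 (n=68)
      no3n<t & fe>=t     : mean interaction -0.3125 (n=32)
     no3n>=t & fe<t      : mean interaction -0.02688 (n=72)
     no3n>=t & fe>=t     : mean interaction +0.1836 (n=28)
```

Reading it: the forest explains ~87% of held-out SOC variance; the
segmented fit brackets the planted nitrate step with knots at 9.48 and
10.47 mg·kg⁻¹ and reports its centre, 9.97 mg·kg⁻¹ (planted: 10.0), as
the threshold; the steep middle slope (2.45 g·kg⁻¹ per mg·kg⁻¹ over a
~1 mg·kg⁻¹ transition) carries the 13.5 → 16.0 g·kg⁻¹ plateau shift.
The interaction-domain search recovers thresholds (9.65, 12.55) near the
planted (10, 12): iron above ~12 mg·kg⁻¹ suppresses SOC when nitrate is
below its threshold (mean interaction −0.31) and turns neutral-positive
above it (+0.18).

The same pipeline is available from the shell:

```sh
socmap simulate --scenario jiaodong --seed 7 --out sim/
socmap krige --samples sim/samples.csv --out krige/
socmap sgs --samples sim/samples.csv --n-real 1000 --seed 3 --out sgs/
socmap thresholds --samples sim/samples.csv --predictor no3n --out thr.json
```

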