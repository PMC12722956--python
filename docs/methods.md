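# Methods

`socmap` couples two analysis layers for topsoil organic carbon (SOC):
a probabilistic geostatistical layer (variography, ordinary kriging,
sequential Gaussian simulation, paired-ensemble difference-probability
maps) and an interpretable machine-learning layer (a fixed training
protocol, permutation importance, partial dependence, exact Shapley
attribution, and a two-stage breakpoint procedure with a dual-threshold
interaction diagnosis). A synthetic soil-landscape generator with planted
spatial structure and response thresholds makes every stage testable
end-to-end against known truth.

## Geostatistical layer

**Semivariogram.** The Matheron estimator on 12 equal-width distance bins
up to half the maximum pairwise distance (both defaults overridable).
Values with |skewness| > 1 can be log- or Box-Cox-transformed first
(`transform_if_skewed`; Box-Cox lambda by maximum likelihood).

**Model fitting and selection.** Spherical, exponential and Gaussian
families are fitted by weighted least squares with Cressie weights
N(h)/gamma_model(h)^2 and multi-start initialisation. Exponential and
Gaussian use the practical-range convention (gamma reaches ~95% of the
sill at h = a) so fitted ranges are comparable across families. The
winning family minimises leave-one-out ordinary-kriging RMSE on the
samples; LOO RMSEs within 1% relative of the best are treated as ties
(differences that small sit below the LOO estimate's own Monte-Carlo
noise) and fall back to WLS cost, then to the fixed order spherical >
exponential > gaussian. When a transform was applied, the summary reports
the nugget fraction on both the fitted and the raw scale, since the two
are not interchangeable.

**Ordinary kriging.** Per target cell, the standard augmented system with
the unbiasedness constraint is solved over a moving neighborhood: the
nearest 16 points within 1.5x the variogram range, expanded to the
nearest 4 when fewer fall inside. Weights sum to 1 by construction;
variance is clipped at 0 against round-off. Duplicate sample locations
raise an error naming the point rather than silently regularising.

**Sequential Gaussian simulation.** Data are normal-score transformed
(plotting positions (r-0.5)/n; ties get average ranks). Each realization
follows an independent uniformly random visiting path (seeded as
SeedSequence([master, realization])); each node is simulated by *simple*
kriging with mean 0 in normal-score space — the flavour SGS requires for
covariance reproduction; ordinary kriging is used only for prediction
surfaces — over a neighborhood that includes previously simulated nodes
(capped at 16 points total). Back-transformation interpolates the data
quantiles and extrapolates linearly to [min - 0.5 IQR, max + 0.5 IQR],
reaching the bound at ±3.5 sigma, so simulated values are bounded. Grid
nodes coincident with a datum copy it exactly (zero-nugget conditioning
exactness); two data on one node is an error.

**Difference-probability maps.** Two ensembles on grids of identical
dimensions are differenced realization-by-realization (index pairing;
the registration of two disjoint regions onto a common grid is the
caller's modelling decision — the synthetic scenarios are built
co-registered). Interval probabilities use left-closed half-open
intervals [a, b) with open extremes; an edge value counts upward. The
per-pixel mean-SD regression is ordinary least squares with adjusted R^2
and the CV map is SD/mean.

## Machine-learning layer

**Protocol.** 70/30 train/test split stratified by region;
z-standardisation fitted on the training rows only and applied to linear
regression and SVM-RBF; grid search inside 10-fold cross-validation on
the training set; adjusted R^2 (1 - (1-R^2)(n-1)/(n-p-1), p = number of
predictors) and RMSE on the held-out test set. Grids are small and
single-core-sized: random forest fixes 200 trees and tunes
features-per-split in {1/3, all} (with ~6 predictors, sqrt(p) and p/3
coincide at 2 features, so that pair would be a degenerate grid; {2, all}
spans the actual bias-variance trade-off); SVM tunes C in {1, 10, 100}
and gamma in {scale, 0.1, 0.01}; XGBoost tunes learning rate {0.05, 0.1}
and depth {3, 5} at 300 trees.

**Permutation importance.** Mean test-MSE increase over 20 permutations
per predictor, floored at zero and normalised to percentages summing to
100 (the "share of model variance" convention).

**Partial dependence.** 50 quantile-spaced grid points between the 1st
and 99th percentile; the response is the mean prediction with the
predictor clamped to each grid value for all rows. Quantile spacing makes
an unweighted fit over grid points approximately density-weighted.

**Shapley attribution.** Exact interventional Shapley values by coalition
enumeration: v(S) is the mean prediction with features outside S replaced
by background rows; all 2^p coalition values are evaluated in one batched
model call and combined with the exact Shapley weights. Pairwise
interaction values use the Shapley interaction index with the diagonal
defined so rows sum to the per-feature value; the matrix is symmetric and
base + sum(phi) reproduces each prediction to float precision. Cost is
O(2^p x background) model rows per explained sample, so explained rows
and background are subsampled (defaults 200 and 50, seeded) and p > 14 is
rejected. This exactness is what the additivity and symmetry contracts in
the test suite rely on.

## Two-stage threshold identification

**Stage 1 — candidates.** On the LOESS-smoothed PDP (span 0.15 — at the
50-point grid resolution a 0.3 span displaces curvature features by more
than the stage-2 search window, so candidate detection uses a
resolution-scaled span; `loess_smooth` itself defaults to 0.3): local
extrema; curvature exceedances (|second difference| > 3 x MAD, with an
absolute floor of 0.1% of the PDP range so straight or flat curves yield
nothing), contributing per contiguous run both the |curvature| peak and
the steepest interior point (the inflection centre of a smoothed step);
and zero crossings of the LOESS-smoothed SHAP dependence. Candidates
within one grid step are merged.

**Stage 2 — segmented regression.** Continuous piecewise-linear least
squares (hinge basis) with knots searched on a grid of x-range/200 inside
windows of ±10% of the x-range around each candidate; two-knot fits are
searched (coarse pair scan, then local refinement) whenever a second
candidate exists. The knot count is chosen by adjusted R^2 — a one-knot
continuous fit cannot represent a level step, so the two-knot model must
be allowed to win directly — and the fit is accepted when it beats the
straight line by at least 0.01 adjusted R^2.

The regression target is, by default, the per-sample *partial residual*
y - y_oof + PDP(x_j), built from 10-fold out-of-fold (OOF) predictions.
Subtracting the OOF prediction removes both the other covariates'
variance and the model's own smoothed rendering of the focal predictor;
adding the PDP back restores the marginal effect. The profile is then
unbiased for the predictor's true response shape with only
residual-scale noise around it — fitting the PDP curve directly, or raw
OOF predictions, inherits the forest's smearing of sharp transitions
(measured on the generator: onsets displaced by ~+0.3 and step sizes
attenuated by ~30%), while raw observations drown small effects in the
other covariates' variance. Both alternatives remain available
(`mode='pdp'`, `mode='oof'`).

**Reported threshold.** A two-knot fit whose steep segment lies in the
middle is a plateau-transition-plateau shape: if the middle segment spans
less than 15% of the x-range it is a smoothed step and the knot midpoint
(the step centre) is reported; otherwise it is a ramp and the onset (the
lower knot) is reported. Other slope patterns report the knot with the
larger |slope change|. Step sizes are measured between the fitted levels
at the medians of the two outer segments, which is robust against knots
sitting slightly inside the transition.

**Dual-threshold domains.** For a feature pair, the per-sample SHAP
interaction values are split by a 2x2 threshold grid over the 1st-9th
deciles of each feature; the reported pair maximises the count-weighted
between-quadrant variance (the ANOVA between-group sum of squares / n).
Weighting by quadrant size is essential: the unweighted variance of the
four quadrant means is maximised by thresholds that isolate a
half-dozen-sample quadrant whose noisy mean dominates. Quadrants with
fewer than 5 samples at the optimum, or a near-zero objective, set a
`flagged` attribute rather than raising.

## Synthetic soil-landscape generator

**Spatial structure.** Each covariate is a zero-mean unit-sill Gaussian
random field synthesised by circulant embedding (exact covariance on the
doubled torus; negative spectral mass is clipped with a warning above
0.1%, with a dense-Cholesky fallback for grids of at most 4000 cells) and
the nugget fraction is added as white noise. Regional structure defaults:
"jiaodong" spherical, range 42.6 km, nugget fraction 39.14%; "southwest"
spherical, range 68.0 km, nugget fraction 1.12%. Both scenarios use a
100x100 grid of 2-km cells.

**Marginals.** Fields pass through a rank-based Gaussian anamorphosis
(exact standard-normal sample marginal) before a monotone quantile map —
lognormal X = med * exp(s z) for concentrations (s solved from the target
IQR in closed form), Gaussian for pH. Without the anamorphosis step, the
ergodic fluctuation of a single long-range realization (domain-mean
drift of ~0.3 sd at a 68-km range on a 200-km domain) shifts sample
medians by up to ±20% and starves the upper tails the threshold analyses
probe; with it, medians and IQRs match the configuration exactly while
the spatial rank structure is preserved. Configured medians follow the
regional survey values (southwest TN 3.67 g/kg, NO3-N 14.94 mg/kg, TP
0.71 g/kg); spreads are chosen so the planted thresholds sit in the
well-sampled part of each distribution.

**Response.** SOC = base + structural terms + centered modifier terms +
centered interactions + Gaussian noise (sd 0.5 g/kg). Threshold terms are
logistic-smoothed piecewise-linear segments with smoothness width 2% of
the marginal's 1st-99th percentile span (the Jiaodong nitrate step is set
sharper, width 0.2 mg/kg, reflecting the abrupt transition it emulates).
Modifier and interaction terms are centered by their analytic expectation
under the generating marginal (Gauss-Hermite quadrature), so the partial
dependence of each focal predictor sits at the configured absolute
levels: Jiaodong nitrate plateaus 13.5 -> 16.0 g/kg at 10 mg/kg;
southwest TN plateau 17.5 g/kg rising at 3.25 g/kg with slope 1.54 to a
2.0 g/kg gain; a -3.1%-of-base nitrate drop above 27 mg/kg; two -2.0 g/kg
phosphorus steps at 0.71/0.81 g/kg; CEC rises of +6.7% of base at 10.8
and +2.2 g/kg at 12.1 cmol/kg (relative amplitudes are converted against
the southwest base level 17.5 g/kg). Interactions: a gated iron term
(-1.5 g/kg above Fe = 12 under nitrate limitation, +0.4 above the
nitrate threshold) and a TN x CEC term flipping sign at TN = 4.0 with
amplitude scaled by centered CEC.

**Sampling.** Sites are distinct grid cells drawn uniformly without
replacement (144 for jiaodong, 123 for southwest by default; the
replication experiments use n=500 to give the ML layer realistic power).
An optional composite mode averages k noise draws per site, emulating
five-point composite sampling; true sub-cell covariate variation is below
the grid resolution and is not modelled.

**What the generator does not emulate.** Real geography and terrain,
covariate cross-correlation (fields are independent unless configured),
anisotropy, measurement-method biases, and spatially structured
residuals (noise is white). Passing tests therefore demonstrate that the
pipeline recovers known structure of this idealised class — spatially
autocorrelated, independently distributed covariates with additive
logistic-threshold responses — not that real-soil inference is unbiased.

## Numerical choices and degenerate inputs

- Seeds: one master seed per run; every stochastic stream derives a child
  via `SeedSequence([master, stream_id])`, so reruns are bit-identical.
- Kriging variances and probabilities are clipped to [0, ...] against
  round-off; probability stacks sum to 1 within 1e-9 by construction.
- Constant inputs: normal scores and mean-SD regression raise; a constant
  predictor gets zero importance with a warning; a flat PDP yields an
  empty candidate set and `accepted=False` downstream.
- Variogram fits bound parameters (nugget, partial sill >= 0; range in
  (0, 4 x max lag]) and multi-start over three range and three nugget
  initialisations.
- The replication experiments use 20 replicate datasets (10 for variogram
  recovery), n=500 sites, and medians across replicates — sizes chosen so
  each experiment settles in minutes on a single core while medians are
  stable against the replicate-to-replicate spread.

## Known limitations

- The interval-probability difference maps pair realizations by index;
  with independently simulated ensembles any fixed pairing is
  exchangeable, but rank-matched pairing would give different joint
  statements. Cross-region co-registration is assumed, not computed.
- Shapley enumeration is exponential in p; beyond ~10 predictors the
  subsampled background dominates the cost and p > 14 is refused.
- Segmented fits are limited to two knots, continuity is imposed, and no
  formal breakpoint inference (confidence intervals, Davies test) is
  provided; the adjusted-R^2 gain rule is a parsimony guard, not a test.
- SGS is a per-node loop in Python; hundreds of realizations on grids
  beyond ~10^4 cells get slow.
- The forest's rendering of effects far inside distribution tails is
  noisy; thresholds planted beyond the ~99th percentile would not be
  recoverable at these sample sizes.
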