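# Methods

## The model

`stfield` models the natural log of 2-week average pollutant
concentrations on a fixed 14-day grid anchored on a weekday (Wednesday by
convention; a 2-week sample whose start is off-grid by exactly one week is
treated as if taken one week earlier or later, and any other offset is an
error). The field decomposes as

    C(s,t) = beta_0(s) + sum_{i=1..m} f_i(t) beta_i(s) + nu(s,t).

The coefficient fields beta_i are Gaussian with mean X_i(s) alpha_i and
covariance either `independent` (tau_i^2 I) or `exponential`
(sigma_i^2 exp(-d/phi_i) + tau_i^2 I, d Euclidean in km on an
equirectangular projection about the region centroid — adequate within the
~75 km modeling radius of a metropolitan region). The residual nu is
independent across periods; within a period its covariance is
lambda^2 + sigma_nu^2 exp(-d/phi_nu) + tau_nu^2 I. The lambda^2 term is a
shared random intercept per period capturing region-wide short-term
variation (synoptic meteorology); it is parameterized as a constant added
to the within-period covariance, which is mathematically identical to an
explicit random effect. Both the residual nugget and the time effect are
present by default and can each be fixed at zero.

Key assumptions: the trends f_i capture enough temporal structure that
residuals are independent across periods (a lag-1 autocorrelation
diagnostic is provided); geographic covariates are constant in time;
fields and residuals are jointly Gaussian on the log scale.

## Time trends

The f_i are empirical: the time-by-site matrix of the long-series sites
(regulatory + fixed + reference tiers) is completed by an EM iteration
(missing cells start at column means; each step refills them from the
current rank-k truncated SVD; k = m+1 capped at n-1; tolerance 1e-8 on the
Frobenius change of the imputed block, iteration cap 500), the leading
left singular vectors of the column-centered completed matrix give raw
trends, and each is projected onto a natural cubic spline basis with
round(df_per_year x span_years) total degrees of freedom, knots equally
spaced in time. The spline basis is the closed-form truncated-power
construction with linearity constraints beyond the boundary knots, built
in-package because no installed dependency exposes a natural-spline
*regression* basis. Note one consequence of the natural-spline choice: a
global cubic is not in the basis span (it is not linear beyond the
boundary knots), so "ample df reproduces the raw curve" holds for curves
in the span, which is what the tests assert.

Each trend is normalized to zero mean and unit RMS over the grid — the
model leaves the scale unidentified (it is absorbed by beta_i), and fixing
it makes parameters comparable across fits — and its sign is set so the
loading on the first source site is positive, making estimation
deterministic. Trends are estimated once and then held fixed through
fitting and cross-validation. Smoothed trends are not re-orthogonalized.

## PLS covariate reduction

Each long-series site's observation series is regressed by OLS on
[1, f_1, ..., f_m], giving per-site coefficients gamma_hat. For each trend
index i (including i = 0), a univariate-outcome PLS1 regression of
gamma_hat_i on the covariate matrix of the training sites produces 2 or 3
score directions; covariates are standardized (mean/SD of the training
sites) because they carry wildly different units. The implementation wraps
scikit-learn's NIPALS `PLSRegression` on the pre-standardized matrix; the
fitted score map (center, scale, rotation matrix) is a fixed affine map,
so scores are computable at any location with known covariates and scoring
the training sites reproduces the training scores exactly. Training uses
all long-series tiers; skewed covariates (distances) are expected to be
log-transformed upstream in the input table.

## Likelihood, gradient and fitting

With F_i the diagonal-in-site expansion of f_i(t), the marginal covariance
of the stacked observations is V = sum_i F_i Sigma_i F_i' +
blockdiag_t(B_t). The mean coefficients alpha are profiled by GLS at every
covariance evaluation (their ML values given the covariance), and the
profile log-likelihood is evaluated with the matrix determinant lemma and
the Woodbury identity: per-period residual blocks are factorized once per
distinct observed-site set (periods sharing a site pattern share one
Cholesky), the inner matrix Sigma_beta^{-1} + F'B^{-1}F of dimension
(m+1) x n_sites is factorized once, and all per-period sums reduce to
precomputed cross-products, so per-evaluation cost is independent of the
number of periods for balanced stretches. The gradient is analytic
(envelope theorem at the profiled alpha), with trace terms assembled from
the same factorizations. A dense N x N implementation exists only in the
test suite and in the acceptance script, as the independent reference.

Optimization: L-BFGS-B on log-transformed parameters (positivity by
construction; bounds +-18 on the log scale), iteration cap 500 by default,
multi-start (default 3 seeded starts with multiplicative jitter around a
moment-style initial guess: total variance split across components, ranges
at a quarter of the region diameter), keeping the best optimum. ML, not
REML. Fitting is deterministic given (data, init, seed).

Identifiability notes observed in simulation: the range parameters are
weakly identified (checked to order of magnitude only); the beta_0 nugget
and sill are mutually confounded at short range (their sum is well
identified; an exponential with vanishing range is likelihood-equivalent
to a nugget, so diagnostics should look at the fitted covariance at
typical distances rather than at individual parameters).

## Prediction

Predictions are conditional expectations under the fitted Gaussian model
given all observations in the region, with the GLS alpha plugged in,
computed through the same Woodbury state. Cross-covariance convention: a
target at zero distance from a monitored site shares that site's
coefficient-field values (including their nuggets) but draws a fresh
residual sample — the residual nugget does not transfer. Consequently a
collocated target reproduces the observation exactly only in the
vanishing-nugget limit. Targets far from all monitors revert to the
covariate-driven mean surface plus the per-period time-effect adjustment.
Back-transformation is plain exponentiation (no lognormal sigma^2/2
correction; a corrected option exists but is off by default), and
long-term averages are arithmetic means of the back-transformed 2-week
predictions over the requested date range — averaging before
exponentiation would give the (smaller) geometric mean. Plug-in kriging
standard errors are available on request (`compute_se=True`); they are
exact but quadratic in per-period site count, so off by default for large
grids.

## Cleaning rules

Below-detection values are replaced by LOD/2 at the native resolution,
before any averaging. Hourly records average to days and days to periods,
each step requiring 75% completeness (the conventional regulatory
criterion; configurable); incomplete periods are absent, not zero.
Regulatory monitors with under 2 years of span are dropped, as are those
with irregular coverage, operationalized as any calendar quarter holding
under 10% of the site's observations (generalizing the summer-only case;
configurable). Covariates are excluded when (a) one value occurs at >80%
of monitoring sites, (b) >2% of monitoring-site values lie >5 SD from the
mean, (c) the participant-location SD exceeds 5x the monitoring-location
SD, or (d) a land-use fraction's maximum over monitors is <=10% (read as
"at most"; threshold configurable). The excluded set is the union of rule
hits; the first rule in a-d order is reported as primary. Samples
straddling the axis end are dropped and counted.

## Cross-validation and model selection

LTAs at left-out sites are the evaluation target, stratified by tier:
leave-one-out for long-series sites, 10-fold for home/distributed sites,
cluster-respecting 10-fold for snapshot sites (fold assignment is random
with a fixed seed; no further stratification). Per fold, covariance
parameters are re-estimated by ML on the retained sites — warm-started
from the full-data fit with a single start — while trends and PLS score
definitions stay fixed; alpha is re-profiled per fold as a GLS by-product.
Metrics are computed on per-site means of back-transformed values:
RMSE, R2_CV = max(0, 1 - RMSE^2/MSE_obs) (fit to the 1-1 line), and
R2_CVreg (squared correlation). The temporally adjusted variants replace
MSE_obs with the MSE of a reference predictor evaluated on site means —
regional average of long-series observations at the site's observed
periods (Avg), the nearest long-series site's observations (Close), or its
fitted smooth trend curve (Smooth); site-periods without reference data
are dropped and counted.

The selection grid enumerates all 16 candidates: trends {1,2} x spline
df/year {4,8} x PLS scores {2,3} x spatial smoothing of the beta fields
{exponential, independent}, toggling beta_0 and beta_i smoothing together
(reported separately; the workflow config allows decoupling them). Ranking
prioritizes home-site R2_CV, then home-site RMSE; failed candidates are
recorded and ranked last.

## Synthetic campaigns

The generator reproduces the multi-tier design from known parameters:
regulatory sites observe the whole axis minus random gap stretches
(default 10% of the record), fixed sites observe one contiguous ~4-year
campaign window, home sites get 1-3 visits in distinct seasons (calendar
quarters) inside that window, and snapshot clusters share three seasonal
periods — winter, summer, and one of spring/fall. Informative covariates
are smooth unit-variance Gaussian fields (exponential correlation, 15 km
default range), distance-like covariates are lognormal transforms of such
fields, and noise covariates are i.i.d. normal. Default generating
parameters are sized for log PM2.5 in a mid-sized U.S. metropolitan
region: long-term mean exp(2.56) ~ 13 ug/m3 with covariate-driven spatial
SD ~0.3 on the log scale, beta_0 exponential (phi 10 km, sill 0.03, nugget
0.005), seasonal amplitude ~0.3 with independent site variation 0.005, and
residual (lambda^2 0.03, spatial 0.015 at 20 km range, nugget 0.01) —
two-week residual SD ~0.23, consistent with the week-to-week variability
regulatory series show. The default campaign has 29 regulatory, 5 fixed,
86 home and 26x4 snapshot sites over 13.25 years. Optional LOD censoring
replaces the bottom quantile (e.g. 1%) with LOD/2.

What the generator does not emulate: real meteorology or chemistry,
non-Gaussian tails, temporally varying covariates, spatially anisotropic
correlation, or instrument-specific error structure. Passing recovery
tests therefore demonstrate that the machinery is correct under the
model's own assumptions — not that the model is adequate for any
particular real campaign.

## Study problem sizes

The quantitative studies are sized to run comfortably on one CPU:

- Oracle agreement: 25 random instances up to 15 sites x 25 periods with
  random covariance structures and unbalanced patterns.
- Parameter recovery: 20 replicates of 100 sites x 50 periods, complete
  panels. The mean-coefficient unbiasedness check is the joint chi-square
  test on the six Monte-Carlo z-scores at the 95% level (a per-coefficient
  2-SE rule would false-alarm on ~1 in 4 runs with six coefficients) plus
  a 3.5-SE per-coefficient cap.
- End-to-end LTA recovery: one full pipeline run at the default
  metropolitan scale (~220 sites, 13.25 years, ~10,000 observations).
- Trend-count selection consistency: 10 replicates of a compact two-trend
  scenario (10 regulatory, 2 fixed, 24 home sites, 4 years), each running
  the full 16-candidate grid with home-stratum 10-fold CV and per-fold ML
  refits. The scenario generates the second trend with a covariate-driven,
  spatially heterogeneous coefficient field (weight equal to the long-term
  mean's): a spatially near-constant trend is absorbed by the per-period
  time random effect and is then — correctly — not worth a candidate trend
  for held-out-site prediction, so the study design places the signal
  where trend count matters.

## Known limitations

- Likelihood cost grows with the number of *distinct* observation
  patterns; pathological designs where every period observes a different
  site set lose the pattern-sharing speedup (the batched path still
  applies).
- Kriging standard errors ignore the uncertainty of alpha and of the
  covariance parameters (plug-in).
- The EM/SVD trend estimator absorbs the shared time effect into the raw
  trend; spline smoothing removes most of it, but trend estimates degrade
  as lambda^2 grows relative to the seasonal amplitude.
- Exponential covariance only; no anisotropy, no spatiotemporal
  covariates in the mean (the framework extends to them, but they are out
  of scope here).
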