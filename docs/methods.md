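# Methods

## The forecasting problem

The target is a regular series of admission counts on a half-month grid: two
bins per calendar month (days 1–15 and 16–end), 24 per year.  Admissions are
strongly seasonal (September–November peak), overdispersed, and plausibly
driven by lagged environmental conditions (temperature anomalies, vegetation
moisture, the El Niño state).  The package forecasts 1–12 fortnights ahead
with calibrated intervals, combining heterogeneous models rather than betting
on one.

## Preprocessing

**Duplicate removal.**  Clinical line lists contain re-recordings of the same
animal within days of admission.  Records are grouped into (clinic, species)
streams; within a stream, any record within `window_days` (default 14 — one
fortnight) after the most recently *retained* record is dropped.  The pass is
greedy and idempotent.  Without animal identifiers this also merges distinct
admissions that land close together in a busy stream; that is the price of
dedup on abstracted records and is reproduced faithfully by the synthetic
generator.  Improbable records are retained (the abstraction is assumed ~95%
specific), which slightly dilutes seasonality.

**STL.**  The additive seasonal–trend decomposition by Loess uses period 24,
a large seasonal smoother window (default 99, near-periodic) and no robust
downweighting; both knobs are exposed.  The seasonally adjusted series is
trend + remainder; seasonal + trend + remainder reconstructs the input to
machine precision by construction.  Stationarity of the adjusted series is
checked by an augmented Dickey–Fuller regression with a constant and
AIC-selected lag order.

**Engineered predictors.**  The moist-vegetation index is computed exactly as
published, `rainfall × (−evapotranspiration) × (shrub + forest cover)`.  That
printed arithmetic makes the index non-positive and *decreasing* in rainfall,
which contradicts its stated intent (wetter = more moisture); a config flag
(`intended_form=True`) provides `rainfall / (1 + ET) × cover` for users who
want the monotone form, and the synthetic generator drives admissions through
the monotone form.  Quarterly anomalies compare each calendar quarter's mean
to the long-term mean of that quarter-of-year, computed over the training
window only so validation data can never leak into the climatology.  A series
repeating identically every year therefore has anomaly ≡ 0.

**Collinearity pruning and lags.**  While any retained pair of predictors has
|Pearson r| > 0.70, the lower-priority member of the worst pair is dropped;
the priority list is explicit config whose default keeps maximum over minimum
temperature and anomaly over raw NDVI.  Each survivor gets the lag (1–6
fortnights) maximizing |cross-correlation| with the seasonally adjusted
series on the training window (ties to the smaller lag), then unit-variance
scaling by training-window moments.  A predictor whose best |r| is below a
configurable threshold (default 0.10) is flagged weak but kept.

## Forecast members

All members emit forecasts as S sample trajectories per horizon (default
1,000), so the ensemble combiner and the particle filter share one
representation; medians and 80/95% intervals are path quantiles, and interval
endpoints are ordered by construction.

**ARIMA (seasonally adjusted scale).**  For every predictor subset up to five
covariates and every (p, d, q) in the order grid, a Gaussian ARIMA with
exogenous regressors is fitted; the subset + orders minimizing in-sample BIC
win.  Forecast paths are innovation simulations from the fitted model.
The default order grid in the orchestration layer is small (p, q ≤ 1–2,
d ≤ 1) to keep the combinatorial search affordable; it is a plain argument.

**GARCH-type (seasonally adjusted scale).**  Mean = intercept + linear
predictor terms + two moving-average innovation lags; conditional variance
σ²ₜ = ω + a₁ε²ₜ₋₁ + a₂ε²ₜ₋₂ (volatility clustering over ~1 month).  All
predictors enter simultaneously with Laplace(0, 0.5) priors — the prior
expectation that most environmental effects are small — plus weakly
informative priors elsewhere (N(0, 10) intercept, N(0, 1) MA terms, a
log-normal on ω centred at the sample variance, uniform ARCH terms with
a₁ + a₂ < 1).  The posterior is sampled with the affine-invariant ensemble
sampler (emcee) from a Nelder–Mead MAP start; walkers are pooled and thinned
to 1,000 retained draws, and split R-hat (walkers grouped into four
pseudo-chains) above 1.05 flags the fit as non-converged so callers can
exclude it from the ensemble.  Forecast paths draw one posterior sample per
trajectory (posterior predictive).

**Negative-binomial GAM (raw counts).**  log μ = intercept + unpenalized
cubic regression spline in continuous year (default 6 df) + cyclic cubic
spline in fortnight-of-year with period 24 (default 8 df; fortnight 25 ≡ 1)
+ one cubic regression spline per predictor (default 5 df) carrying a ridge
("shrinkage") penalty that can drive the whole term to ~0 effective degrees
of freedom.  Estimation is penalized IRLS (Fisher scoring for the log link
with NB variance μ + μ²/φ); smoothing strengths minimize
GCV = n·deviance/(n − γ·edf)² with γ = 1.4, the usual inflation guarding
against GCV undersmoothing, by coordinate descent over a log-spaced grid.
Penalty blocks are rescaled to their design-block magnitude so one grid works
for all terms.  φ is profiled by maximum likelihood in an outer loop.
Forecast paths draw coefficients from the Gaussian approximation
N(β̂, (XᵀWX + S)⁻¹) and then NB counts.  A moving-average residual structure
is *not* modelled; forecast paths treat counts as conditionally independent
given μ, which slightly understates very-short-horizon autocorrelation.

**Prophet-style trend regression (log(x+1) counts).**  Linear-in-parameters
decomposable model: piecewise-linear trend with 25 candidate changepoints in
the first 80% of training and a sparse Laplace prior (scale 0.50, deliberately
loose to let the trend bend), order-10 Fourier seasonality with period 24,
and the three predictors that individually minimize Gaussian deviance in a
trend+seasonality base model.  The MAP is found by L-BFGS on a smoothed-|x|
objective (the problem is convex); the observation noise scale is updated by
alternation.  Forecast uncertainty combines (i) the Gaussian posterior
approximation of the non-changepoint coefficients, (ii) observation noise,
and (iii) simulated future changepoints occurring at the historical rate with
Laplace magnitudes matching the mean fitted |δ| — the same device the
original Prophet model uses.  Paths are back-transformed by exp(·) − 1 and
floored at zero.

**ETS.**  Additive exponential smoothing state-space models with
error/trend(/damped)/seasonal components selected by AICc, used twice: as the
benchmark on log(x+1) counts (back-transformed, floored at zero) and as the
seasonal-component forecaster whose paths restore seasonality for the
seasonally adjusted members (pathwise addition, independent pairing by path
index, floored at zero on the count scale — negative admissions are
meaningless).

**Covariates at forecast time.**  All predictors are lagged ≥ 1 fortnight, so
the forecast at horizon h uses the covariate observed at t + h − lag, which is
available whenever h ≤ lag.  Beyond that, last-value-carried-forward
persistence is used by default; with persistence disabled the forecast
refuses and lists the missing inputs.

## The ensemble

The interval score of a central 95% interval is its width plus 2/α times the
distance by which the observation escapes it (α = 0.05).  The printed source
formula reads "2α"; the standard (Gneiting–Raftery) scoring rule uses 2/α,
and the two can disagree about the optimal weighting, so both conventions are
implemented (`penalty_convention`), defaulting to 2/α.  No scaling
denominator is applied by default; optional scaling by the in-sample
seasonal-naive MAE is available (`scale_denominator`).

Member 95% intervals (and medians) are combined by weighted quantile
averaging.  Weights are constant across horizons and live on the simplex,
enforced by a softmax reparameterization; optimization is multi-start
Nelder–Mead (default 25 restarts, seeded) and every simplex corner is
evaluated explicitly, so the optimized validation score can never exceed the
best single member's.  For ≤ 3 members an exhaustive 0.01-step grid search is
provided as an oracle; the optimizer matches it to < 1e-6 in mean score.

## Sequential Monte Carlo assimilation

The two seasonally adjusted members are adapted to incoming observations
without refitting.  Each of N = 5,000 particles is one forecast trajectory:
for the ARIMA member, the terminal training state of the fitted recursion
(lagged differenced values, lagged innovations, last level), advanced by
simulated innovations; for the GARCH member, one posterior parameter draw
plus its two lagged innovations, so resampling also sharpens the parameter
cloud.  Incoming counts are moved to the seasonally adjusted scale by
subtracting the seasonal ETS forecast of the STL seasonal component.

Assimilating an observation multiplies each particle's accumulated weight by
the Gaussian likelihood of the observation given the particle's one-step
proposal; the bookkeeping is in log space because multiplying raw likelihoods
underflows within a handful of steps.  The observation scale defaults to the
member's residual sd (per-clinic filters re-initialize it from an
ARIMA(1,0,1) fit to that clinic's seasonally adjusted series).  When the
effective sample size 1/Σw² drops below `ess_threshold_fraction × N`
(default 0.5, i.e. N/2), particles are resampled with replacement in
proportion to their weights (multinomial by default, systematic available),
trajectory states — not parameter draws — receive Gaussian random-walk jitter
of scale `mutation_sd` (default 10% of the observation scale; "small" is the
only guidance available, so it is config), and weights reset to uniform.
"Reset to 1" is interpreted as standard sequential importance resampling —
uniform normalized weights — rather than unnormalized raw 1s with history.

On a linear-Gaussian AR(1) state space the filter's posterior mean and
variance match the exact Kalman recursion within replicate-estimated
Monte-Carlo error, and with mutation off and resampling suppressed the
accumulated log-weights equal the summed per-step log-likelihoods exactly.

## Evaluation protocol

The series splits 85/15: training = ⌈0.85 T⌉ observations; the held-out
remainder gives the weight-optimization validation window (everything before
the final season) and the test window (the final season, up to 24
fortnights).  An 11-year series (264 bins) therefore splits 225/15/24.

Rolling evaluation advances the training cut-point one fortnight at a time.
At each origin the STL decomposition, anomaly climatology, collinearity
pruning, lag selection and scaling are recomputed from data up to the origin
only — perturbing later observations leaves an origin's forecasts
bit-identical (tested).  Two update modes exist: `retrained` refits every
member; `pf` fits the seasonally adjusted members once and thereafter
assimilates new observations by particle filter, while the GAM and
Prophet-style members refit and the ETS benchmark always refits.  Point error
is the absolute error of the forecast median (the natural point summary of an
interval forecast; a mean-based variant is a flag away), and interval scores
are computed at the 95% level.  Horizon bands are near-term 1–6 and
medium-term 6–12 fortnights; fortnight 6 belongs to both, exactly as the
week-based bands 2–12 and 12–24 share week 12.  Spline-smoothed score-trend
curves with wide (99%) bands are available for plotting only; all reported
metrics are unsmoothed.

## The synthetic-data module

The generator emulates the structure of an 11-year fortnightly admission
series from five clinics: counts are negative binomial
(λₜ = φ/(φ + μₜ), default φ = 5) with log μ = log baseline (default 2
admissions/fortnight ≈ 520 cases over 11 years) + log seasonal factor
(monthly relative rates peaking September–November, normalized to mean 1) +
piecewise-linear trend (default: decline into a mid-series trough, recovery
afterwards) + Σ effects on lagged unit-scaled predictors (defaults: maximum
temperature anomaly at lag 2 with −0.25, SOI at lag 2 with +0.15, moist
vegetation at lag 6 with +0.10, matching the directions and lags the study
system reports).  Counts are expanded to dated records with clinic, species
(77% dogs) and record class; ~50% of admissions are re-recorded within 14
days (766 retrieved vs 520 retained implies roughly one duplicate per two
admissions) and improbable records are injected uniformly over the year at
5%, diluting seasonality the way real misclassification would.  Climate
covariates are seasonal means plus AR(1) noise (NDVI noise more persistent,
reflecting its monthly native resolution — this also reproduces the
raw-vs-anomaly collinearity that motivates pruning); SOI is zero-mean AR(1);
land cover changes only between years.  Ground truth (per-fortnight μ and
counts) is returned in a separate table so pipeline code cannot consume it.

What the generator does *not* emulate: spatial structure within the study
area, covariate measurement error, reporting delays, multi-year tick cycles,
or changes in clinic participation.  Green tests therefore demonstrate that
the machinery recovers known structure under realistic noise — not that the
models are correct for any particular real dataset.

## Numerical and design choices

* "ARIMA(0,2) mean" for the GARCH-type member is read as a pure MA(2) mean
  process, consistent with "both the mean and variance were influenced by two
  moving average lags"; alternatives are a config away.
* The Prophet-style member takes the *three* best predictors by deviance
  (the described selection procedure), configurable.
* Posterior draws are pooled across walkers and thinned to 1,000; the
  Prophet-style member uses a Gaussian approximation at the MAP instead of
  MCMC — its posterior is log-concave and the approximation is cheap and
  reproducible.
* Fortnight boundary fixed at day 15/16 ("evenly sized" is impossible for
  29–31-day months).
* Count-scale truncation at zero after every back-transform or pathwise
  addition.
* Weighted quantiles in the particle filter use the interpolated inverse-CDF;
  forecast distributions are materialized by resampling particles in
  proportion to weight.
* Scaled-down problem sizes in the test-suite and acceptance script (e.g.
  2,000–5,000 particles, 10–20 replicates, small ARIMA order grids) are the
  package's own choice of demonstration scale; all sizes are arguments.

## Known limitations

* Covariate forecasting is out of scope: beyond each predictor's lag the
  forecasts rely on last-value persistence.
* The GAM omits the residual moving-average structure (uncertainty, not mean).
* The particle filter learns no static parameters beyond random-walk drift of
  trajectory states (coefficient drift is behind a config flag and off by
  default); it is a plain bootstrap filter, not auxiliary or
  Rao-Blackwellized.
* Ensemble weights are constant over time and horizons; time-varying
  weighting is explicitly out of scope.
* Clinic-level adaptation assumes each clinic series spans ≥ 2 seasonal
  cycles and shares the aggregate model's parameters except the observation
  noise scale.
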