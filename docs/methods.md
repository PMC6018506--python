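# Methods

## Data model and rate construction

The unit of observation is a condemned carcass record (day, state,
slaughterhouse, cattle type, condemnation reason).  Cattle types (9) and
condemnation reasons (35) are closed vocabularies; rows outside them are
rejected at parse time with a logged cause, never silently dropped or
coerced.  The named reasons follow standard US postmortem disposition
categories; any closed 35-category set works identically, since the analysis
only groups by category.

Monthly rates divide condemned counts by slaughtered head counts, which are
only available per calendar month — hence daily records are aggregated to
months before any modelling.  A month's key comes from the slaughter date;
no time zones.  A zero denominator yields a missing rate for that month and
the month is skipped by the Kalman filter (prediction without update) rather
than interpolated.  Cross-tabulation percentages are rounded half-up to two
decimals for presentation; unrounded ratios are retained.

## Seasonality screening

Each mean-removed series gets an AR(p) model by Burg's method (stable
spectral factorisation on short series even at high order; Yule-Walker is
available as an option), with p chosen by AIC = N log(sigma_hat^2) + 2p over
p = 1..24, ties to the smaller order.  The implied spectrum is evaluated on
512 frequencies in (0, 0.5] cycles/month, giving a period resolution of
about 0.14 months near the annual peak.

Pronounced peaks are strict interior local maxima whose prominence on the
**log-power** scale exceeds 5% of the spectrum's log-power dynamic range.
The log scale matters: AR spectral peak heights grow roughly quadratically
with component strength, so on a linear scale a genuine 6-month harmonic at
~10% of the annual component's variance shows up at ~1% of the annual peak's
power and a linear threshold can never keep it while rejecting noise.  Peak
periods are reported to one decimal.

A series is seasonal iff some peak lies within 1.5 months of the 12-month
annual period and a *different* peak lies within 0.3 months of a theoretical
harmonic {6, 4, 3, 2.4, 2} (= 12/j, j = 2..6).  The annual tolerance is
deliberately loose (short records resolve the annual cycle coarsely; a peak
at 13.3 months is still the annual cycle); the harmonic tolerance is tight
because harmonic periods are closely spaced.  Both are configurable and
echoed in every report.  Enlarging either tolerance can only add matches,
so the verdict is monotone in the tolerances.

## DHR estimation

State vector `[L, l, alpha_1, beta_1, ..., alpha_n, beta_n]`; IRW trend
(level + slope) and one random-walk pair per harmonic; observation row
`[1, 0, cos(2 pi f_i t), sin(2 pi f_i t), ...]`.  Estimation choices:

* **Harmonic set.**  By default the AR-spectrum peak periods at or below
  13.5 months, rounded to one decimal, are used as `period_i` (multiannual
  peaks are left to the trend).  A peak additionally needs at least 1% of
  the strongest seasonal peak's power to enter the model: marginal wiggles
  that pass the prominence screen otherwise bloat the state vector, and the
  spectral hyperparameter fit can then degenerate into interpolating the
  data (noise variance driven to ~0).  The fixed theoretical set is
  available by passing `periods=[12, 6, ...]`.
* **NVR estimation.**  Least squares between log AR spectrum and log DHR
  pseudo-spectrum over the grid, excluding points within one step of a
  harmonic singularity.  log sigma^2 is an additive offset in log power and
  is concentrated out analytically; the remaining log10-NVRs are optimized
  by L-BFGS-B from three deterministic starts (-2, -4, -6), bounds
  [1e-12, 10].  The lower bound sits far below any plausible NVR on
  purpose: the IRW trend spectrum grows as f^-4, so even an NVR pinned at
  1e-8 injects visible low-frequency power and biases the other components
  on series with no trend at all.  Non-convergence returns the best iterate
  with a warning flag.
* **sigma^2 refinement.**  After the spectral fit, sigma^2 is rescaled by
  the mean squared standardized innovation (the likelihood's concentration
  point).  Rescaling all variances by one factor leaves gains and state
  means unchanged, so this only calibrates the uncertainty bands; a
  discrepancy beyond 2x is logged.
* **Initialization.**  Finite diffuse prior: zero mean, covariance 1e7 x
  series variance on every state.  The first `dim` innovations are excluded
  from the likelihood.  The filter uses Joseph-form updates; the smoother is
  Rauch-Tung-Striebel with a pseudo-inverse fallback for the rank-deficient
  noise-free limit.
* **Components and fit.**  `L` and `Q` come from the smoothed states;
  `e = Y - L - Q` by definition, so the decomposition identity is exact.
  `R_t^2 = 1 - var(e)/var(Y)` is computed on the smoothed fit by default
  (the filtered variant is also exposed).  Smoothed `R_t^2` is an
  *optimistic* measure: the smoother uses the whole record and absorbs part
  of the observation noise, especially when the spectrally estimated NVRs
  are biased upward (see below).

## Forecasting and evaluation

Forecasts propagate the last filtered state with no updates; the point
forecast is the observation row applied to the predicted state, the band is
+/-2 x the predicted observation standard error (about 95% nominal
coverage).  By construction the h-step forecast from origin t equals the
filter's prediction at t+h when the intermediate observations are withheld.

Rolling-origin evaluation walks origins m from the training end to the end
of the record, pairing each h-step forecast of month m+h with the
observation, and summarises per horizon with
`MRPE(%) = mean[((Y - Yhat)/Y)^2] x 100`.  Note the statistic averages
*squared* relative errors without a square root — unusual, but it is the
convention these condemnation-rate series are reported with, and it is
implemented verbatim; an RMS variant sits behind `rms=True` for
comparability with other literature.  Months with Y = 0 are excluded with a
logged count (the relative error is undefined there).  Two modes: `frozen`
(default) keeps the training-window NVRs and sigma^2 and only updates the
filtered state through each origin, which is cheap and deterministic;
`reestimate` refits the hyperparameters through each origin.  Pooling all
origins per horizon is the default; `pool="last"` keeps only the forecast
targeting the final month.

The deterministic trend-slope summary (used to label every reason
increasing / stable / decreasing) is the NVR = 0 limit of the IRW smoother,
which is exactly a straight-line fit; it matches the OLS slope to better
than 1e-8.  For this degenerate case the filter uses a 1e8 x variance prior
anchored at the first observation — larger priors lose float precision,
smaller ones shrink the slope visibly; 1e8 balances the two (verified to
<1e-8 against OLS across 1000 random fixtures during development).  The
stable band is |slope| < 1e-7 per month, configurable.

## Synthetic data

The generator produces exactly the structure the analysis assumes: IRW
trend, RW-modulated harmonics, Gaussian observation noise, and — for
record-level data — monthly condemned counts drawn binomial(denominator,
true rate), spread uniformly over days, with cattle types drawn from a
dairy-dominated mixture and deterministic seasonal slaughter denominators
(~115,000 head/month, +/-6%).  Binomial rather than Poisson counts keep
rates bounded in [0, 1].  Composed rates are clipped to [0, 1] with a
warning; scenarios that would clip more than 5% of months are rejected.

The default scenario has five reasons: an emaciation-like series (strong
12+6-month harmonics, declining trend, baseline 8.5e-4), a lymphoma-like
series (12+6-month harmonics, larger trend NVR for multiannual drift,
baseline 4e-3), a weak low-rate myositis-like series (baseline 2.6e-4), and
two trend-only controls.  Baselines are on the scale of real per-head
monthly condemnation rates.  Signal-to-noise is calibrated so the fitted
R_t^2 of the three seasonal series lands in the 0.78-0.98 range typical of
real slaughter-surveillance series — a calibration choice, not an empirical
claim.  At low baseline rates the binomial sampling noise (sd ~ sqrt(p/m))
dominates the Gaussian noise term, which is why the weak series needed the
largest relative amplitudes.

What passing tests on these data do **not** show: robustness to reporting
artifacts (plant closures, recording changes), overdispersion beyond
binomial, spatial heterogeneity across slaughterhouses, or covariate-driven
seasonality — none of which the generator emulates.

## Known limitations

* The frequency-domain NVR estimator inherits the AR spectrum's finite peak
  bandwidth (~1/N), which inflates harmonic NVRs by roughly a factor 5-8
  (median log10 error ~ +0.8 at N = 120) while trend NVRs are mildly
  underestimated.  Component estimates and forecasts are much less affected
  (seasonal-component correlation with truth ~ 0.99 median), but the NVRs
  themselves should be read as smoothing bandwidths, not physical variances.
* The finite diffuse prior loses ~1e-8 of absolute state accuracy in the
  first updates when the assumed sigma^2 is an order of magnitude below the
  data variance at 8 states; an exact-diffuse or square-root filter would
  remove this.
* MRPE is undefined at zero observations and unstable near them; for very
  low-rate reasons an absolute or count-scale error measure would be more
  appropriate.
* Seasonality screening is a point decision with no significance test; the
  false-positive rate of the default thresholds (~2-8% on trend-plus-noise
  controls) is measured by simulation, not controlled analytically.
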