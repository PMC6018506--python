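"""Dynamic harmonic regression: hyperparameter estimation, fitting, forecasting.

The free hyperparameters of the DHR state-space model are the noise-variance
ratios (NVRs) of the trend and of each harmonic, plus the observation-noise
variance sigma2.  They are estimated in the frequency domain: the theoretical
pseudo-spectrum implied by the DHR model (IRW trend spectrum + shifted
random-walk spectra at each harmonic frequency + white-noise floor) is fitted
to the AR spectrum of the data by least squares on the log scale.  The fitted
model is then run through the Kalman filter/smoother to decompose the series
into trend L(t), seasonal Q(t) and irregular e(t), to score the fit, and to
produce multi-step forecasts with +/- 2 SE bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from . import periodicity as _per
from .data import RateSeries
from .statespace import (DIFFUSE_SCALE, DHRModelSpec, FilterResult,
                         SmoothResult, build_state_space, kalman_filter,
                         kalman_smooth, observation_matrix)

logger = logging.getLogger(__name__)

#: log10-NVR search bounds for the spectral optimizer.  The lower bound must
#: sit well below any plausible NVR: even 1e-8 of trend NVR injects visible
#: power at the lowest grid frequencies (the IRW spectrum grows as f^-4) and
#: biases the fit when the data carry no low-frequency power at all.
NVR_LOG10_BOUNDS = (-12.0, 1.0)
#: Deterministic multi-start points (log10 NVR, applied to every component).
NVR_STARTS = (-2.0, -4.0, -6.0)
#: Harmonic periods longer than this are treated as trend, not seasonality.
MAX_SEASONAL_PERIOD = 13.5
#: A detected peak enters the harmonic set only if its power is at least this
#: fraction of the strongest seasonal peak; marginal wiggles that pass the
#: prominence screen would otherwise bloat the state vector and let the
#: spectral NVR fit degenerate into interpolation.
HARMONIC_POWER_FLOOR = 0.01


def dhr_model_spectrum(spec: DHRModelSpec, grid: np.ndarray) -> np.ndarray:
    """Pseudo-spectrum of the DHR model on ``grid`` (cycles/month).

    S(f) = sigma2 * { nvr_trend / [2(1-cos 2 pi f)]^m
                      + sum_i (nvr_i/2) * (1/[2(1-cos 2 pi (f-f_i))]
                                           + 1/[2(1-cos 2 pi (f+f_i))])
                      + 1 }

    with m = 2 for the IRW trend and m = 1 for an RW trend.  Grid points at
    the singularities f = 0 or f = +/- f_i are a hard error; offset the grid
    by half a step instead.
    """
    grid = np.asarray(grid, dtype=float)
    step = np.min(np.diff(grid)) if len(grid) > 1 else 1e-3
    eps = 1e-9
    if np.any(np.abs(grid) < eps):
        raise ValueError("grid contains the trend singularity f = 0")
    shape = _dhr_spectrum_shape(spec, grid, eps)
    return spec.sigma2 * shape


def _rw_spectrum(f: np.ndarray) -> np.ndarray:
    return 1.0 / (2.0 * (1.0 - np.cos(2.0 * np.pi * f)))


def _dhr_spectrum_shape(spec: DHRModelSpec, grid: np.ndarray,
                        eps: float = 1e-9) -> np.ndarray:
    """Spectrum divided by sigma2; raises on singular grid points."""
    for f_i in spec.frequencies:
        if np.any(np.abs(grid - f_i) < eps) or np.any(np.abs(grid + f_i) < eps):
            raise ValueError(f"grid contains the harmonic singularity f = {f_i:g}")
    m = 2 if spec.trend == "irw" else 1
    shape = spec.nvr_trend * _rw_spectrum(grid) ** m + 1.0
    for f_i, nvr in zip(spec.frequencies, spec.nvr_harmonics):
        shape = shape + 0.5 * nvr * (_rw_spectrum(grid - f_i) + _rw_spectrum(grid + f_i))
    return shape


@dataclass
class NVROptimization:
    """Result of the frequency-domain NVR fit."""

    nvr_trend: float
    nvr_harmonics: tuple[float, ...]
    sigma2: float
    objective: float
    converged: bool
    n_grid: int


def optimize_nvr(ar_spec: _per.ARSpectrum, frequencies: tuple[float, ...],
                 *, trend: str = "irw",
                 log10_bounds: tuple[float, float] = NVR_LOG10_BOUNDS,
                 starts: tuple[float, ...] = NVR_STARTS,
                 tol: float = 1e-14) -> NVROptimization:
    """Fit NVRs and sigma2 by matching the DHR pseudo-spectrum to the AR
    spectrum in log power.

    The objective sum_k [log S_AR(f_k) - log S_DHR(f_k)]^2 is minimised over
    log10-NVRs by bounded quasi-Newton search (L-BFGS-B) from a deterministic
    grid of starts; log sigma2 enters as an additive offset and is
    concentrated out analytically.  Grid points within one step of a harmonic
    singularity are excluded.
    """
    grid = ar_spec.frequency_grid
    step = grid[1] - grid[0] if len(grid) > 1 else 1e-3
    mask = np.ones(len(grid), dtype=bool)
    for f_i in frequencies:
        mask &= np.abs(grid - f_i) > 0.75 * step
    g = grid[mask]
    log_sar = np.log(ar_spec.power[mask])
    n_par = 1 + len(frequencies)

    def unpack(theta: np.ndarray) -> DHRModelSpec:
        nvrs = 10.0 ** np.asarray(theta, dtype=float)
        return DHRModelSpec(frequencies=tuple(frequencies), nvr_trend=nvrs[0],
                            nvr_harmonics=tuple(nvrs[1:]), sigma2=1.0, trend=trend)

    def objective(theta: np.ndarray) -> float:
        shape = _dhr_spectrum_shape(unpack(theta), g)
        resid = log_sar - np.log(shape)
        resid = resid - resid.mean()  # concentrates out log sigma2
        return float(resid @ resid)

    best = None
    any_success = False
    for s in starts:
        theta0 = np.full(n_par, s)
        res = scipy.optimize.minimize(objective, theta0, method="L-BFGS-B",
                                      bounds=[log10_bounds] * n_par,
                                      options={"ftol": tol, "gtol": 1e-10,
                                               "maxiter": 500})
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_success:
        logger.warning("NVR optimization did not converge; best iterate returned")
    nvrs = 10.0 ** best.x
    shape = _dhr_spectrum_shape(unpack(best.x), g)
    log_sigma2 = float(np.mean(log_sar - np.log(shape)))
    return NVROptimization(nvr_trend=float(nvrs[0]),
                           nvr_harmonics=tuple(float(v) for v in nvrs[1:]),
                           sigma2=float(np.exp(log_sigma2)),
                           objective=float(best.fun), converged=any_success,
                           n_grid=int(mask.sum()))


@dataclass
class DHRFit:
    """A fitted DHR decomposition Y(t) = L(t) + Q(t) + e(t).

    ``fitted`` = L + Q (smoothed); the residual e is defined as Y - L - Q, so
    the decomposition identity holds exactly at every observed sample.
    """

    spec: DHRModelSpec
    y: np.ndarray = field(repr=False)
    t_index: np.ndarray = field(repr=False)
    months: pd.PeriodIndex | None
    filtered: FilterResult = field(repr=False)
    smoothed: SmoothResult = field(repr=False)
    trend: np.ndarray = field(repr=False)
    slope: np.ndarray = field(repr=False)
    seasonal: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    r_squared: float
    r_squared_filtered: float
    loglik: float
    nvr_info: NVROptimization | None = None
    ar_spectrum: _per.ARSpectrum | None = field(default=None, repr=False)
    periodicity: _per.PeriodicityReport | None = None

    @property
    def periods(self) -> tuple[float, ...]:
        return tuple(1.0 / f for f in self.spec.frequencies)

    def components_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"t": self.t_index, "observed": self.y,
                            "trend": self.trend, "seasonal": self.seasonal,
                            "residual": self.residuals})
        if self.months is not None:
            out.insert(0, "month", self.months.astype(str))
        return out

    def model_card(self) -> dict:
        return {
            "periods": [round(p, 4) for p in self.periods],
            "frequencies": [round(f, 6) for f in self.spec.frequencies],
            "trend": self.spec.trend,
            "nvr_trend": self.spec.nvr_trend,
            "nvr_harmonics": list(self.spec.nvr_harmonics),
            "sigma2": self.spec.sigma2,
            "r_squared": self.r_squared,
            "r_squared_filtered": self.r_squared_filtered,
            "loglik": self.loglik,
        }


def _seasonal_periods_from_peaks(report: _per.PeriodicityReport) -> list[float]:
    """Peak periods usable as harmonic components.

    Multiannual peaks belong to the trend, and peaks far weaker than the
    dominant seasonal peak are left to the noise floor.
    """
    seasonal = [(p, w) for p, w in report.peaks if p <= MAX_SEASONAL_PERIOD]
    if not seasonal:
        return []
    top = max(w for _, w in seasonal)
    return [p for p, w in seasonal if w >= HARMONIC_POWER_FLOOR * top]


def fit_dhr(series: RateSeries | np.ndarray,
            frequencies: tuple[float, ...] | None = None,
            *,
            periods=None,
            nvr_trend: float | None = None,
            nvr_harmonics=None,
            sigma2: float | None = None,
            trend: str = "irw",
            max_order: int = _per.DEFAULT_MAX_ORDER,
            min_prominence: float = _per.DEFAULT_MIN_PROMINENCE,
            diffuse_scale: float = DIFFUSE_SCALE,
            r_squared_on: str = "smoothed") -> DHRFit:
    """Estimate a DHR model for one monthly rate series.

    Harmonic periods default to the AR-spectrum peak periods at or below
    ~13.5 months (rounded to one decimal); pass ``periods`` or ``frequencies``
    to override (e.g. the theoretical set 12, 6, 4, 3, 2.4, 2).  NVRs and
    sigma2 default to the frequency-domain spectral fit; sigma2 is then
    refined by the innovation-variance concentration of the likelihood.
    """
    if isinstance(series, RateSeries):
        y = np.asarray(series.values, dtype=float)
        months = series.months
    else:
        y = np.asarray(series, dtype=float)
        months = None
    n = len(y)
    if n < 36:
        logger.warning("series has %d months (< 3 years); DHR NVRs weakly identified", n)
    t_index = np.arange(n)

    y_ar = y
    if np.isnan(y).any():
        y_ar = pd.Series(y).interpolate(limit_direction="both").to_numpy()
        logger.info("interpolated %d missing months for spectrum estimation",
                    int(np.isnan(y).sum()))

    ar_spec = None
    report = None
    if frequencies is None and periods is None:
        ar_spec, report = _per.analyze_periodicity(y_ar, max_order=max_order,
                                                   min_prominence=min_prominence)
        use_periods = _seasonal_periods_from_peaks(report)
        if not use_periods:
            use_periods = [12.0, 6.0]
            logger.warning("no seasonal spectral peaks found; "
                           "falling back to theoretical periods 12 and 6")
        frequencies = tuple(1.0 / p for p in use_periods)
    elif periods is not None:
        frequencies = tuple(1.0 / float(p) for p in periods)

    need_opt = nvr_trend is None or nvr_harmonics is None or sigma2 is None
    nvr_info = None
    if need_opt:
        if ar_spec is None:
            ar_spec = _per.estimate_spectrum(y_ar, max_order=max_order)
        nvr_info = optimize_nvr(ar_spec, frequencies, trend=trend)
        if nvr_trend is None:
            nvr_trend = nvr_info.nvr_trend
        if nvr_harmonics is None:
            nvr_harmonics = nvr_info.nvr_harmonics
        if sigma2 is None:
            sigma2 = nvr_info.sigma2
    if np.ndim(nvr_harmonics) == 0:
        nvr_harmonics = (float(nvr_harmonics),) * len(frequencies)

    spec = DHRModelSpec(frequencies=tuple(frequencies), nvr_trend=float(nvr_trend),
                        nvr_harmonics=tuple(float(v) for v in nvr_harmonics),
                        sigma2=float(sigma2), trend=trend)

    filt = kalman_filter(y, spec, t_index=t_index, diffuse_scale=diffuse_scale)
    # refine sigma2 as the innovation-variance concentration; rescaling all
    # variances by a common factor leaves state means and gains unchanged
    valid = np.isfinite(filt.innovations)
    valid[:filt.n_burn] = False
    valid &= filt.innovation_variances > 0
    if valid.sum() >= 4:
        factor = float(np.mean(filt.innovations[valid] ** 2
                               / filt.innovation_variances[valid]))
        factor = max(factor, 1e-12)  # keep sigma2 > 0 on noiseless series
        if factor > 2.0 or factor < 0.5:
            logger.info("sigma2 refined by factor %.3g relative to spectral fit", factor)
        spec = DHRModelSpec(frequencies=spec.frequencies, nvr_trend=spec.nvr_trend,
                            nvr_harmonics=spec.nvr_harmonics,
                            sigma2=spec.sigma2 * factor, trend=spec.trend)
        filt = kalman_filter(y, spec, t_index=t_index, diffuse_scale=diffuse_scale)

    smooth = kalman_smooth(filt)
    Z = filt.Z
    nt = spec.n_trend_states
    trend_comp = smooth.x_smooth[:, 0]
    slope = smooth.x_smooth[:, 1] if spec.trend == "irw" else np.zeros(n)
    seasonal = np.einsum("ij,ij->i", Z[:, nt:], smooth.x_smooth[:, nt:])
    fitted = trend_comp + seasonal
    residuals = y - fitted

    obs = np.isfinite(y)
    r2 = _r2(y[obs], fitted[obs])
    fitted_f = np.einsum("ij,ij->i", Z, filt.x_filt)
    r2_f = _r2(y[obs], fitted_f[obs])

    return DHRFit(spec=spec, y=y, t_index=t_index, months=months,
                  filtered=filt, smoothed=smooth, trend=trend_comp, slope=slope,
                  seasonal=seasonal, fitted=fitted, residuals=residuals,
                  r_squared=r2 if r_squared_on == "smoothed" else r2_f,
                  r_squared_filtered=r2_f, loglik=filt.loglik,
                  nvr_info=nvr_info, ar_spectrum=ar_spec, periodicity=report)


def _r2(observed: np.ndarray, fitted: np.ndarray) -> float:
    return float(1.0 - np.var(observed - fitted) / np.var(observed))


@dataclass
class ForecastResult:
    """Multi-horizon point forecasts with symmetric +/- 2 SE bands."""

    origin_t: int
    origin_month: pd.Period | None
    horizons: np.ndarray
    point: np.ndarray
    se: np.ndarray

    @property
    def lower(self) -> np.ndarray:
        return self.point - 2.0 * self.se

    @property
    def upper(self) -> np.ndarray:
        return self.point + 2.0 * self.se

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"horizon": self.horizons, "forecast": self.point,
                            "se": self.se, "se_lo": self.lower, "se_hi": self.upper})
        if self.origin_month is not None:
            months = self.origin_month + self.horizons
            out.insert(0, "month", [str(m) for m in months])
        return out


def forecast_from_filter(filtered: FilterResult, origin_idx: int,
                         h: int) -> ForecastResult:
    """h-step-ahead prediction from the filtered state at ``origin_idx``.

    The state is propagated with no further updates; this coincides with the
    filter's own one-step predictions when updates are withheld.
    """
    if h < 1:
        raise ValueError("horizon must be >= 1")
    spec = filtered.spec
    F, Q, sigma2 = build_state_space(spec)
    x = filtered.x_filt[origin_idx].copy()
    P = filtered.P_filt[origin_idx].copy()
    t0 = int(filtered.t_index[origin_idx])
    horizons = np.arange(1, h + 1)
    point = np.empty(h)
    se = np.empty(h)
    for j, k in enumerate(horizons):
        x = F @ x
        P = F @ P @ F.T + Q
        z = observation_matrix(spec, np.array([t0 + k]))[0]
        point[j] = z @ x
        se[j] = np.sqrt(z @ P @ z + sigma2)
    return ForecastResult(origin_t=t0, origin_month=None, horizons=horizons,
                          point=point, se=se)


def forecast(fit: DHRFit, h: int) -> ForecastResult:
    """Forecast 1..h months past the end of the fitted series."""
    res = forecast_from_filter(fit.filtered, len(fit.y) - 1, h)
    if fit.months is not None:
        res.origin_month = fit.months[-1]
    return res


@dataclass
class TrendSlopeReport:
    """Deterministic trend slope of a series and its sign classification."""

    slope: float
    intercept: float
    classification: str
    dead_band: float


def trend_slope(values: np.ndarray, *, dead_band: float = 1e-7,
                diffuse_scale: float = 1e8) -> TrendSlopeReport:
    """Trend slope from the NVR = 0 integrated-random-walk smoother.

    With zero process noise the IRW degenerates to a deterministic straight
    line, so the smoothed slope equals the ordinary-least-squares slope of the
    series on its time index.  ``dead_band`` sets the |slope| threshold for
    the increasing / stable / decreasing label.
    """
    y = np.asarray(values, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 samples for a trend slope")
    scale = np.nanvar(y)
    spec = DHRModelSpec(frequencies=(), nvr_trend=0.0, nvr_harmonics=(),
                        sigma2=scale if scale > 0 else 1.0,
                        trend="irw")
    # anchoring the prior mean at the first observation keeps the innovations
    # small relative to the diffuse prior, which preserves float precision
    filt = kalman_filter(y, spec, diffuse_scale=diffuse_scale,
                         x0=np.array([y[0], 0.0]))
    smooth = kalman_smooth(filt)
    slope = float(smooth.x_smooth[-1, 1])
    intercept = float(smooth.x_smooth[0, 0])
    if abs(slope) < dead_band:
        label = "stable"
    elif slope > 0:
        label = "increasing"
    else:
        label = "decreasing"
    return TrendSlopeReport(slope=slope, intercept=intercept,
                            classification=label, dead_band=dead_band)
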