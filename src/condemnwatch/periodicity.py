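"""AR-spectrum estimation and the seasonality decision rule.

A monthly rate series is screened for seasonality by fitting an autoregressive
model (order chosen by AIC), evaluating the implied power spectrum on a dense
frequency grid, locating its pronounced peaks, and asking whether one peak sits
at (or close to) the annual period of 12 months/cycle while at least one other
peak sits near a theoretical seasonal harmonic (6, 4, 3, 2.4 or 2 months).
Only series passing this rule are handed to the harmonic-regression model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal
from statsmodels.regression.linear_model import burg, yule_walker

from .vocab import theoretical_periods

logger = logging.getLogger(__name__)

DEFAULT_MAX_ORDER = 24
DEFAULT_GRID_SIZE = 512
DEFAULT_MIN_PROMINENCE = 0.05
DEFAULT_TOL_ANNUAL = 1.5
DEFAULT_TOL_HARMONIC = 0.3


@dataclass
class ARFit:
    """One fitted AR(p) model: x_t = sum_k a_k x_{t-k} + e_t, e_t ~ (0, s2)."""

    order: int
    coefficients: np.ndarray
    innovation_variance: float
    aic: float
    n: int


@dataclass
class ARSpectrum:
    """AR power spectrum with the AIC trace of candidate orders."""

    order: int
    ar_coefficients: np.ndarray
    innovation_variance: float
    frequency_grid: np.ndarray = field(repr=False)
    power: np.ndarray = field(repr=False)
    aic_by_order: dict[int, float] = field(default_factory=dict)


def default_grid(size: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """``size`` equally spaced frequencies in (0, 0.5] cycles/month."""
    return np.arange(1, size + 1) * (0.5 / size)


def fit_ar(values: np.ndarray, order: int, *, method: str = "burg") -> ARFit:
    """Fit a mean-removed AR(p) model by Burg (default) or Yule-Walker.

    AIC = N log(innovation variance) + 2p.  Burg guarantees a stationary
    spectral factorisation (all characteristic roots inside the unit circle).
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    n = len(x)
    if order < 1:
        raise ValueError("order must be >= 1")
    if order >= n / 2:
        raise ValueError(f"order {order} too large for series of length {n}")
    x = x - x.mean()
    if np.var(x) == 0.0:
        raise ValueError("series is constant; AR spectrum is degenerate")
    if method == "burg":
        coeffs, sigma2 = burg(x, order=order, demean=False)
    elif method == "yule_walker":
        coeffs, sigma = yule_walker(x, order=order, demean=False)
        sigma2 = float(sigma) ** 2
    else:
        raise ValueError(f"unknown AR estimation method {method!r}")
    sigma2 = float(sigma2)
    if sigma2 <= 0 or not np.isfinite(sigma2):
        raise ValueError("degenerate innovation variance")
    aic = n * np.log(sigma2) + 2 * order
    return ARFit(order=order, coefficients=np.asarray(coeffs, dtype=float),
                 innovation_variance=sigma2, aic=float(aic), n=n)


def select_ar_order(values: np.ndarray, max_order: int = DEFAULT_MAX_ORDER,
                    *, method: str = "burg") -> tuple[ARFit, dict[int, float]]:
    """AIC order selection over 1..max_order; ties broken toward smaller p."""
    x = np.asarray(values, dtype=float)
    if max_order >= len(x) / 2:
        raise ValueError(f"max_order {max_order} must be < length/2 = {len(x) / 2:g}")
    fits: dict[int, ARFit] = {}
    aic_by_order: dict[int, float] = {}
    for p in range(1, max_order + 1):
        fit = fit_ar(x, p, method=method)
        fits[p] = fit
        aic_by_order[p] = fit.aic
    best = min(aic_by_order, key=lambda p: (aic_by_order[p], p))
    return fits[best], aic_by_order


def ar_spectrum_power(coefficients: np.ndarray, innovation_variance: float,
                      grid: np.ndarray) -> np.ndarray:
    """Power S(f) = s2 / |1 - sum_k a_k exp(-2i pi f k)|^2 on the grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.min() <= 0 or grid.max() > 0.5:
        raise ValueError("frequency grid must lie in (0, 0.5] cycles/month")
    a = np.asarray(coefficients, dtype=float)
    k = np.arange(1, len(a) + 1)
    # stationarity: all roots of 1 - a1 z - ... - ap z^p outside the unit circle
    poly = np.concatenate(([1.0], -a))
    roots = np.roots(poly[::-1]) if len(a) else np.array([])
    if len(roots) and np.any(np.abs(roots) <= 1.0 - 1e-6):
        warnings.warn("AR coefficients are non-stationary; spectrum evaluated anyway",
                      RuntimeWarning, stacklevel=2)
    transfer = 1.0 - np.exp(-2j * np.pi * np.outer(grid, k)) @ a
    return innovation_variance / np.abs(transfer) ** 2


def estimate_spectrum(values: np.ndarray, *, max_order: int = DEFAULT_MAX_ORDER,
                      grid: np.ndarray | None = None,
                      method: str = "burg") -> ARSpectrum:
    """Mean-remove, select the AR order by AIC and evaluate the spectrum."""
    if grid is None:
        grid = default_grid()
    fit, aic_by_order = select_ar_order(values, max_order=max_order, method=method)
    power = ar_spectrum_power(fit.coefficients, fit.innovation_variance, grid)
    return ARSpectrum(order=fit.order, ar_coefficients=fit.coefficients,
                      innovation_variance=fit.innovation_variance,
                      frequency_grid=grid, power=power, aic_by_order=aic_by_order)


def find_peaks(spectrum: ARSpectrum,
               min_prominence: float = DEFAULT_MIN_PROMINENCE) -> list[tuple[float, float]]:
    """Pronounced spectral peaks as (period months/cycle, power), power-sorted.

    Peaks are strict interior local maxima of the spectrum.  Prominence is
    judged on the log-power scale (AR spectra span orders of magnitude, and
    peak height ratios grow quadratically with component strength, so a
    secondary seasonal harmonic is invisible on a linear scale): a peak is
    pronounced if its log-power prominence exceeds ``min_prominence`` times
    the log-power dynamic range of the spectrum.  Periods are reported to one
    decimal.  A monotone or flat spectrum has no peaks.
    """
    power = spectrum.power
    log_power = np.log(power)
    span = float(log_power.max() - log_power.min())
    if span == 0.0:
        return []
    idx, _ = scipy.signal.find_peaks(log_power, prominence=min_prominence * span)
    periods = 1.0 / spectrum.frequency_grid[idx]
    peaks = sorted(zip(np.round(periods, 1), power[idx]),
                   key=lambda pk: -pk[1])
    return [(float(p), float(w)) for p, w in peaks]


@dataclass
class PeriodicityReport:
    """Outcome of the seasonality screen for one condemnation reason."""

    peaks: list[tuple[float, float]]
    is_seasonal: bool
    matched_theoretical_periods: list[float]
    tol_annual: float
    tol_harmonic: float
    annual_period: float = 12.0

    def to_dict(self) -> dict:
        return {
            "peaks": [{"period": p, "power": w} for p, w in self.peaks],
            "is_seasonal": self.is_seasonal,
            "matched_periods": self.matched_theoretical_periods,
            "parameters": {"annual_period": self.annual_period,
                           "tol_annual": self.tol_annual,
                           "tol_harmonic": self.tol_harmonic},
        }


def classify_seasonality(peaks: list[tuple[float, float]],
                         *,
                         annual_period: float = 12.0,
                         harmonics: tuple[float, ...] | None = None,
                         tol_annual: float = DEFAULT_TOL_ANNUAL,
                         tol_harmonic: float = DEFAULT_TOL_HARMONIC) -> PeriodicityReport:
    """Seasonality rule: a pronounced peak near 12 months AND a second peak
    near a theoretical harmonic.

    ``harmonics`` defaults to {6, 4, 3, 2.4, 2} (annual period / j, j = 2..6).
    The annual match and the harmonic match must be two distinct peaks.
    """
    if harmonics is None:
        harmonics = theoretical_periods()[1:]
    annual_idx = [i for i, (p, _) in enumerate(peaks)
                  if abs(p - annual_period) <= tol_annual]
    matched: list[float] = []
    harmonic_hit = False
    for i, (p, _) in enumerate(peaks):
        for h in harmonics:
            if abs(p - h) <= tol_harmonic:
                matched.append(h)
                # the harmonic peak must differ from at least one annual peak
                if any(j != i for j in annual_idx):
                    harmonic_hit = True
                break
    is_seasonal = bool(annual_idx) and harmonic_hit
    if annual_idx:
        matched = [annual_period] + sorted(set(matched), reverse=True)
    else:
        matched = sorted(set(matched), reverse=True)
    return PeriodicityReport(peaks=peaks, is_seasonal=is_seasonal,
                             matched_theoretical_periods=matched,
                             tol_annual=tol_annual, tol_harmonic=tol_harmonic,
                             annual_period=annual_period)


def analyze_periodicity(values: np.ndarray, *, max_order: int = DEFAULT_MAX_ORDER,
                        min_prominence: float = DEFAULT_MIN_PROMINENCE,
                        tol_annual: float = DEFAULT_TOL_ANNUAL,
                        tol_harmonic: float = DEFAULT_TOL_HARMONIC,
                        method: str = "burg") -> tuple[ARSpectrum, PeriodicityReport]:
    """Full screen: AR spectrum -> peak list -> seasonality verdict."""
    spectrum = estimate_spectrum(values, max_order=max_order, method=method)
    peaks = find_peaks(spectrum, min_prominence=min_prominence)
    report = classify_seasonality(peaks, tol_annual=tol_annual,
                                  tol_harmonic=tol_harmonic)
    return spectrum, report
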