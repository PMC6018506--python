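"""Goodness of fit and rolling-origin forecast evaluation.

Fit quality is scored by the coefficient of determination
R_t^2 = 1 - var(Y - Yhat) / var(Y).  Predictive skill per horizon h is the
mean relative prediction error

    MRPE(%) = (1/n) * sum_t [(Y(t) - Yhat(t)) / Y(t)]^2 * 100,

the mean of *squared* relative errors (no square root) — the convention used
for these surveillance series.  A root-mean-square variant is available behind
a flag for comparability with other literature.  Rolling-origin evaluation
walks the forecast origin month by month through a held-out window, producing
the h-step-ahead forecast of each target month and pooling the errors per
horizon, with model hyperparameters either frozen at the training fit or
re-estimated at every origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import RateSeries
from .dhr import DHRFit, fit_dhr, forecast_from_filter
from .statespace import kalman_filter

logger = logging.getLogger(__name__)

DEFAULT_HORIZONS = tuple(range(3, 13))


def r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Coefficient of determination 1 - var(observed - fitted)/var(observed)."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if len(obs) != len(fit):
        raise ValueError("observed and fitted must have equal length")
    if len(obs) < 2:
        raise ValueError("need at least 2 observations")
    v = np.var(obs)
    if v == 0.0:
        raise ValueError("observed variance is zero; R^2 undefined")
    return float(1.0 - np.var(obs - fit) / v)


def mrpe(observed: np.ndarray, predicted: np.ndarray, *,
         rms: bool = False) -> float:
    """Mean relative prediction error in percent.

    Zero observations cannot enter the relative error and are excluded with a
    logged count; if all observations are zero the statistic is undefined.
    With ``rms=True`` the square root of the mean squared relative error is
    returned instead (not used by default).
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if len(y) != len(yhat):
        raise ValueError("observed and predicted must have equal length")
    keep = y != 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("mrpe: excluded %d zero observation(s)", n_dropped)
    if not keep.any():
        raise ValueError("all observations are zero; MRPE undefined")
    rel2 = ((y[keep] - yhat[keep]) / y[keep]) ** 2
    value = float(np.mean(rel2) * 100.0)
    return float(np.sqrt(np.mean(rel2)) * 100.0) if rms else value


@dataclass
class EvaluationReport:
    """Per-horizon MRPE over a rolling-origin held-out window."""

    series_id: str
    train_end: object
    horizons: tuple[int, ...]
    mrpe_percent: dict[int, float]
    n_origins: dict[int, int]
    mode: str
    pairs: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict,
                                                            repr=False)

    def to_rows(self) -> list[dict]:
        return [{"horizon": h, "mrpe_percent": self.mrpe_percent.get(h),
                 "n_origins": self.n_origins.get(h, 0)} for h in self.horizons]


def rolling_origin_evaluate(
    series: RateSeries | np.ndarray,
    *,
    train_end,
    horizons: tuple[int, ...] = DEFAULT_HORIZONS,
    mode: str = "frozen",
    fit: DHRFit | None = None,
    series_id: str = "",
    pool: str = "all",
    fit_kwargs: dict | None = None,
) -> EvaluationReport:
    """Rolling-origin forecast evaluation over the post-training window.

    Parameters
    ----------
    train_end
        Last month of the training window: a ``YYYY-MM`` string / Period when
        ``series`` is a RateSeries, else an integer sample index.
    mode
        ``"frozen"`` keeps the NVRs and sigma2 from the training fit and only
        updates the filtered state through each origin; ``"reestimate"``
        re-runs the spectral hyperparameter fit on the data through each
        origin before forecasting.
    pool
        ``"all"`` pools every origin's h-step forecast per horizon (default);
        ``"last"`` keeps only the forecast whose target is the final month.

    For each origin month m >= train_end the h-step-ahead forecast of month
    m + h is paired with the observation; pairs with a zero observation are
    excluded by :func:`mrpe`.
    """
    if isinstance(series, RateSeries):
        y = np.asarray(series.values, dtype=float)
        import pandas as pd
        train_end_idx = int(series.months.get_loc(pd.Period(train_end, freq="M")))
        train_end_label = str(train_end)
    else:
        y = np.asarray(series, dtype=float)
        train_end_idx = int(train_end)
        train_end_label = train_end_idx
    n = len(y)
    if mode not in ("frozen", "reestimate"):
        raise ValueError("mode must be 'frozen' or 'reestimate'")
    fit_kwargs = dict(fit_kwargs or {})

    if fit is None:
        fit = fit_dhr(y[: train_end_idx + 1], **fit_kwargs)
    spec = fit.spec

    mrpe_by_h: dict[int, float] = {}
    n_by_h: dict[int, int] = {}
    pairs: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    if mode == "frozen":
        full_filter = kalman_filter(y, spec)
        predictions = {h: {} for h in horizons}
        max_h = max(horizons)
        for m in range(train_end_idx, n - 1):
            hmax = min(max_h, n - 1 - m)
            fc = forecast_from_filter(full_filter, m, hmax)
            for h in horizons:
                if h <= hmax:
                    predictions[h][m + h] = fc.point[h - 1]
    else:
        predictions = {h: {} for h in horizons}
        freqs = spec.frequencies
        for m in range(train_end_idx, n - 1):
            sub_kwargs = dict(fit_kwargs)
            sub_kwargs.setdefault("frequencies", freqs)
            refit = fit_dhr(y[: m + 1], **sub_kwargs)
            hmax = min(max(horizons), n - 1 - m)
            fc = forecast_from_filter(refit.filtered, m, hmax)
            for h in horizons:
                if h <= hmax:
                    predictions[h][m + h] = fc.point[h - 1]

    for h in horizons:
        targets = sorted(predictions[h])
        if pool == "last":
            targets = targets[-1:] if targets else []
        obs = np.array([y[t] for t in targets])
        pred = np.array([predictions[h][t] for t in targets])
        ok = np.isfinite(obs)
        obs, pred = obs[ok], pred[ok]
        if len(obs) == 0:
            logger.warning("horizon %d: no valid evaluation pairs; skipped", h)
            continue
        valid = obs != 0
        n_by_h[h] = int(valid.sum())
        try:
            mrpe_by_h[h] = mrpe(obs, pred)
        except ValueError:
            logger.warning("horizon %d: all observations zero; skipped", h)
            continue
        pairs[h] = (obs, pred)

    return EvaluationReport(series_id=series_id, train_end=train_end_label,
                            horizons=tuple(horizons), mrpe_percent=mrpe_by_h,
                            n_origins=n_by_h, mode=mode, pairs=pairs)
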