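"""Linear-Gaussian state space for dynamic harmonic regression (DHR).

The observed monthly rate decomposes as Y(t) = L(t) + Q(t) + e(t):

* ``L`` — trend, an integrated random walk (IRW) with level L and slope l:
  L(t) = L(t-1) + l(t-1), l(t) = l(t-1) + eta_L(t); a plain random walk is
  available as the degenerate option.
* ``Q`` — cyclical term, sum over harmonics i of
  alpha_i(t) cos(2 pi f_i t) + beta_i(t) sin(2 pi f_i t), the coefficients
  evolving as random walks (time-varying amplitude and phase).
* ``e`` — Gaussian white observation noise with variance sigma2.

Each state's process-noise variance is expressed as a noise-variance ratio
(NVR) times sigma2; NVRs are the smoothing hyperparameters.  The state vector
is [L, l, alpha_1, beta_1, ..., alpha_n, beta_n] (dimension 2 + 2n for the
IRW trend).  Estimation is by Kalman filtering with a finite diffuse prior and
fixed-interval (RTS) smoothing; the likelihood is the prediction-error
decomposition with the first ``dim`` innovations excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Prior state variance = DIFFUSE_SCALE x series variance (finite diffuse prior).
DIFFUSE_SCALE = 1e7


@dataclass(frozen=True)
class DHRModelSpec:
    """Definition of one DHR model: harmonics, stochastic types, NVRs, sigma2."""

    frequencies: tuple[float, ...]
    nvr_trend: float
    nvr_harmonics: tuple[float, ...]
    sigma2: float
    trend: str = "irw"  # "irw" (level+slope) or "rw" (level only)
    samples_per_year: int = 12

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if np.any(f <= 0) or np.any(f > 0.5):
            raise ValueError("frequencies must lie in (0, 0.5] cycles/month")
        if len(set(np.round(f, 12))) != len(f):
            raise ValueError("frequencies must be distinct")
        if len(self.nvr_harmonics) != len(self.frequencies):
            raise ValueError("need one harmonic NVR per frequency")
        if self.nvr_trend < 0 or any(v < 0 for v in self.nvr_harmonics):
            raise ValueError("NVRs must be >= 0")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if self.trend not in ("irw", "rw"):
            raise ValueError("trend must be 'irw' or 'rw'")

    @property
    def n_harmonics(self) -> int:
        return len(self.frequencies)

    @property
    def n_trend_states(self) -> int:
        return 2 if self.trend == "irw" else 1

    @property
    def dim(self) -> int:
        return self.n_trend_states + 2 * self.n_harmonics

    @classmethod
    def from_periods(cls, periods, *, nvr_trend, nvr_harmonics, sigma2,
                     trend="irw") -> "DHRModelSpec":
        """Convenience constructor from periods in months/cycle (f = 1/P)."""
        freqs = tuple(1.0 / float(p) for p in periods)
        nh = tuple(float(v) for v in (nvr_harmonics if np.ndim(nvr_harmonics)
                                      else [nvr_harmonics] * len(freqs)))
        return cls(frequencies=freqs, nvr_trend=float(nvr_trend),
                   nvr_harmonics=nh, sigma2=float(sigma2), trend=trend)


def build_state_space(spec: DHRModelSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Transition matrix F, process-noise covariance Q and observation
    variance sigma2 for a DHR spec.

    F is block-diagonal: a 2x2 IRW block [[1, 1], [0, 1]] for (L, l) (or the
    scalar 1 for an RW trend) and an identity block per harmonic.  Process
    noise enters the slope (trend NVR) and each harmonic coefficient pair
    (harmonic NVR), all scaled by sigma2.
    """
    k = spec.dim
    F = np.eye(k)
    q = np.zeros(k)
    if spec.trend == "irw":
        F[0, 1] = 1.0
        q[1] = spec.nvr_trend * spec.sigma2
    else:
        q[0] = spec.nvr_trend * spec.sigma2
    off = spec.n_trend_states
    for i, _ in enumerate(spec.frequencies):
        q[off + 2 * i] = spec.nvr_harmonics[i] * spec.sigma2
        q[off + 2 * i + 1] = spec.nvr_harmonics[i] * spec.sigma2
    return F, np.diag(q), spec.sigma2


def observation_matrix(spec: DHRModelSpec, t: np.ndarray) -> np.ndarray:
    """Time-varying observation rows [1, 0, cos(2 pi f_1 t), sin(2 pi f_1 t), ...].

    ``t`` is the integer sample index (months since the series origin); its
    absolute offset only re-phases the harmonic coefficients.
    """
    t = np.asarray(t, dtype=float)
    cols = [np.ones_like(t)]
    if spec.trend == "irw":
        cols.append(np.zeros_like(t))
    for f in spec.frequencies:
        cols.append(np.cos(2.0 * np.pi * f * t))
        cols.append(np.sin(2.0 * np.pi * f * t))
    return np.column_stack(cols)


@dataclass
class FilterResult:
    """Output of one Kalman-filter pass."""

    spec: DHRModelSpec
    y: np.ndarray = field(repr=False)
    t_index: np.ndarray = field(repr=False)
    Z: np.ndarray = field(repr=False)
    x_pred: np.ndarray = field(repr=False)
    P_pred: np.ndarray = field(repr=False)
    x_filt: np.ndarray = field(repr=False)
    P_filt: np.ndarray = field(repr=False)
    innovations: np.ndarray = field(repr=False)
    innovation_variances: np.ndarray = field(repr=False)
    loglik: float = np.nan
    n_burn: int = 0


@dataclass
class SmoothResult:
    """Fixed-interval smoothed states and covariances."""

    x_smooth: np.ndarray = field(repr=False)
    P_smooth: np.ndarray = field(repr=False)


def kalman_filter(y: np.ndarray, spec: DHRModelSpec, *,
                  t_index: np.ndarray | None = None,
                  diffuse_scale: float = DIFFUSE_SCALE,
                  x0: np.ndarray | None = None,
                  P0: np.ndarray | None = None) -> FilterResult:
    """Kalman filter with a finite diffuse prior; NaN observations are skipped
    (prediction without update), interior gaps included.

    The log-likelihood is the Gaussian prediction-error decomposition over the
    post-burn-in innovations (burn-in = state dimension).
    """
    y = np.asarray(y, dtype=float)
    if np.any(np.isinf(y)):
        raise ValueError("series contains non-finite (infinite) values")
    n = len(y)
    if t_index is None:
        t_index = np.arange(n)
    F, Q, sigma2 = build_state_space(spec)
    Z = observation_matrix(spec, t_index)
    k = spec.dim

    if P0 is None:
        scale = np.nanvar(y)
        if not np.isfinite(scale) or scale == 0.0:
            scale = 1.0
        P0 = diffuse_scale * scale * np.eye(k)
    if x0 is None:
        x0 = np.zeros(k)

    x_pred = np.empty((n, k))
    P_pred = np.empty((n, k, k))
    x_filt = np.empty((n, k))
    P_filt = np.empty((n, k, k))
    innov = np.full(n, np.nan)
    innov_var = np.full(n, np.nan)

    x, P = np.asarray(x0, dtype=float), np.asarray(P0, dtype=float)
    I = np.eye(k)
    for i in range(n):
        x_pred[i], P_pred[i] = x, P
        z = Z[i]
        if np.isfinite(y[i]):
            v = y[i] - z @ x
            s = float(z @ P @ z + sigma2)
            K = (P @ z) / s
            x = x + K * v
            # Joseph-form update for numerical symmetry/stability
            A = I - np.outer(K, z)
            P = A @ P @ A.T + sigma2 * np.outer(K, K)
            innov[i], innov_var[i] = v, s
        x_filt[i], P_filt[i] = x, P
        x = F @ x
        P = F @ P @ F.T + Q

    n_burn = k
    valid = np.isfinite(innov)
    valid[:n_burn] = False
    # rounding in the diffuse start can leave non-positive variances in the
    # noise-free limit; such terms carry no usable likelihood information
    valid &= innov_var > 0
    ll = -0.5 * np.sum(np.log(2.0 * np.pi * innov_var[valid])
                       + innov[valid] ** 2 / innov_var[valid])
    return FilterResult(spec=spec, y=y, t_index=np.asarray(t_index), Z=Z,
                        x_pred=x_pred, P_pred=P_pred, x_filt=x_filt,
                        P_filt=P_filt, innovations=innov,
                        innovation_variances=innov_var, loglik=float(ll),
                        n_burn=n_burn)


def kalman_smooth(filtered: FilterResult) -> SmoothResult:
    """Rauch-Tung-Striebel fixed-interval smoother.

    At the last time point the smoothed state equals the filtered state; the
    smoothed variance never exceeds the filtered variance on the diagonal.
    """
    spec = filtered.spec
    F, Q, _ = build_state_space(spec)
    n, k = filtered.x_filt.shape
    xs = np.empty((n, k))
    Ps = np.empty((n, k, k))
    xs[-1], Ps[-1] = filtered.x_filt[-1], filtered.P_filt[-1]
    for i in range(n - 2, -1, -1):
        Pf = filtered.P_filt[i]
        Pp = F @ Pf @ F.T + Q  # one-step prediction covariance from i to i+1
        try:
            G = np.linalg.solve(Pp.T, (Pf @ F.T).T).T
        except np.linalg.LinAlgError:
            # degenerate (noise-free) limit: covariances collapse to rank-deficient
            G = Pf @ F.T @ np.linalg.pinv(Pp)
        xs[i] = filtered.x_filt[i] + G @ (xs[i + 1] - F @ filtered.x_filt[i])
        Ps[i] = Pf + G @ (Ps[i + 1] - Pp) @ G.T
    return SmoothResult(x_smooth=xs, P_smooth=Ps)
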