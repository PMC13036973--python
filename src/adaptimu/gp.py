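"""Sliding-window Gaussian-process motion forecaster with risk head.

A time-indexed GP with a composite covariance — a Matérn-3/2 term for
smooth aperiodic motion plus an exp-sine-squared (periodic) term for the
gait cycle:

    k(t_i, t_j) = sigma_f^2 * Matern32(d; l_m) + sigma_p^2 * Periodic(d; l_p, T)

Each motion-feature dimension is modeled by an independent scalar GP over
time.  Inference is exact: the observation window is capped at the 50 most
recent feature vectors, so the covariance factorization never exceeds
50 x 50.  The forecast at t + horizon feeds a logistic risk head
r = sigmoid(w^T x_hat + b); the alert boundary is the validated risk
threshold tau = 0.6.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from sklearn.linear_model import LogisticRegression

RISK_THRESHOLD = 0.6
BUFFER_CAPACITY = 50
DEFAULT_HORIZON_S = 0.150


@dataclass
class GpKernelParams:
    sigma_f_sq: float = 1.24       # Matérn signal variance
    sigma_p_sq: float = 0.58       # periodic variance
    matern_length: float = 0.5     # s
    periodic_length: float = 0.3   # dimensionless warp length
    periodic_period: float = 0.7   # s, approx. one stride
    noise_var: float = 0.05

    def __post_init__(self):
        for name in ("sigma_f_sq", "sigma_p_sq", "matern_length",
                     "periodic_length", "periodic_period"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.noise_var < 0:
            raise ValueError("noise_var must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array([self.sigma_f_sq, self.sigma_p_sq, self.matern_length,
                         self.periodic_length, self.periodic_period,
                         self.noise_var])


def _matern32(d: np.ndarray, length: float) -> np.ndarray:
    r = np.sqrt(3.0) * np.abs(d) / length
    return (1.0 + r) * np.exp(-r)


def _periodic(d: np.ndarray, length: float, period: float) -> np.ndarray:
    s = np.sin(np.pi * np.abs(d) / period)
    return np.exp(-2.0 * s * s / length ** 2)


def kernel_eval(x_i: float, x_j: float, theta: GpKernelParams) -> float:
    """Composite covariance between two time points (noise excluded)."""
    d = np.asarray(x_i, dtype=float) - np.asarray(x_j, dtype=float)
    val = (theta.sigma_f_sq * _matern32(d, theta.matern_length)
           + theta.sigma_p_sq * _periodic(d, theta.periodic_length,
                                          theta.periodic_period))
    return float(val) if np.ndim(val) == 0 else val


def kernel_matrix(t1: np.ndarray, t2: np.ndarray,
                  theta: GpKernelParams) -> np.ndarray:
    d = np.subtract.outer(np.asarray(t1, float), np.asarray(t2, float))
    return (theta.sigma_f_sq * _matern32(d, theta.matern_length)
            + theta.sigma_p_sq * _periodic(d, theta.periodic_length,
                                           theta.periodic_period))


@dataclass
class GpForecast:
    x_hat: np.ndarray
    variance: np.ndarray
    horizon_s: float = DEFAULT_HORIZON_S
    risk: float | None = None


class GpBuffer:
    """FIFO window of the most recent (timestamp, feature vector) pairs."""

    def __init__(self, capacity: int = BUFFER_CAPACITY):
        self.capacity = capacity
        self._entries: deque = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([t for t, _ in self._entries])

    @property
    def features(self) -> np.ndarray:
        return np.array([x for _, x in self._entries])

    def push(self, timestamp: float, features) -> "GpBuffer":
        if self._entries and timestamp <= self._entries[-1][0]:
            raise ValueError("out-of-order observation timestamp")
        self._entries.append((float(timestamp),
                              np.atleast_1d(np.asarray(features, float))))
        return self


def update_buffer(buffer: GpBuffer, timestamp: float, features) -> GpBuffer:
    return buffer.push(timestamp, features)


def _chol_with_jitter(K: np.ndarray):
    """Cholesky with escalating jitter 1e-8 -> 1e-4 (x10 per attempt)."""
    jitter = 1e-8
    while jitter <= 1e-4:
        try:
            return cho_factor(K + jitter * np.eye(K.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            jitter *= 10
    raise np.linalg.LinAlgError(
        "covariance not positive definite after jitter escalation to 1e-4")


def predict_ahead(buffer: GpBuffer, theta: GpKernelParams,
                  horizon_s: float = DEFAULT_HORIZON_S) -> GpForecast:
    """Exact GP posterior mean/variance at t_last + horizon, per feature."""
    if len(buffer) == 0:
        raise ValueError("cannot predict from an empty buffer")
    t = buffer.timestamps
    Y = buffer.features
    t_star = t[-1] + horizon_s
    K = kernel_matrix(t, t, theta) + theta.noise_var * np.eye(len(t))
    cf = _chol_with_jitter(K)
    k_star = kernel_matrix(np.array([t_star]), t, theta)[0]
    alpha = cho_solve(cf, Y)
    mean = k_star @ alpha
    v = cho_solve(cf, k_star)
    prior_var = kernel_eval(t_star, t_star, theta)
    var = max(prior_var - float(k_star @ v), 0.0)
    return GpForecast(x_hat=np.atleast_1d(mean),
                      variance=np.full(Y.shape[1], var),
                      horizon_s=horizon_s)


def log_marginal_likelihood(t: np.ndarray, Y: np.ndarray,
                            theta: GpKernelParams) -> float:
    """Exact GP evidence, summed over independent feature dimensions."""
    t = np.asarray(t, float)
    Y = np.atleast_2d(np.asarray(Y, float))
    if Y.shape[0] != t.shape[0]:
        Y = Y.T
    n = t.shape[0]
    K = kernel_matrix(t, t, theta) + theta.noise_var * np.eye(n)
    cf = _chol_with_jitter(K)
    alpha = cho_solve(cf, Y)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    d = Y.shape[1]
    quad = float(np.sum(Y * alpha))
    return -0.5 * quad - 0.5 * d * logdet - 0.5 * d * n * np.log(2 * np.pi)


_LOG_BOUNDS = [(-9.0, 6.0),   # log sigma_f_sq
               (-9.0, 6.0),   # log sigma_p_sq
               (-4.0, 3.0),   # log matern_length
               (-4.0, 3.0),   # log periodic_length
               (-3.0, 2.5),   # log periodic_period
               (-9.0, 6.0)]   # log noise_var


def fit_hyperparameters(t: np.ndarray, Y: np.ndarray,
                        init: GpKernelParams | None = None,
                        n_restarts: int = 5, seed: int = 0) -> GpKernelParams:
    """Maximize the log marginal likelihood over log-parameters (L-BFGS-B)
    with seeded multi-start."""
    t = np.asarray(t, float)
    Y = np.atleast_2d(np.asarray(Y, float))
    if Y.shape[0] != t.shape[0]:
        Y = Y.T
    if t.shape[0] < 10:
        raise ValueError("need at least 10 observations to fit hyperparameters")
    base = (init or GpKernelParams()).to_array()
    rng = np.random.default_rng(seed)

    def neg_lml(log_theta):
        th = GpKernelParams(*np.exp(log_theta))
        try:
            return -log_marginal_likelihood(t, Y, th)
        except np.linalg.LinAlgError:
            return 1e12

    best_val, best_x = np.inf, np.log(base)
    starts = [np.log(base)]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(np.log(base) + rng.normal(scale=0.7, size=base.size))
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in _LOG_BOUNDS], [b[1] for b in _LOG_BOUNDS])
        res = minimize(neg_lml, x0, method="L-BFGS-B", bounds=_LOG_BOUNDS)
        if res.fun < best_val:
            best_val, best_x = res.fun, res.x
    if not np.isfinite(best_val):
        raise np.linalg.LinAlgError(
            "hyperparameter fit failed: covariance not PSD at every start")
    return GpKernelParams(*np.exp(best_x))


# ---------------------------------------------------------------------------
# risk head


@dataclass
class RiskHead:
    w: np.ndarray
    b: float

    def __post_init__(self):
        self.w = np.atleast_1d(np.asarray(self.w, float))
        if not (np.all(np.isfinite(self.w)) and np.isfinite(self.b)):
            raise ValueError("risk head parameters must be finite")


def risk_score(forecast: GpForecast | np.ndarray, head: RiskHead) -> float:
    """Logistic risk r = sigmoid(w^T x_hat + b) in (0, 1)."""
    x = forecast.x_hat if isinstance(forecast, GpForecast) else np.asarray(forecast)
    if x.shape[-1] != head.w.shape[0]:
        raise ValueError("risk head dimension does not match features")
    z = float(x @ head.w + head.b)
    r = float(_stable_sigmoid(z))
    if isinstance(forecast, GpForecast):
        forecast.risk = r
    return r


def _stable_sigmoid(z):
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.clip(z, None, 500))),
                    np.exp(np.clip(z, -500, None))
                    / (1.0 + np.exp(np.clip(z, -500, None))))


def fit_risk_head(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> RiskHead:
    """L2-regularized logistic fit of risk labels on forecast features."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1 and len(np.asarray(y)) > 1:
        X = X.T
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("risk-head fit requires both classes")
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=2000, tol=1e-10)
    clf.fit(X, y)
    return RiskHead(w=clf.coef_[0], b=float(clf.intercept_[0]))
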