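"""Chaos detection for short ecological time series.

Implements the battery used to decide whether patch abundance
trajectories are chaotic: delay-embedding selection (average mutual
information for the lag, false nearest neighbours for the dimension),
the direct Lyapunov-exponent estimator of Rosenstein (mean log
divergence of embedded nearest neighbours), the indirect Jacobian
estimator built on S-map locally weighted regression, and a sliding
window variant for local stability.

Classification follows a deliberately conservative rule: a series counts
as chaotic only when the *lower bound* of the Jacobian Lyapunov exponent
exceeds 0.01 per step AND the S-map nonlinearity parameter theta selected
by leave-one-out forecast skill is strictly positive (a globally linear
model, theta = 0, cannot distinguish chaos from exponential growth, so a
positive exponent with theta = 0 is labelled a chaos/growth mixture).

Abundance series are analysed on a log(1 + count) scale by default to
temper the exponential growth trend; the raw scale is available via
``transform="raw"`` (required for series with values <= -1, e.g.
zero-mean test signals).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from patchchaos.population_models import AbundanceSeries

__all__ = [
    "EmbeddingParams",
    "LyapunovEstimate",
    "WindowedStability",
    "DEFAULT_THETA_GRID",
    "select_embedding",
    "rosenstein_le",
    "smap_jacobian_le",
    "classify_chaos",
    "sliding_window_le",
    "chaos_battery",
]

#: S-map local-weighting grid; theta = 0 is the global linear model.
DEFAULT_THETA_GRID = (0.0, 0.1, 0.3, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0)

#: positive-LE evidence threshold on the lower bound, per timestep
LE_LOWER_BOUND_THRESHOLD = 0.01

#: sliding-window length (timesteps)
DEFAULT_WINDOW = 50

Classification = Literal["chaotic_nonlinear", "chaos_growth_mix", "not_chaotic"]


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding hyperparameters: dimension E and lag tau (steps)."""

    E: int
    tau: int

    def __post_init__(self) -> None:
        if self.E < 1 or self.tau < 1:
            raise ValueError("need E >= 1 and tau >= 1")


@dataclass(frozen=True)
class LyapunovEstimate:
    """One Lyapunov-exponent estimate (per timestep units)."""

    lam: float
    lam_lb: float
    theta_opt: float | None
    method: Literal["rosenstein", "jacobian"]
    classification: Classification | None = None

    def __post_init__(self) -> None:
        if self.lam_lb > self.lam + 1e-12:
            raise ValueError("lower bound cannot exceed the point estimate")
        if self.theta_opt is not None and self.theta_opt < 0:
            raise ValueError("theta must be >= 0")


@dataclass(frozen=True)
class WindowedStability:
    """Sliding-window local stability: (start index, estimate) pairs."""

    window: int
    estimates: tuple[tuple[int, LyapunovEstimate], ...]

    def fraction(self, label: Classification) -> float:
        if not self.estimates:
            return 0.0
        hits = sum(e.classification == label for _, e in self.estimates)
        return hits / len(self.estimates)


def _transform(x: np.ndarray, transform: str) -> np.ndarray:
    x = np.asarray(x, float).ravel()
    if transform == "raw":
        return x
    if transform == "log1p":
        if np.any(x <= -1):
            raise ValueError("log1p transform needs values > -1; use transform='raw'")
        return np.log1p(x)
    raise ValueError(f"unknown transform {transform!r}")


def _check_series(x: np.ndarray, min_len: int = 20) -> np.ndarray:
    if x.size < min_len:
        raise ValueError(f"series too short ({x.size} < {min_len})")
    if np.ptp(x) == 0:
        raise ValueError("constant series: dynamics are unidentifiable")
    return x


def _embed(x: np.ndarray, E: int, tau: int) -> np.ndarray:
    """Delay vectors (x_t, x_{t-tau}, ..., x_{t-(E-1)tau}), newest first."""
    n = x.size - (E - 1) * tau
    if n < 2:
        raise ValueError("series too short for this embedding")
    # column j holds x_{t - j*tau}; column 0 is the newest coordinate
    cols = [x[(E - 1 - j) * tau : (E - 1 - j) * tau + n] for j in range(E)]
    return np.column_stack(cols)


def _average_mutual_information(x: np.ndarray, max_lag: int) -> tuple[np.ndarray, float]:
    """Histogram AMI over lags 1..max_lag on rank-uniformized marginals.

    Returns the AMI curve and the approximate independence floor of the
    estimator, (bins - 1)^2 / (2 n) nats — the bias a finite-sample
    histogram MI shows even for independent pairs.
    """
    n = x.size
    bins = int(np.clip(np.sqrt(n / 5.0), 4, 16))
    u = stats.rankdata(x, method="average") / (n + 1)
    ami = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        a, b = u[:-lag], u[lag:]
        h, _, _ = np.histogram2d(a, b, bins=bins, range=[[0, 1], [0, 1]])
        p = h / h.sum()
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        nz = p > 0
        ami[lag - 1] = np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz]))
    floor = (bins - 1) ** 2 / (2.0 * n)
    return ami, floor


def select_embedding(
    series: np.ndarray,
    transform: str = "log1p",
    max_lag: int = 10,
    max_dim: int = 6,
    fnn_threshold: float = 0.10,
) -> EmbeddingParams:
    """Choose the delay-embedding lag and dimension for one time series.

    The lag is the first local minimum of the average mutual information
    over lags 1..``max_lag`` (falling back to 1 when the AMI curve has no
    interior minimum, as for white noise); the dimension is the smallest
    E whose false-nearest-neighbour fraction drops below
    ``fnn_threshold`` (Kennel criteria), capped so the embedded cloud
    keeps enough points.
    """
    x = _check_series(_transform(series, transform))
    n = x.size
    max_lag = min(max_lag, max(1, n // 4))
    # one extra lag so a minimum sitting exactly at max_lag is detectable
    ami, floor = _average_mutual_information(x, min(max_lag + 1, max(2, n // 4)))
    tau = 1
    for k in range(1, min(max_lag, ami.size - 1)):
        # a minimum sitting at the estimator's independence floor means the
        # series has simply decorrelated; lag 1 is then the honest choice
        if ami[k] < ami[k - 1] and ami[k] <= ami[k + 1] and ami[k] > 2.0 * floor:
            tau = k + 1  # lags are 1-indexed
            break
    # keep at least ~12 embedded vectors at the largest candidate dimension
    while tau > 1 and n - (max_dim - 1) * tau < 12:
        tau -= 1
    feasible_dim = max(1, min(max_dim, (n - 12) // max(tau, 1) + 1))
    E = _fnn_dimension(x, tau, feasible_dim, fnn_threshold)
    return EmbeddingParams(E=E, tau=tau)


def _fnn_dimension(x: np.ndarray, tau: int, max_dim: int, threshold: float,
                   rtol: float = 15.0, atol: float = 2.0) -> int:
    sd = x.std()
    for E in range(1, max_dim + 1):
        if x.size - E * tau < 10:
            return max(1, E - 1)
        X = _embed(x, E, tau)
        m = X.shape[0] - tau  # need the (E+1)-th coordinate for each point
        if m < 10:
            return max(1, E - 1)
        Xc = X[:m]
        d = squareform(pdist(Xc))
        np.fill_diagonal(d, np.inf)
        nn = np.argmin(d, axis=1)
        dnn = d[np.arange(m), nn]
        # extra coordinate when the dimension is raised by one
        nxt = x[(E - 1) * tau + tau :]
        extra = np.abs(nxt[:m] - nxt[:m][nn])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dnn > 0, extra / dnn, np.inf)
        false = (ratio > rtol) | (np.sqrt(dnn**2 + extra**2) / max(sd, 1e-12) > atol)
        if false.mean() < threshold:
            return E
    return max_dim


def rosenstein_le(
    series: np.ndarray,
    emb: EmbeddingParams | None = None,
    transform: str = "log1p",
    max_steps: int | None = None,
) -> LyapunovEstimate:
    """Direct Lyapunov-exponent estimate after Rosenstein.

    Embeds the series, pairs every point with its nearest neighbour
    outside a Theiler window of ``tau`` steps, and fits the slope of the
    mean log divergence over the first ``max_steps`` (default
    min(10, T/10)) divergence steps.  The method is known to conflate
    noise-driven and chaos-driven divergence, so positive values are an
    upper envelope of evidence, not a classification.
    """
    x = _check_series(_transform(series, transform))
    if emb is None:
        emb = select_embedding(x, transform="raw")
    X = _embed(x, emb.E, emb.tau)
    m = X.shape[0]
    if m < 12:
        raise ValueError("too few embedded vectors for divergence tracking")
    max_steps = max_steps or max(3, min(10, x.size // 10))
    d = squareform(pdist(X))
    theiler = emb.tau
    idx = np.arange(m)
    mask = np.abs(idx[:, None] - idx[None, :]) <= theiler
    d_masked = np.where(mask, np.inf, d)
    nn = np.argmin(d_masked, axis=1)
    curve = []
    for k in range(1, max_steps + 1):
        valid = (idx + k < m) & (nn + k < m)
        if valid.sum() < 5:
            break
        sep = np.linalg.norm(X[idx[valid] + k] - X[nn[valid] + k], axis=1)
        sep = sep[sep > 0]
        if sep.size < 5:
            break
        curve.append(np.mean(np.log(sep)))
    if len(curve) < 2:
        raise ValueError("divergence curve too short to fit a slope")
    k = np.arange(1, len(curve) + 1, dtype=float)
    slope = np.polyfit(k, np.array(curve), 1)[0]
    return LyapunovEstimate(lam=float(slope), lam_lb=float(slope), theta_opt=None, method="rosenstein")


def _smap_loo(X: np.ndarray, y: np.ndarray, theta: float, ridge: float = 1e-8):
    """Leave-one-out S-map fits for one theta.

    Returns (predictions, coefficient matrix) where row t of the
    coefficient matrix holds the local linear map fitted at point t
    (intercept first, then one coefficient per embedding coordinate).
    """
    m, E = X.shape
    d = squareform(pdist(X))
    dbar = d.sum(axis=1) / np.maximum(m - 1, 1)
    dbar = np.maximum(dbar, 1e-12)
    W = np.exp(-theta * d / dbar[:, None])
    np.fill_diagonal(W, 0.0)  # leave-one-out
    Z = np.column_stack([np.ones(m), X])
    p = E + 1
    A = np.einsum("ij,jp,jq->ipq", W, Z, Z, optimize=True)
    A += ridge * np.trace(A, axis1=1, axis2=2)[:, None, None] / p * np.eye(p)
    b = np.einsum("ij,jp,j->ip", W, Z, y, optimize=True)
    coef = np.linalg.solve(A, b[..., None])[..., 0]
    pred = np.einsum("ip,ip->i", Z, coef)
    return pred, coef


def _lyapunov_from_jacobians(coefs: np.ndarray, E: int) -> tuple[float, np.ndarray]:
    """Leading exponent from a product of companion-matrix Jacobians.

    ``coefs`` holds per-time-point S-map coefficients (intercept first).
    Returns the exponent and the sequence of per-step log stretching
    factors from QR accumulation (used for the bootstrap lower bound).
    """
    C = coefs[:, 1:]  # (m, E): d x_{t+1} / d x_{t-j*tau}
    m = C.shape[0]
    if E == 1:
        incr = np.log(np.maximum(np.abs(C[:, 0]), 1e-12))
        return float(incr.mean()), incr
    Q = np.eye(E)
    incr = np.empty(m)
    for t in range(m):
        J = np.zeros((E, E))
        J[0] = C[t]
        J[1:, :-1] = np.eye(E - 1)
        M = J @ Q
        Q, R = np.linalg.qr(M)
        incr[t] = np.log(max(abs(R[0, 0]), 1e-12))
    return float(incr.mean()), incr


def _block_bootstrap_lb(incr: np.ndarray, n_boot: int, rng: np.random.Generator,
                        quantile: float = 0.05) -> float:
    """Stationary block bootstrap of the mean per-step log stretching."""
    m = incr.size
    block = max(2, int(round(np.sqrt(m))))
    means = np.empty(n_boot)
    for b in range(n_boot):
        out = np.empty(m)
        pos = 0
        while pos < m:
            start = rng.integers(m)
            length = min(rng.geometric(1.0 / block), m - pos)
            take = np.arange(start, start + length) % m
            out[pos : pos + length] = incr[take]
            pos += length
        means[b] = out.mean()
    return float(np.quantile(means, quantile))


def smap_jacobian_le(
    series: np.ndarray,
    emb: EmbeddingParams | None = None,
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
    transform: str = "log1p",
    n_boot: int = 200,
    seed: int | None = 0,
) -> LyapunovEstimate:
    """Indirect (Jacobian) Lyapunov exponent via S-map regression.

    For every theta on the grid, locally weighted linear maps are fitted
    by leave-one-out; the theta with the best forecast RMSE is selected
    (ties go to the smaller theta, so the linear model wins unless
    nonlinearity genuinely helps).  The exponent is the leading growth
    rate of the product of the fitted per-point companion Jacobians (QR
    accumulation); the lower bound is the 5th percentile of a stationary
    block bootstrap over the per-step log stretching factors.
    """
    x = _check_series(_transform(series, transform))
    if emb is None:
        emb = select_embedding(x, transform="raw")
    # standardize for numerical stability; Jacobians are scale-invariant
    xs = (x - x.mean()) / x.std()
    X_all = _embed(xs, emb.E, emb.tau)
    X = X_all[:-1]
    y = xs[(emb.E - 1) * emb.tau + 1 :]
    if X.shape[0] < 12:
        raise ValueError("too few embedded vectors for S-map fitting")
    best = None
    for theta in sorted(theta_grid):
        if theta < 0:
            raise ValueError("theta grid must be non-negative")
        pred, coef = _smap_loo(X, y, theta)
        rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
        # a larger theta must earn its keep: demand a >1% forecast
        # improvement, so chance fluctuations cannot flag nonlinearity
        if best is None or (best[0] > 1e-6 and rmse < best[0] * (1.0 - 0.01)):
            best = (rmse, float(theta), coef)
    _, theta_opt, coef = best
    lam, incr = _lyapunov_from_jacobians(coef, emb.E)
    rng = np.random.default_rng(seed)
    lb = _block_bootstrap_lb(incr, n_boot, rng)
    lb = min(lb, lam)
    est = LyapunovEstimate(lam=lam, lam_lb=lb, theta_opt=theta_opt, method="jacobian")
    return replace(est, classification=classify_chaos(est))


def classify_chaos(est: LyapunovEstimate) -> Classification:
    """Conservative chaos label from an exponent estimate.

    ``chaotic_nonlinear``: lower bound > 0.01 and a nonlinear S-map
    (theta > 0) forecasts best.  ``chaos_growth_mix``: lower bound >
    0.01 but the globally linear model suffices (theta = 0), i.e. the
    positive exponent may just reflect exponential growth.  Everything
    else is ``not_chaotic``.
    """
    positive = est.lam_lb > LE_LOWER_BOUND_THRESHOLD
    if not positive:
        return "not_chaotic"
    theta = est.theta_opt if est.theta_opt is not None else 0.0
    return "chaotic_nonlinear" if theta > 0 else "chaos_growth_mix"


def sliding_window_le(
    series: np.ndarray,
    w: int = DEFAULT_WINDOW,
    transform: str = "log1p",
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
    n_boot: int = 200,
    seed: int | None = 0,
) -> WindowedStability:
    """Local stability via Jacobian LE on sliding windows of length ``w``.

    Windows advance by one step and number T - w (55 for the standard
    105-step series), each analysed with its own embedding selection,
    S-map exponent and classification.
    """
    x = np.asarray(series, float).ravel()
    if x.size <= w:
        raise ValueError(f"need more than w={w} points, got {x.size}")
    out = []
    for start in range(x.size - w):
        seg = x[start : start + w]
        try:
            est = smap_jacobian_le(seg, transform=transform, theta_grid=theta_grid,
                                   n_boot=n_boot, seed=seed)
        except ValueError:
            est = LyapunovEstimate(lam=float("-inf"), lam_lb=float("-inf"),
                                   theta_opt=0.0, method="jacobian",
                                   classification="not_chaotic")
        out.append((start, est))
    return WindowedStability(window=w, estimates=tuple(out))


def chaos_battery(
    series: AbundanceSeries,
    methods: Sequence[str] = ("jacobian", "rosenstein"),
    transform: str = "log1p",
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
    n_boot: int = 200,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Run the requested LE estimators on every patch series.

    Returns a tidy frame with columns ``patch_id, method, lam, lam_lb,
    theta_opt, classification``; patches whose series defeat an estimator
    (constant, too short) appear with NaN results.
    """
    rows = []
    for k, pid in enumerate(series.patch_ids):
        x = series.values[k]
        for method in methods:
            lam = lam_lb = theta = np.nan
            label = None
            try:
                if method == "jacobian":
                    est = smap_jacobian_le(x, transform=transform, theta_grid=theta_grid,
                                           n_boot=n_boot, seed=seed)
                    theta = est.theta_opt
                elif method == "rosenstein":
                    est = rosenstein_le(x, transform=transform)
                else:
                    raise ValueError(f"unknown method {method!r}")
                lam, lam_lb, label = est.lam, est.lam_lb, est.classification
            except ValueError:
                pass
            rows.append({"patch_id": pid, "method": method, "lam": lam,
                         "lam_lb": lam_lb, "theta_opt": theta, "classification": label})
    return pd.DataFrame(rows)
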