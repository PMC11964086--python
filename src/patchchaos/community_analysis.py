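"""Multivariate structure over time and space.

Treats each timestep's 50-patch abundance vector like a community sample:
Bray-Curtis dissimilarity between timepoints (how much the spatial
distribution reorganizes over time), dynamic-time-warping distance
between patch trajectories (how similarly patches behave), PERMANOVA
variance partitioning of either matrix against time or chip position,
and NMDS ordination for visualization.

PERMANOVA here is the distance-based linear model: the dissimilarity
matrix is Gower-centred, covariates (continuous by default — timestep
index, or x/y chip coordinates fitted sequentially) define a hat-matrix
projection, and R^2 = SS_term / SS_total with a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from numba import njit
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from patchchaos.chip_topology import ChipGraph
from patchchaos.population_models import AbundanceSeries

__all__ = [
    "DissimilarityMatrix",
    "PermanovaResult",
    "NmdsResult",
    "bray_curtis_matrix",
    "dtw_matrix",
    "dtw_distance",
    "permanova",
    "permanova_position",
    "nmds",
]


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric non-negative dissimilarities with a metric tag."""

    d: np.ndarray
    metric: Literal["bray_curtis", "dtw"]
    object_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.d, float)
        object.__setattr__(self, "d", d)
        if d.shape != (len(self.object_ids),) * 2:
            raise ValueError("dissimilarity matrix must be square over object_ids")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise ValueError("need a symmetric non-negative matrix with zero diagonal")

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class PermanovaResult:
    term: str
    R2: float
    pseudo_F: float
    p_perm: float
    n_perm: int

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.R2 <= 1 + 1e-9):
            raise ValueError("R2 must lie in [0, 1]")


@dataclass(frozen=True)
class NmdsResult:
    coords: np.ndarray   # (n, k), centred
    stress: float        # Kruskal stress-1


def bray_curtis_matrix(series: AbundanceSeries, axis: str = "timepoints") -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity between timepoint abundance vectors.

    BC(u, v) = sum|u - v| / sum(u + v) over patches; 0 for identical
    distributions, 1 for disjoint ones.
    """
    if axis != "timepoints":
        raise ValueError("Bray-Curtis is computed between timepoints here")
    m = series.values.T  # (T, P)
    if np.any(m.sum(axis=1) <= 0):
        raise ValueError("every timepoint needs positive total abundance")
    d = squareform(pdist(m, metric="braycurtis"))
    return DissimilarityMatrix(d, "bray_curtis", tuple(range(series.n_steps)))


@njit(cache=True)
def _dtw_cost(a, b):  # pragma: no cover - exercised through dtw_distance
    n, m = a.size, b.size
    big = 1e300
    D = np.full((n + 1, m + 1), big)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = abs(a[i - 1] - b[j - 1])
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = c + best
    return D[n, m]


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Classic dynamic-time-warping cost (symmetric step, no window)."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("series must have length >= 2")
    return float(_dtw_cost(a, b))


def dtw_matrix(series: AbundanceSeries, axis: str = "patches") -> DissimilarityMatrix:
    """Pairwise DTW distance between patch time series."""
    if axis != "patches":
        raise ValueError("DTW is computed between patch series here")
    v = series.values
    p = series.n_patches
    d = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            d[i, j] = d[j, i] = _dtw_cost(v[i], v[j])
    return DissimilarityMatrix(d, "dtw", series.patch_ids)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(Xc: np.ndarray) -> np.ndarray:
    # projection onto the column space of the centred covariates
    q, r = np.linalg.qr(Xc)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def permanova(
    dm: DissimilarityMatrix,
    covariate: np.ndarray,
    term: str = "covariate",
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    categorical: bool = False,
) -> PermanovaResult:
    """Distance-based variance partition for a single explanatory term.

    The covariate may be continuous (default; e.g. the timestep index) or
    categorical (dummy-coded).  SS_term = tr(H G H) on the Gower-centred
    matrix G, R^2 = SS_term / SS_total, pseudo-F uses the residual
    degrees of freedom, and the p-value permutes object labels.
    """
    rng = np.random.default_rng() if rng is None else rng
    cov = np.asarray(covariate)
    if cov.shape[0] != dm.n:
        raise ValueError("covariate length must match the number of objects")
    if categorical:
        levels = pd.unique(cov)
        if len(levels) < 2:
            raise ValueError("categorical covariate needs >= 2 levels")
        X = np.column_stack([(cov == lv).astype(float) for lv in levels[:-1]])
    else:
        X = np.asarray(cov, float).reshape(dm.n, -1)
        if np.all(np.ptp(X, axis=0) == 0):
            raise ValueError("constant covariate explains nothing")
    Xc = X - X.mean(axis=0)
    G = _gower_center(dm.d)
    ss_total = np.trace(G)
    H = _hat(Xc)
    df_model = int(round(np.trace(H)))
    df_resid = dm.n - df_model - 1
    if df_resid <= 0:
        raise ValueError("not enough objects for the requested model")

    def _stat(g: np.ndarray) -> tuple[float, float]:
        # tr(H g H) = tr(g H) for idempotent symmetric H
        ss = float(np.sum(g * H))
        resid = (ss_total - ss) / df_resid
        # a perfect partition (zero residual) gets an infinite pseudo-F
        f = np.inf if resid <= 0 else (ss / df_model) / resid
        return ss, f

    ss_obs, f_obs = _stat(G)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(dm.n)
        _, f_p = _stat(G[np.ix_(perm, perm)])
        if f_p >= f_obs - 1e-15:
            count += 1
    return PermanovaResult(term=term, R2=float(ss_obs / ss_total), pseudo_F=float(f_obs),
                           p_perm=(1 + count) / (n_perm + 1), n_perm=n_perm)


def permanova_position(
    dm: DissimilarityMatrix,
    graph: ChipGraph,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> dict[str, PermanovaResult]:
    """Partition a patch-level dissimilarity matrix by chip position.

    Fits x (along the chip length) and y (across the width) sequentially,
    so their explained-variance shares can be compared, plus the joint
    position model.  Patch order of ``dm`` must match the graph.
    """
    if dm.object_ids != graph.patch_ids:
        raise ValueError("dissimilarity object ids must match graph patch ids")
    rng = np.random.default_rng() if rng is None else rng
    coords = graph.coord_array()
    out = {
        "position_x": permanova(dm, coords[:, 0], "position_x", n_perm, rng),
        "position_y": permanova(dm, coords[:, 1], "position_y", n_perm, rng),
        "position": permanova(dm, coords, "position", n_perm, rng),
    }
    return out


def nmds(dm: DissimilarityMatrix, k: int = 2, seed: int | None = 0,
         n_init: int = 20, max_iter: int = 500) -> NmdsResult:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    SMACOF with monotone regression from ``n_init`` random starts;
    reports Kruskal stress-1.  Coordinates are centred; the configuration
    is reproducible from the seed.
    """
    if k >= dm.n:
        raise ValueError("embedding dimension must be below the object count")
    mds = MDS(n_components=k, metric_mds=False, metric="precomputed",
              n_init=n_init, init="random", max_iter=max_iter,
              random_state=seed, normalized_stress=True, eps=1e-9)
    coords = mds.fit_transform(dm.d)
    coords = coords - coords.mean(axis=0)
    return NmdsResult(coords=coords, stress=float(mds.stress_))
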