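"""Spatial statistics on the patch network.

Per-timestep spatial autocorrelation (Moran's I over the chip adjacency,
with a Monte-Carlo permutation test) and the between-patch correlation
structure (pairwise Spearman on total-normalized abundances with Holm
family-wise correction), plus the correlation-versus-graph-distance
summary.

Abundances are normalized by the total at each timestep before
correlation analysis so the shared exponential growth trend does not
masquerade as spatial association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from patchchaos.chip_topology import ChipGraph, DistanceMatrix
from patchchaos.population_models import AbundanceSeries

__all__ = [
    "MoranResult",
    "CorrelationStructure",
    "DistanceDecay",
    "normalize_by_total",
    "morans_i",
    "morans_i_mc",
    "moran_by_timestep",
    "pairwise_spearman_holm",
    "correlation_by_distance",
]

DEFAULT_N_PERM = 12_000


@dataclass(frozen=True)
class MoranResult:
    I: float
    p_mc: float
    n_perm: int

    def __post_init__(self) -> None:
        if not (0 < self.p_mc <= 1):
            raise ValueError("permutation p-value must be in (0, 1]")


@dataclass(frozen=True)
class CorrelationStructure:
    """Pairwise Spearman coefficients with Holm-adjusted p-values."""

    patch_ids: tuple[int, ...]
    rho: np.ndarray        # (P, P), symmetric, unit diagonal
    p_adj: np.ndarray      # (P, P), Holm-adjusted, NaN for undefined pairs
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            sig = self.p_adj < self.alpha
        np.fill_diagonal(sig, False)
        return sig

    def fraction_significant(self) -> float:
        """Share of unordered patch pairs with a significant correlation."""
        p = len(self.patch_ids)
        iu = np.triu_indices(p, k=1)
        return float(np.mean(self.significant[iu]))


@dataclass(frozen=True)
class DistanceDecay:
    """Mean correlation per integer graph-distance class."""

    distances: np.ndarray   # (K,), sorted unique distances >= 1
    mean_rho: np.ndarray
    sem_rho: np.ndarray
    counts: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"distance": self.distances, "mean_rho": self.mean_rho,
                             "sem_rho": self.sem_rho, "n_pairs": self.counts})


def normalize_by_total(series: AbundanceSeries) -> AbundanceSeries:
    """Relative abundances: each timestep column rescaled to sum to 1."""
    totals = series.totals()
    if np.any(totals <= 0):
        t = int(np.argmax(totals <= 0))
        raise ValueError(f"timestep {t} has non-positive total abundance")
    return AbundanceSeries(series.values / totals[None, :], series.times, series.patch_ids)


def _weights(graph: ChipGraph, style: str) -> np.ndarray:
    w = graph.adjacency_matrix()
    if style == "row_standardized":
        rs = w.sum(axis=1, keepdims=True)
        w = np.divide(w, rs, out=np.zeros_like(w), where=rs > 0)
    elif style != "binary":
        raise ValueError(f"unknown weight style {style!r}")
    return w


def morans_i(values: np.ndarray, graph: ChipGraph, style: str = "row_standardized") -> float:
    """Moran's I of one per-patch field over the chip adjacency.

    I = (n / S0) * (z' W z) / (z' z) with z the centered field and W the
    (default row-standardized) binary adjacency weights.  Raises on a
    constant field, where the statistic is undefined.
    """
    z = np.asarray(values, float).ravel()
    if z.size != graph.n_patches:
        raise ValueError("values length must match patch count")
    if z.size < 3:
        raise ValueError("need at least 3 patches")
    if np.ptp(z) == 0:
        raise ValueError("Moran's I undefined for a constant field")
    w = _weights(graph, style)
    zc = z - z.mean()
    s0 = w.sum()
    return float(z.size / s0 * (zc @ w @ zc) / (zc @ zc))


def morans_i_mc(
    values: np.ndarray,
    graph: ChipGraph,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
    style: str = "row_standardized",
) -> MoranResult:
    """Monte-Carlo permutation test of Moran's I (one-sided, greater).

    The field is randomly relabelled over patches ``n_perm`` times;
    p = (1 + #{I_perm >= I_obs}) / (n_perm + 1).  One-sided because only
    positive autocorrelation (clustering) is of interest here.
    """
    rng = np.random.default_rng() if rng is None else rng
    z = np.asarray(values, float).ravel()
    i_obs = morans_i(z, graph, style)
    w = _weights(graph, style)
    s0 = w.sum()
    n = z.size
    zc = z - z.mean()
    denom = zc @ zc
    count = 0
    remaining = n_perm
    while remaining > 0:  # batched to bound memory at large n_perm
        batch = min(remaining, 4000)
        zp = rng.permuted(np.tile(zc, (batch, 1)), axis=1)
        i_perm = n / s0 * np.einsum("pi,ij,pj->p", zp, w, zp, optimize=True) / denom
        count += int(np.sum(i_perm >= i_obs - 1e-15))
        remaining -= batch
    return MoranResult(I=i_obs, p_mc=(1 + count) / (n_perm + 1), n_perm=n_perm)


def moran_by_timestep(
    series: AbundanceSeries,
    graph: ChipGraph,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    style: str = "row_standardized",
) -> pd.DataFrame:
    """Moran's I permutation test at every timestep, Holm-adjusted.

    All timesteps of one experiment form a single Holm family.  Returns a
    tidy frame ``timestep, I, p_raw, p_adj, significant``; constant
    fields yield NaN rows (undefined statistic).
    """
    rng = np.random.default_rng() if rng is None else rng
    rows = []
    for t in range(series.n_steps):
        field = series.values[:, t]
        try:
            res = morans_i_mc(field, graph, n_perm=n_perm, rng=rng, style=style)
            rows.append({"timestep": t, "I": res.I, "p_raw": res.p_mc})
        except ValueError:
            rows.append({"timestep": t, "I": np.nan, "p_raw": np.nan})
    df = pd.DataFrame(rows)
    ok = df["p_raw"].notna()
    df["p_adj"] = np.nan
    if ok.any():
        df.loc[ok, "p_adj"] = multipletests(df.loc[ok, "p_raw"], method="holm")[1]
    df["significant"] = df["p_adj"] < alpha
    return df


def pairwise_spearman_holm(series: AbundanceSeries, alpha: float = 0.05) -> CorrelationStructure:
    """Spearman correlation between every pair of patch time series.

    Expects total-normalized abundances (see :func:`normalize_by_total`);
    all P(P-1)/2 raw p-values form one Holm family.  Pairs involving a
    constant series are flagged undefined (NaN).
    """
    if series.n_steps < 5:
        raise ValueError("need at least 5 timesteps for rank correlation")
    v = series.values
    p = series.n_patches
    constant = np.ptp(v, axis=1) == 0
    rho = np.full((p, p), np.nan)
    pval = np.full((p, p), np.nan)
    np.fill_diagonal(rho, 1.0)
    for i in range(p):
        for j in range(i + 1, p):
            if constant[i] or constant[j]:
                continue  # rank correlation undefined for a flat series
            r, pv = stats.spearmanr(v[i], v[j])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = pv
    iu = np.triu_indices(p, k=1)
    raw = pval[iu]
    adj_mat = np.full((p, p), np.nan)
    ok = ~np.isnan(raw)
    if ok.any():
        adj = np.full(raw.shape, np.nan)
        adj[ok] = multipletests(raw[ok], method="holm")[1]
        adj_mat[iu] = adj
        adj_mat[(iu[1], iu[0])] = adj
    return CorrelationStructure(series.patch_ids, rho, adj_mat, alpha=alpha)


def correlation_by_distance(cs: CorrelationStructure, dm: DistanceMatrix) -> DistanceDecay:
    """Mean +/- SEM of the pairwise correlation per graph-distance class."""
    if cs.patch_ids != dm.patch_ids:
        raise ValueError("patch ids of correlations and distances do not match")
    p = len(cs.patch_ids)
    iu = np.triu_indices(p, k=1)
    rho = cs.rho[iu]
    dist = dm.d[iu]
    classes = np.unique(dist)
    mean, sem, counts = [], [], []
    for d in classes:
        vals = rho[dist == d]
        counts.append(vals.size)
        vals = vals[~np.isnan(vals)]
        mean.append(vals.mean() if vals.size else np.nan)
        sem.append(vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan)
    return DistanceDecay(classes.astype(int), np.array(mean), np.array(sem), np.array(counts))
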