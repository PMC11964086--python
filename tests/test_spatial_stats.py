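"""Moran's I, permutation testing, correlation structure and distance decay."""

import numpy as np
import pytest
from scipy import stats

from patchchaos.chip_topology import min_path_distances
from patchchaos.population_models import AbundanceSeries, SimulationConfig
from patchchaos.spatial_stats import (
    correlation_by_distance,
    moran_by_timestep,
    morans_i,
    morans_i_mc,
    normalize_by_total,
    pairwise_spearman_holm,
)
from patchchaos.synthetic_data import generate_experiment_set

from conftest import make_cycle_graph, make_path_graph


def morans_i_brute(values, graph, style="row_standardized"):
    """Literal double-sum evaluation of the Moran formula."""
    z = np.asarray(values, float)
    n = z.size
    ids = graph.patch_ids
    w = np.zeros((n, n))
    for a, b in graph.adjacency:
        i, j = ids.index(a), ids.index(b)
        w[i, j] = w[j, i] = 1.0
    if style == "row_standardized":
        w = w / w.sum(axis=1, keepdims=True)
    zb = z.mean()
    num = sum(w[i, j] * (z[i] - zb) * (z[j] - zb) for i in range(n) for j in range(n))
    den = sum((z[i] - zb) ** 2 for i in range(n))
    return n / w.sum() * num / den


class TestMoransI:
    def test_path_graph_matches_formula(self, path4):
        assert morans_i([1, 2, 3, 4], path4) == pytest.approx(
            morans_i_brute([1, 2, 3, 4], path4)
        )

    @pytest.mark.parametrize("style", ["row_standardized", "binary"])
    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_oracle_on_random_small_graphs(self, style, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        g = make_cycle_graph(n) if seed % 2 else make_path_graph(n)
        z = rng.normal(size=n)
        assert morans_i(z, g, style) == pytest.approx(morans_i_brute(z, g, style))

    def test_alternating_cycle_is_perfectly_negative(self):
        g6 = make_cycle_graph(6)
        assert morans_i([1, -1, 1, -1, 1, -1], g6) == pytest.approx(-1.0)

    def test_constant_field_undefined(self, path4):
        with pytest.raises(ValueError, match="undefined"):
            morans_i([2, 2, 2, 2], path4)


class TestMoranPermutation:
    def test_smooth_gradient_gives_small_p(self, chip, rng):
        x = chip.coord_array()[:, 0]  # field = position along the chip
        res = morans_i_mc(x, chip, n_perm=999, rng=rng)
        assert res.I > 0
        assert res.p_mc <= 0.01

    def test_default_permutation_count(self):
        import inspect

        from patchchaos.spatial_stats import DEFAULT_N_PERM, morans_i_mc as f
        assert DEFAULT_N_PERM == 12_000
        assert inspect.signature(f).parameters["n_perm"].default == 12_000

    def test_null_p_values_are_uniform(self, chip):
        # shuffled fields: the permutation p-value must be uniform
        rng = np.random.default_rng(0)
        pvals = [
            morans_i_mc(rng.permutation(np.arange(50.0)), chip, n_perm=500, rng=rng).p_mc
            for _ in range(200)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_p_bounded_below_by_permutation_resolution(self, chip, rng):
        res = morans_i_mc(chip.coord_array()[:, 0], chip, n_perm=99, rng=rng)
        assert res.p_mc >= 1 / 100


class TestNormalization:
    def test_columns_sum_to_one(self, chip):
        s = generate_experiment_set(chip, n=1, seed=0).experiments[0]
        rel = normalize_by_total(s)
        assert np.allclose(rel.values.sum(axis=0), 1.0, atol=1e-12)

    def test_scale_invariance_per_timestep(self, path4):
        v = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])
        a = normalize_by_total(AbundanceSeries(v, [0, 1], (1, 2, 3, 4)))
        v2 = v.copy()
        v2[:, 1] *= 10
        b = normalize_by_total(AbundanceSeries(v2, [0, 1], (1, 2, 3, 4)))
        assert np.allclose(a.values, b.values)

    def test_zero_total_timestep_rejected(self, path4):
        v = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="timestep 1"):
            normalize_by_total(AbundanceSeries(v, [0, 1], (1, 2, 3, 4)))


class TestSpearmanHolm:
    def test_diagonal_is_unity_and_symmetric(self, chip):
        s = generate_experiment_set(chip, n=1, seed=3).experiments[0]
        cs = pairwise_spearman_holm(normalize_by_total(s))
        assert np.allclose(np.diag(cs.rho), 1.0)
        assert np.allclose(cs.rho, cs.rho.T, equal_nan=True)

    def test_rank_invariance_under_monotone_transform(self, path4, rng):
        v = rng.uniform(1, 10, size=(4, 30))
        a = pairwise_spearman_holm(AbundanceSeries(v, np.arange(30), (1, 2, 3, 4)))
        b = pairwise_spearman_holm(AbundanceSeries(np.exp(v / 3), np.arange(30), (1, 2, 3, 4)))
        assert np.allclose(a.rho, b.rho)

    def test_adjusted_p_never_smaller_than_raw(self, chip):
        s = generate_experiment_set(chip, n=1, seed=6).experiments[0]
        df = moran_by_timestep(s, chip, n_perm=99, rng=np.random.default_rng(1))
        ok = df["p_adj"].notna()
        assert np.all(df.loc[ok, "p_adj"] >= df.loc[ok, "p_raw"] - 1e-12)

    def test_constant_patch_flagged_undefined(self):
        v = np.vstack([np.full(30, 5.0), np.random.default_rng(0).uniform(1, 2, 30),
                       np.random.default_rng(1).uniform(1, 2, 30)])
        cs = pairwise_spearman_holm(AbundanceSeries(v, np.arange(30), (1, 2, 3)))
        assert np.isnan(cs.rho[0, 1]) and np.isnan(cs.p_adj[0, 1])
        assert np.isfinite(cs.rho[1, 2])


class TestDistanceDecay:
    def test_two_patch_single_class(self):
        g = make_path_graph(2)
        v = np.vstack([np.arange(10.0) + 1, (np.arange(10.0) + 1)[::-1]])
        cs = pairwise_spearman_holm(AbundanceSeries(v, np.arange(10), (1, 2)))
        dd = correlation_by_distance(cs, min_path_distances(g))
        assert list(dd.distances) == [1]
        assert dd.mean_rho[0] == pytest.approx(cs.rho[0, 1])

    def test_hand_built_4_patch_class_means(self, path4, rng):
        v = rng.uniform(1, 5, size=(4, 40))
        cs = pairwise_spearman_holm(AbundanceSeries(v, np.arange(40), (1, 2, 3, 4)))
        dd = correlation_by_distance(cs, min_path_distances(path4))
        rho = cs.rho
        assert dd.counts.sum() == 6
        assert dd.mean_rho[0] == pytest.approx(np.mean([rho[0, 1], rho[1, 2], rho[2, 3]]))
        assert dd.mean_rho[1] == pytest.approx(np.mean([rho[0, 2], rho[1, 3]]))
        assert dd.mean_rho[2] == pytest.approx(rho[0, 3])

    def test_default_chip_classes_extend_beyond_5(self, chip):
        s = generate_experiment_set(chip, n=1, seed=4).experiments[0]
        cs = pairwise_spearman_holm(normalize_by_total(s))
        dd = correlation_by_distance(cs, min_path_distances(chip))
        assert dd.distances.max() > 5


def holm_stepdown(p):
    """Textbook Holm step-down: monotone max of (m - i) * p_(i), capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def test_moran_by_timestep_uses_holm_family_over_timesteps(chip):
    cfg = SimulationConfig(steps=12)
    s = generate_experiment_set(chip, n=1, seed=5, config=cfg).experiments[0]
    df = moran_by_timestep(s, chip, n_perm=199, rng=np.random.default_rng(0))
    assert len(df) == 12
    ok = df["p_adj"].notna()
    assert np.allclose(df.loc[ok, "p_adj"], holm_stepdown(df.loc[ok, "p_raw"]))
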