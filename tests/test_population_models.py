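"""Simulators: transition sampling, exact interval propagation, both models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchchaos.population_models import (
    AbundanceSeries,
    DensityDependenceParams,
    SimulationConfig,
    integrate_interval,
    read_series_csv,
    run_deterministic_model,
    run_stochastic_model,
    sample_transition_matrix,
    write_series_csv,
)

from conftest import make_path_graph


class TestTransitionSampling:
    def test_degenerate_normal_gives_exact_total_efflux(self, chip, rng):
        tm = sample_transition_matrix(chip, 0.60, 0.0, "per_patch_total", rng)
        assert np.allclose(tm.efflux(), 0.60)

    def test_rates_only_on_edges(self, chip, rng):
        tm = sample_transition_matrix(chip, 0.60, 0.15, "per_patch_total", rng)
        off_graph = (chip.adjacency_matrix() == 0) & ~np.eye(50, dtype=bool)
        assert np.all(tm.rates[off_graph] == 0)
        assert np.all(np.diag(tm.rates) == 0)

    @pytest.mark.parametrize("mode", ["per_patch_total", "per_edge"])
    def test_mean_total_efflux_matches_calibration(self, chip, mode, rng):
        # 10^4 per-patch draws: sample mean of the total efflux ~ 0.60/min
        effl = np.concatenate([
            sample_transition_matrix(chip, 0.60, 0.15, mode, rng).efflux()
            for _ in range(200)
        ])
        se = effl.std() / np.sqrt(effl.size)
        assert abs(effl.mean() - 0.60) < 4 * se

    def test_negative_draws_truncate_to_zero(self, chip, rng):
        tm = sample_transition_matrix(chip, 0.01, 10.0, "per_patch_total", rng)
        assert np.all(tm.rates >= 0)


class TestIntegrateInterval:
    def test_mass_conserved_without_growth(self, chip, rng):
        tm = sample_transition_matrix(chip, 0.6, 0.15, rng=rng)
        y0 = rng.uniform(0, 100, size=50)
        y1 = integrate_interval(y0, tm, g=0.0, dt=6.333)
        assert y1.sum() == pytest.approx(y0.sum(), rel=1e-8)

    def test_isolated_patch_grows_exponentially(self):
        y1 = integrate_interval([100.0], np.zeros((1, 1)), g=4.51, dt=633.0)
        assert y1[0] == pytest.approx(100.0 * math.exp(4.51 * 633.0 / 1440.0), rel=1e-9)

    def test_two_patch_difference_decays_at_2r(self):
        # eigenmodes of the symmetric 2-patch system: sum constant,
        # difference decaying at rate 2r
        r, dt = 0.3, 5.0
        A = np.array([[0.0, r], [r, 0.0]])
        y0 = np.array([80.0, 20.0])
        y1 = integrate_interval(y0, A, g=0.0, dt=dt)
        expected = (y0[0] - y0[1]) * math.exp(-2 * r * dt)
        assert y1[0] - y1[1] == pytest.approx(expected, rel=1e-9)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            integrate_interval([-1.0, 2.0], np.zeros((2, 2)), g=0.0, dt=1.0)


class TestStochasticModel:
    def test_same_seed_is_bit_identical(self, chip):
        cfg = SimulationConfig(seed=7)
        a = run_stochastic_model(chip, cfg, init=2000.0)
        b = run_stochastic_model(chip, cfg, init=2000.0)
        assert np.array_equal(a.values, b.values)

    def test_total_follows_growth_closed_form(self, chip):
        cfg = SimulationConfig(seed=1, g_sd=0.0)
        s = run_stochastic_model(chip, cfg, init=1159.0)
        t_total = s.times[-1]
        assert s.totals()[-1] == pytest.approx(
            1159.0 * math.exp(4.51 * t_total / 1440.0), rel=1e-6
        )

    def test_symmetric_two_patch_uniform_stays_uniform(self):
        g2 = make_path_graph(2)
        cfg = SimulationConfig(seed=0, sigma=0.0, g_sd=0.0, steps=20)
        s = run_stochastic_model(g2, cfg, init=np.array([500.0, 500.0]))
        assert np.allclose(s.values[0], s.values[1])

    def test_mass_conserved_over_full_run(self, chip):
        cfg = SimulationConfig(seed=3, g_mean=0.0, g_sd=0.0)
        s = run_stochastic_model(chip, cfg, init=2500.0)
        assert np.all(np.abs(s.totals() - s.totals()[0]) / s.totals()[0] < 1e-6)

    def test_non_negative_everywhere(self, chip):
        s = run_stochastic_model(chip, SimulationConfig(seed=11), init=1200.0)
        assert np.all(s.values >= 0)

    def test_mean_final_total_matches_expectation(self, chip):
        # 200 runs at fixed g: transitions cancel in the total, so the
        # mean final total must match the closed form within 2 SE
        cfg = SimulationConfig(g_sd=0.0, steps=30)
        rng = np.random.default_rng(5)
        finals = np.array([
            run_stochastic_model(chip, cfg, init=1000.0, rng=rng).totals()[-1]
            for _ in range(200)
        ])
        expected = 1000.0 * math.exp(4.51 * (29 * cfg.dt) / 1440.0)
        se = finals.std(ddof=1) / np.sqrt(finals.size)
        assert abs(finals.mean() - expected) <= max(2 * se, 1e-6 * expected)


class TestDeterministicModel:
    def test_beta_zero_reduces_to_constant_rate_run(self, chip, rng):
        alloc = rng.multinomial(3000, np.full(50, 1 / 50)).astype(float)
        cfg = SimulationConfig(g_sd=0.0, sigma=0.0, seed=0)
        det = run_deterministic_model(chip, cfg, DensityDependenceParams(beta=0.0), init=alloc)
        sto = run_stochastic_model(chip, cfg, init=alloc.copy())
        assert np.allclose(det.values, sto.values, rtol=1e-10)

    def test_identical_inputs_identical_output(self, chip, rng):
        alloc = rng.multinomial(2000, np.full(50, 1 / 50)).astype(float)
        cfg = SimulationConfig(g_sd=0.0)
        dd = DensityDependenceParams()
        a = run_deterministic_model(chip, cfg, dd, init=alloc)
        b = run_deterministic_model(chip, cfg, dd, init=alloc.copy())
        assert np.array_equal(a.values, b.values)

    def test_perturbed_initial_condition_diverges_measurably(self, chip, rng):
        alloc = rng.multinomial(3000, np.full(50, 1 / 50)).astype(float)
        pert = alloc.copy()
        pert[10] *= 1.01
        cfg = SimulationConfig(g_sd=0.0)
        dd = DensityDependenceParams()
        a = run_deterministic_model(chip, cfg, dd, init=alloc)
        b = run_deterministic_model(chip, cfg, dd, init=pert)
        rel = np.max(np.abs(a.values[:, -1] - b.values[:, -1]) / np.maximum(a.values[:, -1], 1e-9))
        assert rel > 1e-4  # far above solver tolerance

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DensityDependenceParams(a_min=0.5, a_max=0.1)


@settings(deadline=None, max_examples=20)
@given(
    n=st.integers(2, 5),
    total=st.floats(10.0, 1e4),
    r=st.floats(0.0, 2.0),
    seed=st.integers(0, 2**16),
)
def test_mass_balance_property_on_path_graphs(n, total, r, seed):
    """Without growth, any rate matrix on any path graph conserves mass."""
    g = make_path_graph(n)
    rng = np.random.default_rng(seed)
    y0 = rng.dirichlet(np.ones(n)) * total
    tm = sample_transition_matrix(g, r, r / 4 if r else 0.0, rng=rng)
    y1 = integrate_interval(y0, tm, g=0.0, dt=6.333)
    assert y1.sum() == pytest.approx(total, rel=1e-8)
    assert np.all(y1 >= 0)


def test_series_csv_roundtrip(tmp_path, chip):
    s = run_stochastic_model(chip, SimulationConfig(seed=2, steps=10), init=800.0)
    path = tmp_path / "series.csv"
    write_series_csv(s, path, metadata={"seed": 2})
    back = read_series_csv(path)
    assert back.patch_ids == s.patch_ids
    assert np.allclose(back.values, s.values)
    assert (tmp_path / "series.meta.json").exists()


def test_series_validation():
    with pytest.raises(ValueError):
        AbundanceSeries(np.ones((2, 3)) * -1, np.arange(3), (1, 2))
    with pytest.raises(ValueError):
        AbundanceSeries(np.ones((2, 3)), np.array([0.0, 0.0, 1.0]), (1, 2))
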