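"""Simulator ground-truth invariants and the coverage downsampler."""

import math

import numpy as np
import pytest
from scipy import stats

import hitchdriver as hd


def brute_force_carriers(tumor):
    """Oracle: recount carriers by walking every final cell's mutation
    chain, independently of the subtree-accumulation path."""
    counts = np.zeros(len(tumor.parents), dtype=np.int64)
    for g in tumor.final_genotypes:
        node = int(g)
        while node >= 0:
            counts[node] += 1
            node = int(tumor.parents[node])
    return counts


class TestBirthDeath:
    def test_infinite_sites_and_nesting(self, small_tumor):
        t = small_tumor
        assert np.all(t.parents < np.arange(len(t.parents)))  # parents precede children
        child_ok = t.parents >= 0
        # a mutation's carriers are a subset of its parent's carriers
        assert np.all(
            t.carriers[child_ok] <= t.carriers[t.parents[child_ok]]
        )

    def test_carrier_counts_match_brute_force(self):
        cfg = hd.SimConfig(k=2.0, trigger_population=30, max_population=600)
        t = hd.simulate_birth_death(cfg, seed=4)
        np.testing.assert_array_equal(t.carriers, brute_force_carriers(t))
        assert t.carriers.sum() > 0
        assert np.all(t.frequencies <= 1.0)

    def test_hitchhikers_dominate_driver(self, small_tumor):
        t = small_tumor
        f_d = t.driver_frequency
        hh = t.hitchhiker_ids()
        assert len(hh) > 0
        assert np.all(t.frequencies[hh] >= f_d)

    def test_neutral_frequency_rank_tracks_occurrence(self):
        """Pure-birth neutral growth: the j-th mutation's frequency is
        about 1/j and rank order follows occurrence order."""
        cfg = hd.SimConfig(k=1.0, death=0.0, trigger_population=None,
                           stop_population=2000)
        t = hd.simulate_birth_death(cfg, seed=2)
        f = t.frequencies
        # singleton mutations are massively tied in rank; judge the rank
        # agreement on mutations that rose to a resolvable frequency
        alive = np.nonzero(t.carriers >= 5)[0]
        rho = stats.spearmanr(alive, -f[alive]).statistic
        # split-share variance (the first split is uniform) keeps this
        # well below 1 even in large populations
        assert rho > 0.55
        # E[f_j] ~ 1/j for the early mutations (Yule split shares)
        j = np.arange(1, 31)
        ratio = np.median(f[:30] * j)
        assert 0.4 < ratio < 2.5

    def test_bit_reproducible(self):
        cfg = hd.SimConfig(k=2.0, trigger_population=50, max_population=500)
        a = hd.simulate_birth_death(cfg, seed=9)
        b = hd.simulate_birth_death(cfg, seed=9)
        np.testing.assert_array_equal(a.carriers, b.carriers)
        assert a.driver_id == b.driver_id
        c = hd.simulate_birth_death(cfg, seed=10)
        assert c.n_final != a.n_final or c.driver_id != a.driver_id

    def test_logistic_mode_caps_growth(self):
        cfg = hd.SimConfig(k=1.0, death=0.1, carrying_capacity=300,
                           trigger_population=None, stop_population=None,
                           max_events=200_000)
        t = hd.simulate_birth_death(cfg, seed=3)
        assert t.n_final <= 450  # stochastic wobble around K


class TestLaggedExponential:
    def test_lag_zero_matches_plain_growth_scale(self):
        cfg = hd.SimConfig(k=1.0, death=0.1, trigger_population=None,
                           stop_population=300, division_lag=0.0)
        times = []
        for seed in range(4):
            t = hd.simulate_lagged_exponential(cfg, seed=seed)
            assert t.n_final >= 300
            times.append(t.trajectory_t[-1])
        # pure exponential reaches 300 cells in roughly ln(300)/(b-d)
        expected = math.log(300) / 0.9
        assert np.median(times) == pytest.approx(expected, rel=0.5)

    def test_lag_slows_growth(self):
        base = dict(k=1.0, death=0.0, trigger_population=None, stop_population=300)
        t_fast = [
            hd.simulate_lagged_exponential(hd.SimConfig(division_lag=0.0, **base), seed=s).trajectory_t[-1]
            for s in range(4)
        ]
        t_slow = [
            hd.simulate_lagged_exponential(hd.SimConfig(division_lag=1.0, **base), seed=s).trajectory_t[-1]
            for s in range(4)
        ]
        assert np.median(t_slow) > np.median(t_fast)

    def test_driver_invariants_hold(self):
        cfg = hd.SimConfig(k=2.0, trigger_population=30, division_lag=0.3,
                           max_population=2000)
        t = hd.simulate_lagged_exponential(cfg, seed=1)
        assert t.driver_id is not None
        hh = t.hitchhiker_ids()
        assert np.all(t.frequencies[hh] >= t.driver_frequency)


class TestStochasticMu:
    def test_mutation_budget(self):
        t = hd.simulate_stochastic_mu(s=0.0, seed=1, n_cells=2000)
        divisions = t.n_final - 1  # death = 0: every division is net growth
        assert len(t.parents) == pytest.approx(10 * divisions, rel=0.1)

    def test_selection_coefficient_maps_to_k(self):
        t = hd.simulate_stochastic_mu(s=1.5, seed=3, n_cells=2000)
        assert t.true_k == pytest.approx(2.5)
        assert t.driver_id is not None

    def test_neutral_has_no_driver(self):
        t = hd.simulate_stochastic_mu(s=0.0, seed=2, n_cells=1000)
        assert t.driver_id is None and t.true_k == 1.0


class TestDownsampleCoverage:
    def test_fixed_points(self):
        rng = np.random.default_rng(0)
        assert hd.downsample_coverage(np.array([1.0]), 100, rng)[0] == 1.0
        # coverage 1000 is the base representation: pure quantization
        out = hd.downsample_coverage(np.array([0.4751]), 1000, rng, drop_zero=False)
        assert out[0] == pytest.approx(0.475)

    def test_binomial_moments(self):
        rng = np.random.default_rng(1)
        f = np.full(4000, 0.475)
        out = hd.downsample_coverage(f, 500, rng, drop_zero=False)
        assert out.mean() == pytest.approx(0.475, abs=0.005)
        assert out.var() == pytest.approx(0.475 * 0.525 / 500, rel=0.15)

    def test_rare_mutation_drop_probability(self):
        rng = np.random.default_rng(2)
        f = np.full(5000, 0.001)
        kept = hd.downsample_coverage(f, 100, rng)
        drop = 1.0 - len(kept) / 5000
        assert drop == pytest.approx((1 - 0.001) ** 100, abs=0.02)

    def test_invalid_coverage(self):
        with pytest.raises(ValueError):
            hd.downsample_coverage(np.array([0.5]), 0, np.random.default_rng(0))
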