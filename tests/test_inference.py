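"""Spectrum ordering, window fits, the sliding scan and benchmarking."""

import math

import numpy as np
import pandas as pd
import pytest

import hitchdriver as hd
from hitchdriver.inference import (
    _local_maxima,
    benchmark_distances,
    best_peak,
    classify_predictions,
    detect_peaks,
    fit_window,
    order_spectrum,
    sliding_fit,
    tune_window,
)


def _table(freqs, chrom="c", pos=None):
    n = len(freqs)
    return pd.DataFrame(
        {
            "id": [f"x{i}" for i in range(n)],
            "chrom": chrom,
            "pos": pos if pos is not None else np.arange(n),
            "ref": "A",
            "alt": "T",
            "freq": freqs,
        }
    )


class TestOrderSpectrum:
    def test_sorts_descending_and_indexes(self):
        spec = order_spectrum(_table([0.5, 0.9, 0.1]))
        assert list(spec.freq) == [0.9, 0.5, 0.1]
        assert list(spec.table["i"]) == [1, 2, 3]
        assert spec.rank_of("x1") == 1

    def test_ties_break_by_coordinates(self):
        df = _table([0.3, 0.3], pos=[200, 100])
        spec = order_spectrum(df)
        assert list(spec.table["pos"]) == [100, 200]

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            order_spectrum(_table([]))
        with pytest.raises(ValueError):
            order_spectrum(_table([0.5, 1.2]))
        with pytest.raises(ValueError):
            order_spectrum(_table([0.5, 0.0]))
        dup = _table([0.5, 0.4])
        dup.loc[1, "id"] = "x0"
        with pytest.raises(ValueError):
            order_spectrum(dup)

    def test_simulated_neutral_rank_matches_occurrence(self):
        """With pure birth (no death) frequency rank tracks occurrence
        order, so ties resolved by position (= mutation id) keep the
        ordering consistent with history."""
        cfg = hd.SimConfig(k=1.0, death=0.0, trigger_population=None,
                           stop_population=400)
        tum = hd.simulate_birth_death(cfg, seed=5)
        spec = order_spectrum(tum.spectrum(), "neu")
        ids = spec.table["pos"].to_numpy()  # pos carries the mutation id
        from scipy.stats import spearmanr

        rho = spearmanr(np.arange(len(ids)), ids).statistic
        assert rho > 0.8


class TestFitWindow:
    def _window_from_model(self, r, k, f_d, n_tot, t_g, m):
        alpha = hd.asymptote_from_effect(k, f_d, n_tot)
        j = np.arange(1, m + 1, dtype=float)
        return np.exp(-r * (t_g + j)) * (1 - alpha) + alpha, alpha

    @pytest.mark.parametrize("method", ["profile", "lm"])
    def test_recovers_exact_model(self, method):
        """A window sampled exactly from the hitchhiker curve returns the
        generating rate and plateau."""
        window, alpha = self._window_from_model(0.1, 2.0, 0.2, 1e6, 3.0, 150)
        fit = fit_window(window, 1, 150, mode="offset", method=method)
        assert fit.r == pytest.approx(0.1, abs=1e-3)
        assert fit.alpha == pytest.approx(alpha, abs=1e-4)

    def test_neutral_window_gives_neutral_effect(self):
        freqs = np.exp(-0.05 * np.arange(1, 151))
        fit = fit_window(freqs, 1, 150, mode="simple")
        assert abs(fit.alpha) < 1e-4
        k = hd.effect_from_asymptote(max(fit.alpha, 0.0), freqs[-1], 1e6)
        assert k == pytest.approx(1.0, abs=0.01)

    def test_simple_mode_uses_absolute_order(self):
        """A deep window in simple mode is pinned to the global decay, so
        the fitted rate matches the global exponent, not a rescaled one."""
        freqs = np.exp(-0.02 * np.arange(1, 401))
        fit = fit_window(freqs, 200, 150, mode="simple")
        assert fit.r == pytest.approx(0.02, abs=2e-3)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            fit_window(np.ones(10), 5, 150)


class TestSlidingFit:
    def test_single_driver_forward_model(self, single_driver_forward):
        """On a noiseless single-driver spectrum the effect signal peaks
        at the driver's ordered index and recovers its effect."""
        spec, true_rank = single_driver_forward
        track = sliding_fit(spec, m=150, n_tot=1e6)
        i, k_hat = best_peak(track)
        assert abs(i - true_rank) <= 1
        assert k_hat == pytest.approx(2.0, rel=0.1)

    def test_neutral_spectrum_flat(self):
        table = hd.neutral_spectrum(length=400, r=0.015)
        spec = order_spectrum(table)
        track = sliding_fit(spec, m=150, n_tot=1e6)
        ks = track.table["k"].to_numpy()
        assert np.nanmedian(ks) == pytest.approx(1.0, abs=0.05)
        _, k_peak = best_peak(track)
        assert k_peak < 1.2

    def test_min_window_extends_scan_to_head(self, single_driver_forward):
        spec, true_rank = single_driver_forward
        track = sliding_fit(spec, m=150, n_tot=1e6, min_window=5)
        assert track.table["i"].min() == 6

    def test_undefined_k_flagged_not_dropped(self, single_driver_forward):
        spec, true_rank = single_driver_forward
        track = sliding_fit(spec, m=150, n_tot=1e6)
        sub = track.table.set_index("i").loc[true_rank + 1 : true_rank + 5, "k"]
        assert sub.isna().any()  # just past the driver the inversion is invalid
        assert len(track) == len(spec) - 150

    def test_too_short_spectrum(self):
        spec = order_spectrum(_table(np.linspace(0.9, 0.1, 50)))
        with pytest.raises(ValueError):
            sliding_fit(spec, m=150)


class TestPeaks:
    def test_monotone_signal_peaks_at_first_point(self):
        sig = np.linspace(1.0, 0.0, 50)
        assert _local_maxima(sig)[0] == 0

    def test_three_driver_recovery(self, three_driver_forward):
        spec, ranks = three_driver_forward
        track = sliding_fit(spec, m=100, n_tot=1e6, min_window=20)
        peaks = detect_peaks(track, top_n=3)
        for true_rank in ranks:
            assert min(abs(p - true_rank) for p in peaks) <= 10

    def test_smoothing_fallback_warns(self, single_driver_forward):
        spec, _ = single_driver_forward
        track = sliding_fit(spec, m=150, n_tot=1e6, scan_limit=200)
        with pytest.warns(UserWarning):
            detect_peaks(track, top_n=1, smooth=10_000)


class TestBenchmarking:
    def test_exact_hits(self):
        out = benchmark_distances([10, 20], [10, 20], [500, 500], seed=1)
        assert out["median_D"] == 0.0
        assert out["median_abs_D"] == 0.0

    def test_seeded_reproducibility(self):
        a = benchmark_distances([5, 50], [10, 40], [300, 300], seed=9)
        b = benchmark_distances([5, 50], [10, 40], [300, 300], seed=9)
        assert a == b

    def test_no_p_value_for_single_sim(self):
        out = benchmark_distances([5], [10], [300], seed=2)
        assert out["p_value"] is None

    def test_classification_rule(self):
        out = classify_predictions([10.0, 20.0])
        assert (out["TP"], out["FP"], out["TN"], out["FN"]) == (1, 1, 1, 1)
        assert out["sensitivity"] == 0.5 and out["PPV"] == 0.5
        perfect = classify_predictions([0.0, 3.0, 16.0])
        assert perfect["sensitivity"] == 1.0 and perfect["PPV"] == 1.0

    def test_tune_window_degenerate_candidate(self, single_driver_forward):
        spec, true_rank = single_driver_forward
        report = tune_window([(spec, true_rank)], [spec], [100], scan_limit=400)
        assert list(report["m"]) == [100]
        assert report.loc[0, "median_abs_D"] >= 0
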