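"""WPLI, band aggregation, permutation null and pair-set analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import flickervig as fv
from flickervig.connectivity import (nearest_rank_percentile,
                                     significant_pair_counts, wpli_from_imag)
from flickervig.spectral import ALPHA, LOWER_ALPHA

from conftest import epochs_from_array, epochs_from_recording, sinusoid_pair_epochs


class TestWPLIFormula:
    def test_hand_evaluated_mixed_signs(self):
        """Im values {+2, +1, -1} give |2/3| / (4/3) = 0.5."""
        assert wpli_from_imag(np.array([[2.0], [1.0], [-1.0]]))[0] == pytest.approx(0.5)

    def test_consistent_sign_gives_one(self):
        assert wpli_from_imag(np.array([[0.5], [2.0], [0.1]]))[0] == pytest.approx(1.0)

    def test_balanced_leads_lags_give_zero(self):
        assert wpli_from_imag(np.array([[1.0], [-1.0]]))[0] == pytest.approx(0.0)

    def test_zero_denominator_defined_as_zero(self):
        assert wpli_from_imag(np.zeros((4, 3))).tolist() == [0.0, 0.0, 0.0]


class TestCrossSpectra:
    def test_identical_signals_have_zero_imaginary_part(self, rng):
        data = rng.standard_normal((6, 1, 2048))
        epochs = epochs_from_array(np.concatenate([data, data], axis=1),
                                   ch_names=["x", "y"])
        cross = fv.pair_cross_spectra(epochs, "x", "y")
        assert np.abs(cross.sxy.imag).max() < 1e-12 * np.abs(cross.sxy.real).max()
        assert np.all(fv.wpli(cross) == 0.0)

    def test_quarter_period_lag_constant_imag_sign(self):
        epochs = sinusoid_pair_epochs(20, np.pi / 2, f0=10.0)
        cross = fv.pair_cross_spectra(epochs, "x", "y")
        i10 = np.argmin(np.abs(cross.freqs - 10.0))
        assert np.all(cross.sxy.imag[:, i10] > 0)
        assert fv.wpli(cross)[i10] == pytest.approx(1.0)

    def test_independent_noise_mean_imag_shrinks(self, rng):
        ims = []
        for n_seg in (16, 256):
            data = rng.standard_normal((n_seg, 2, 1024))
            cross = fv.pair_cross_spectra(epochs_from_array(data), "CH1", "CH2")
            ims.append(np.abs(cross.sxy.imag.mean(axis=0)).mean())
        assert ims[1] < ims[0] / 2

    def test_single_segment_rejected(self):
        with pytest.raises(ValueError, match="2 segments"):
            fv.pair_cross_spectra(epochs_from_array(np.zeros((1, 2, 1024))),
                                  "CH1", "CH2")


class TestBandAggregate:
    def test_flat_band(self):
        freqs = np.arange(0, 20.5, 0.5)
        w = np.full(len(freqs), 0.3)
        mean, peak, peak_f = fv.band_aggregate(w, freqs, ALPHA)
        assert (mean, peak) == (pytest.approx(0.3), pytest.approx(0.3))
        assert peak_f == 8.0

    def test_tie_resolves_to_lowest_frequency(self):
        freqs = np.array([8.0, 9.0, 10.0])
        w = np.array([0.1, 0.4, 0.4])
        _, _, peak_f = fv.band_aggregate(w, freqs, ALPHA)
        assert peak_f == 9.0

    def test_coupled_source_peak_frequency(self):
        cfg = fv.SimConfig(n_channels=2, ch_names=["O1", "O2"],
                           ssvep_amplitude=0.0,
                           coupled_pairs=[("O1", "O2", 9.0, np.pi / 2, 0.8)])
        rec = fv.simulate_recording(cfg, 240, seed=4)
        cross = fv.pair_cross_spectra(epochs_from_recording(rec), "O1", "O2")
        _, _, peak_f = fv.band_aggregate(fv.wpli(cross), cross.freqs, ALPHA)
        assert peak_f == pytest.approx(9.0, abs=0.5)


class TestWPLIProperties:
    @given(arrays(np.float64, shape=(8, 4),
                  elements=st.floats(-5, 5, allow_nan=False)))
    @settings(max_examples=100, deadline=None)
    def test_bounds(self, im):
        w = wpli_from_imag(im)
        assert np.all(w >= 0) and np.all(w <= 1 + 1e-12)

    def test_symmetry_and_amplitude_invariance(self, rng):
        data = rng.standard_normal((10, 2, 1024))
        epochs = epochs_from_array(data)
        w_xy = fv.wpli(fv.pair_cross_spectra(epochs, "CH1", "CH2"))
        w_yx = fv.wpli(fv.pair_cross_spectra(epochs, "CH2", "CH1"))
        assert np.allclose(w_xy, w_yx)
        scaled = data.copy()
        scaled[:, 0] *= 7.3
        w_scaled = fv.wpli(fv.pair_cross_spectra(epochs_from_array(scaled),
                                                 "CH1", "CH2"))
        assert np.allclose(w_xy, w_scaled)

    def test_constant_lag_wpli_near_one_despite_noise(self, rng):
        """A constant-lag pair keeps WPLI near 1 at large segment counts even
        under noise, while heavy noise (sign-flipping segments) pulls the
        population value below 1."""
        def estimate(noise, n_seg):
            epochs = sinusoid_pair_epochs(
                n_seg, np.pi / 2, f0=10.0,
                phases=rng.uniform(0, 2 * np.pi, n_seg))
            noisy = epochs.data + rng.standard_normal(epochs.data.shape) * noise
            cross = fv.pair_cross_spectra(
                epochs_from_array(noisy, ch_names=["x", "y"]), "x", "y")
            i10 = np.argmin(np.abs(cross.freqs - 10.0))
            return fv.wpli(cross)[i10]

        assert estimate(noise=8.0, n_seg=512) > 0.9
        assert estimate(noise=80.0, n_seg=512) < 0.5

    def test_montage_pair_count(self, rng):
        epochs = epochs_from_array(rng.standard_normal((2, 32, 1024)),
                                   ch_names=fv.BIOSEMI32)
        table = fv.wpli_all_pairs(epochs)
        assert len(table.pairs) == 32 * 31 // 2 == 496


def white_noise_cohort(rng, n_subjects=4, n_epochs=67, n_ch=3):
    cohort = []
    for _ in range(n_subjects):
        data = rng.standard_normal((n_epochs, n_ch, 2048))
        cohort.append(epochs_from_array(data))
    return cohort


class TestPermutationNull:
    def test_threshold_below_bias_bound_for_white_noise(self, rng):
        """With ~200 segments per subject, the 99.99th-percentile null WPLI
        stays below 0.3 (finite-sample bias bound)."""
        null = fv.permutation_null(white_noise_cohort(rng), n_perm=500,
                                   percentile=99.99, seed=5)
        assert all(t < 0.3 for t in null.thresholds.values())
        assert null.pooled_threshold < 0.3

    def test_nearest_rank_percentile_rule(self):
        samples = np.arange(1.0, 101.0)
        assert nearest_rank_percentile(samples, 99.99) == 100.0
        assert nearest_rank_percentile(samples, 75.0) == 75.0
        assert nearest_rank_percentile(samples, 0.5) == 1.0

    def test_same_seed_same_threshold(self, rng):
        cohort = white_noise_cohort(rng, n_subjects=3, n_epochs=10)
        a = fv.permutation_null(cohort, n_perm=200, seed=7)
        b = fv.permutation_null(cohort, n_perm=200, seed=7)
        assert a.thresholds == b.thresholds

    def test_single_subject_rejected(self, rng):
        with pytest.raises(ValueError, match="2 subjects"):
            fv.permutation_null(white_noise_cohort(rng, n_subjects=1),
                                n_perm=200)

    def test_null_pvalues_uniform_under_no_coupling(self, rng):
        """Empirical p-values of uncoupled pairs against the null are ~U(0,1)."""
        from scipy.stats import kstest
        cohort = white_noise_cohort(rng, n_subjects=4, n_epochs=30, n_ch=4)
        null = fv.permutation_null(cohort, n_perm=2000, seed=11,
                                   bands=[ALPHA], statistic="mean")
        samples = np.sort(null.band_samples["alpha"])
        obs = []
        for ep in cohort:
            table = fv.wpli_all_pairs(ep, bands=[ALPHA])
            obs.extend(table.band_values(ALPHA))
        pvals = [(1 + np.sum(samples >= o)) / (len(samples) + 1) for o in obs]
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestSignificance:
    def _table(self, rng):
        epochs = epochs_from_array(rng.standard_normal((4, 3, 1024)))
        return fv.wpli_all_pairs(epochs, bands=[ALPHA])

    def test_all_below_threshold_counts_zero(self, rng):
        table = self._table(rng)
        null = fv.NullDistribution(
            n_perm=100, percentile=99.99, seed=0,
            band_samples={"alpha": np.ones(100)}, pooled_samples=np.ones(100),
            thresholds={"alpha": 1.0}, pooled_threshold=1.0)
        flags = fv.significant_pairs(table, null, bands=[ALPHA])
        assert significant_pair_counts(flags).n_significant.sum() == 0

    def test_threshold_boundary_is_strict(self, rng):
        table = self._table(rng)
        v = float(table.band_values(ALPHA)[0])
        null = fv.NullDistribution(
            n_perm=100, percentile=99.99, seed=0,
            band_samples={"alpha": np.full(100, v)},
            pooled_samples=np.full(100, v),
            thresholds={"alpha": v}, pooled_threshold=v)
        flags = fv.significant_pairs(table, null, bands=[ALPHA])
        first = flags.iloc[0]
        assert first.value == v and not first.significant

    def test_planted_coupling_listed_significant(self, rng):
        cfg = fv.SimConfig(
            n_channels=4, ch_names=["O1", "O2", "P3", "P4"],
            ssvep_amplitude=0.0,
            coupled_pairs=[("O1", "O2", 9.0, np.pi / 2, 0.9)])
        rec = fv.simulate_recording(cfg, 240, seed=17)
        table = fv.wpli_all_pairs(epochs_from_recording(rec), bands=[LOWER_ALPHA])
        null = fv.NullDistribution(
            n_perm=100, percentile=99.99, seed=0,
            band_samples={"lower_alpha": np.full(100, 0.3)},
            pooled_samples=np.full(100, 0.3),
            thresholds={"lower_alpha": 0.3}, pooled_threshold=0.3)
        flags = fv.significant_pairs(table, null, bands=[LOWER_ALPHA])
        sig = flags.loc[flags.significant]
        assert len(sig) == 1
        assert {sig.iloc[0].channel_a, sig.iloc[0].channel_b} == {"O1", "O2"}


class TestHighFCPairs:
    def test_all_equal_values_give_empty_sets(self):
        df = pd.DataFrame({"channel_a": ["a"] * 496, "channel_b": ["b"] * 496,
                           "value": [0.1] * 496})
        sets, thr = fv.high_fc_pairs({"g1": df})
        assert thr == pytest.approx(0.1)
        assert len(sets["g1"]) == 0

    def test_quartile_interpolation_oracle(self):
        vals = np.arange(1.0, 101.0)
        df = pd.DataFrame({"channel_a": "a", "channel_b": "b", "value": vals})
        sets, thr = fv.high_fc_pairs({"g": df})
        assert thr == pytest.approx(75.25)   # linear-interpolation quantile
        assert len(sets["g"]) == (vals > 75.25).sum() == 25

    def test_shifted_group_has_larger_high_fc_set(self):
        """A +0.05 WPLI shift in one group enlarges its top-quartile set in
        >= 90% of seeds."""
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            base = r.uniform(0.02, 0.12, size=200)
            a = pd.DataFrame({"channel_a": "a", "channel_b": "b",
                              "value": base + 0.05})
            b = pd.DataFrame({"channel_a": "a", "channel_b": "b",
                              "value": r.uniform(0.02, 0.12, size=200)})
            sets, _ = fv.high_fc_pairs({"A": a, "B": b})
            wins += len(sets["A"]) > len(sets["B"])
        assert wins >= 18
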