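"""Epoching, Welch PSD, normalization, aperiodic fit and band power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flickervig as fv
from flickervig.recording import Recording, empty_events
from flickervig.spectral import (ALL_BANDS, CANONICAL_BANDS, BandDef, PSDSet,
                                 band_power_table)

from conftest import epochs_from_array

FS = 512.0


def _recording(data, events=None):
    events = events if events is not None else empty_events()
    return Recording(data=np.atleast_2d(data), sfreq=FS, ch_names=["Cz"],
                     events=events)


def _trials(change_onsets):
    return pd.DataFrame({
        "trial_index": np.arange(len(change_onsets)),
        "trial_start_s": np.asarray(change_onsets) - 6.0,
        "change_onset_s": change_onsets,
        "press_times": [() for _ in change_onsets],
    })


class TestEpoching:
    def test_one_epoch_per_trial(self):
        rec = _recording(np.zeros(int(120 * FS)))
        epochs = fv.make_epochs(rec, _trials([10.0, 20.0, 30.0]))
        assert epochs.n_trials == 3
        assert epochs.data.shape[-1] == int(4 * FS)

    def test_out_of_bounds_trial_dropped(self):
        rec = _recording(np.zeros(int(60 * FS)))
        epochs = fv.make_epochs(rec, _trials([3.0, 20.0, 30.0]))
        assert epochs.n_trials == 2
        assert epochs.dropped_trials == [0]

    def test_trial_overlapping_break_dropped(self):
        events = pd.DataFrame({"onset_s": [28.0, 88.0],
                               "event_type": ["break_start", "break_end"]})
        rec = _recording(np.zeros(int(200 * FS)), events)
        onsets = [10.0, 20.0, 30.0, 100.0, 110.0, 120.0, 130.0, 140.0, 150.0, 160.0]
        epochs = fv.make_epochs(rec, _trials(onsets))
        # trial at 30 s has window (26, 30) overlapping the 28-88 s break
        assert epochs.n_trials == 9
        assert epochs.dropped_trials == [2]

    def test_no_eligible_trials_raises(self):
        rec = _recording(np.zeros(int(10 * FS)))
        with pytest.raises(ValueError, match="no eligible trials"):
            fv.make_epochs(rec, _trials([1.0]))


class TestHighpass:
    def test_dc_removed(self):
        rec = _recording(np.full(int(20 * FS), 5.0))
        out = fv.highpass_filter(rec, 1.0)
        assert np.abs(out.data).max() < 1e-6 * 5.0

    def test_passband_preserved_stopband_attenuated(self):
        t = np.arange(int(40 * FS)) / FS
        for freq, keep in ((10.0, True), (0.2, False)):
            rec = _recording(np.sin(2 * np.pi * freq * t))
            out = fv.highpass_filter(rec, 1.0)
            mid = out.data[0, int(5 * FS):-int(5 * FS)]
            amp = np.abs(mid).max()
            if keep:
                assert amp == pytest.approx(1.0, rel=0.01)
            else:
                assert amp < 0.1

    def test_cutoff_above_nyquist_rejected(self):
        rec = _recording(np.zeros(int(20 * FS)))
        with pytest.raises(ValueError, match="Nyquist"):
            fv.highpass_filter(rec, 300.0)


class TestWelch:
    def test_parseval_white_noise(self, rng):
        data = rng.standard_normal((40, 1, 2048))
        psd = fv.welch_psd(epochs_from_array(data))
        integral = np.trapezoid(psd.power[:, 0], psd.freqs)
        assert integral == pytest.approx(1.0, abs=0.05)

    def test_sinusoid_power_recovered(self, rng):
        """Integral over the taper mainlobe around an exact-bin sinusoid
        recovers the analytic power A^2/2."""
        A, f0 = 2.0, 10.0
        t = np.arange(2048) / FS
        data = np.stack([[A * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))]
                         for _ in range(10)])
        psd = fv.welch_psd(epochs_from_array(data))
        i0 = int(np.argmin(np.abs(psd.freqs - f0)))
        got = np.trapezoid(psd.power[i0 - 2:i0 + 3, 0], psd.freqs[i0 - 2:i0 + 3])
        assert got == pytest.approx(A ** 2 / 2, rel=0.05)

    def test_zero_input_zero_psd(self):
        psd = fv.welch_psd(epochs_from_array(np.zeros((3, 2, 2048))))
        assert np.all(psd.power == 0)

    def test_segments_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            fv.welch_psd(epochs_from_array(np.zeros((3, 1, 512))))


class TestNormalization:
    def _psd(self, rng, n_ch=2):
        data = rng.standard_normal((20, n_ch, 2048))
        return fv.welch_psd(epochs_from_array(data))

    def test_area_is_one(self, rng):
        for lo in (1.0, 2.0):
            norm = fv.normalize_psd(self._psd(rng), lo, 55.0)
            mask = (norm.freqs >= lo) & (norm.freqs <= 55.0)
            area = np.trapezoid(norm.power[mask], norm.freqs[mask], axis=0)
            assert np.allclose(area, 1.0, atol=1e-6)
            assert norm.normalization == f"area({lo:g}-55)"

    def test_scale_invariance(self, rng):
        psd = self._psd(rng)
        scaled = PSDSet(freqs=psd.freqs, power=psd.power * [1.0, 10.0],
                        ch_names=psd.ch_names)
        a = fv.normalize_psd(psd)
        b = fv.normalize_psd(scaled)
        assert np.allclose(a.power, b.power)

    def test_flat_spectrum_value(self):
        freqs = np.arange(1.0, 60.5, 0.5)
        psd = PSDSet(freqs=freqs, power=np.ones((len(freqs), 1)), ch_names=["a"])
        norm = fv.normalize_psd(psd, 2.0, 55.0)
        assert norm.power[10, 0] == pytest.approx(1 / 53.0)

    def test_double_normalization_rejected(self, rng):
        norm = fv.normalize_psd(self._psd(rng))
        with pytest.raises(ValueError, match="already normalized"):
            fv.normalize_psd(norm)


class TestAperiodicFit:
    freqs = np.arange(2.0, 55.5, 0.5)

    def test_exact_power_law(self):
        psd = PSDSet(freqs=self.freqs, power=(10.0 / self.freqs ** 2)[:, None],
                     ch_names=["a"])
        fit = fv.fit_aperiodic(psd, (2.0, 55.0))
        assert fit.exponent[0] == pytest.approx(2.0, abs=0.01)
        assert np.abs(fit.residual).max() < 1e-6

    def test_alpha_peak_masked(self):
        bump = 10 ** (0.8 * np.exp(-0.5 * ((self.freqs - 10.0) / 1.0) ** 2))
        psd = PSDSet(freqs=self.freqs,
                     power=(10.0 / self.freqs ** 2 * bump)[:, None],
                     ch_names=["a"])
        fit = fv.fit_aperiodic(psd, (2.0, 55.0))
        assert fit.exponent[0] == pytest.approx(2.0, abs=0.05)
        i10 = np.argmin(np.abs(fit.freqs - 10.0))
        assert fit.residual[i10, 0] == pytest.approx(0.8, abs=0.1)

    def test_flat_spectrum_zero_exponent(self):
        psd = PSDSet(freqs=self.freqs, power=np.ones((len(self.freqs), 1)),
                     ch_names=["a"])
        fit = fv.fit_aperiodic(psd, (2.0, 55.0))
        assert fit.exponent[0] == pytest.approx(0.0, abs=0.05)

    @pytest.mark.parametrize("exponent", [0.5, 1.0, 1.5, 2.0])
    def test_recovery_on_simulated_one_over_f(self, exponent):
        cfg = fv.SimConfig(n_channels=1, ch_names=["Cz"],
                           aperiodic_exponent=exponent, band_oscillations=[],
                           ssvep_amplitude=0.0, noise_sd=0.05)
        rec = fv.simulate_recording(cfg, 120, seed=int(10 * exponent))
        from conftest import epochs_from_recording
        psd = fv.welch_psd(epochs_from_recording(rec))
        fit = fv.fit_aperiodic(psd, (2.0, 55.0))
        assert fit.exponent[0] == pytest.approx(exponent, abs=0.1)


class TestBandPower:
    def test_hand_enumerated_peak(self):
        """Half-open delta [2, 4): the 4 Hz bin belongs to theta."""
        freqs = np.array([2.0, 2.5, 3.0, 4.0])
        psd = PSDSet(freqs=freqs, power=np.array([[0.1], [0.3], [0.2], [0.5]]),
                     ch_names=["a"])
        assert fv.band_peak_power(psd, BandDef("delta", 2, 4))[0] == 0.3

    def test_monotone_spectrum_peak_at_lowest_bin(self):
        freqs = np.arange(1.0, 50.0, 0.5)
        psd = PSDSet(freqs=freqs, power=(1.0 / freqs)[:, None], ch_names=["a"])
        for band in CANONICAL_BANDS:
            lo_bin = freqs[band.mask(freqs)][0]
            assert fv.band_peak_power(psd, band)[0] == pytest.approx(1.0 / lo_bin)

    def test_empty_band_rejected(self):
        psd = PSDSet(freqs=np.array([1.0, 2.0]), power=np.ones((2, 1)),
                     ch_names=["a"])
        with pytest.raises(ValueError, match="no frequency bins"):
            fv.band_peak_power(psd, BandDef("hi", 100.0, 110.0))

    def test_band_table_covers_all_bands(self, rng):
        psd = fv.welch_psd(epochs_from_array(rng.standard_normal((5, 2, 2048))))
        table = band_power_table(psd)
        assert set(table.band) == {b.name for b in ALL_BANDS}

    @given(st.floats(min_value=2.0, max_value=36.9))
    @settings(max_examples=200, deadline=None)
    def test_canonical_bands_partition_their_range(self, freq):
        hits = [b.name for b in CANONICAL_BANDS if b.mask(np.array([freq]))[0]]
        assert len(hits) == 1
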