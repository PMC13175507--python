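"""Epoching, Welch spectra, normalization, aperiodic fit, band power.

The spectral conventions follow common EEG practice for vigilance studies:
epochs span the 4 s attending period immediately before the color change;
power spectral densities use Welch's method with 2 s Hamming windows at 50%
overlap and a 1024-point FFT.  At the pipeline's 512 Hz working rate a 2 s
window is exactly 1024 samples, giving 0.5 Hz resolution.  Raw power is
normalized per channel by the area under the PSD over 1-55 or 2-55 Hz so
that group comparisons measure relative power from a common baseline.

A simplified robust aperiodic (1/f) fit is provided to separate broadband
background from narrowband (periodic) activity: an iterative straight-line
fit of log10(power) on log10(frequency) with candidate peak bins masked at
+2.5 robust SD before the refit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .recording import Recording

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Equal-length trials x channels x samples epochs."""

    data: np.ndarray                 # (n_trials, n_channels, n_samples)
    sfreq: float
    ch_names: list[str]
    window: tuple[float, float] = (-4.0, 0.0)
    trial_indices: np.ndarray = field(default_factory=lambda: np.array([], int))
    dropped_trials: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials, channels, samples)")
        self.trial_indices = np.asarray(self.trial_indices, dtype=int)
        if np.any(np.diff(self.trial_indices) <= 0):
            raise ValueError("trial_indices must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in epochs") from None


@dataclass
class WelchParams:
    """Welch segmentation: 2 s Hamming windows, 50% overlap, 1024-pt FFT."""

    window_length: float = 2.0
    overlap_fraction: float = 0.5
    taper: str = "hamming"
    n_fft: int = 1024

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")

    def nperseg(self, sfreq: float) -> int:
        n = int(round(self.window_length * sfreq))
        if n > self.n_fft:
            raise ValueError(
                f"window of {n} samples exceeds FFT size {self.n_fft}; "
                "resample or enlarge n_fft")
        return n

    def noverlap(self, sfreq: float) -> int:
        return int(self.nperseg(sfreq) * self.overlap_fraction)


@dataclass
class PSDSet:
    """Power spectral densities: frequencies x channels."""

    freqs: np.ndarray                # (n_freqs,)
    power: np.ndarray                # (n_freqs, n_channels)
    ch_names: list[str]
    normalization: str = "none"      # "none" | "area(1-55)" | "area(2-55)"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.power.shape != (len(self.freqs), len(self.ch_names)):
            raise ValueError("power must be (n_freqs, n_channels)")

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in PSD") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.power, columns=self.ch_names)
        df.insert(0, "frequency", self.freqs)
        return df.melt(id_vars="frequency", var_name="channel", value_name="power")


@dataclass(frozen=True)
class BandDef:
    """A frequency band [lo, hi); hi inclusive when closed_upper is set."""

    name: str
    lo: float
    hi: float
    closed_upper: bool = False

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("band lo must be < hi")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        if self.closed_upper:
            return (freqs >= self.lo) & (freqs <= self.hi)
        return (freqs >= self.lo) & (freqs < self.hi)


# Half-open edges so every bin in the canonical range belongs to exactly one
# band; the uppermost canonical band keeps its top edge.
DELTA = BandDef("delta", 2.0, 4.0)
THETA = BandDef("theta", 4.0, 8.0)
ALPHA = BandDef("alpha", 8.0, 13.0)
BETA = BandDef("beta", 13.0, 30.0)
LOW_GAMMA = BandDef("low_gamma", 30.0, 37.0, closed_upper=True)
FLICKER = BandDef("flicker", 39.0, 41.0, closed_upper=True)
LOWER_ALPHA = BandDef("lower_alpha", 8.0, 10.0)
UPPER_ALPHA = BandDef("upper_alpha", 10.0, 13.0)

CANONICAL_BANDS = [DELTA, THETA, ALPHA, BETA, LOW_GAMMA]
ALL_BANDS = CANONICAL_BANDS + [FLICKER, LOWER_ALPHA, UPPER_ALPHA]


@dataclass
class AperiodicFit:
    """Per-channel robust 1/f fit and the periodic residual spectrum."""

    freqs: np.ndarray                # bins inside the fit range
    offset: np.ndarray               # (n_channels,) log10 power at 1 Hz
    exponent: np.ndarray             # (n_channels,) power-law exponent
    residual: np.ndarray             # (n_bins, n_channels) log10 residual
    ch_names: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def highpass_filter(recording: Recording, cutoff: float = 1.0,
                    order: int = 4) -> Recording:
    """Zero-phase (forward-backward) Butterworth high-pass."""
    nyq = recording.sfreq / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, cutoff, btype="highpass",
                        fs=recording.sfreq, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.data, axis=1)
    return Recording(data=filtered, sfreq=recording.sfreq,
                     ch_names=list(recording.ch_names),
                     events=recording.events.copy())


def resample_recording(recording: Recording, target_rate: float) -> Recording:
    """Polyphase resampling to the spectral working rate."""
    if target_rate == recording.sfreq:
        return recording
    from fractions import Fraction
    frac = Fraction(target_rate / recording.sfreq).limit_denominator(1000)
    data = signal.resample_poly(recording.data, frac.numerator,
                                frac.denominator, axis=1)
    logger.info("resampled %.0f Hz -> %.0f Hz", recording.sfreq, target_rate)
    return Recording(data=data, sfreq=target_rate,
                     ch_names=list(recording.ch_names),
                     events=recording.events.copy())


def make_epochs(recording: Recording, trials: pd.DataFrame,
                window: tuple[float, float] = (-4.0, 0.0)) -> EpochSet:
    """Cut one epoch per trial, relative to the color-change event.

    Trials whose window extends past the recording edge or overlaps a break
    are dropped and logged.  Raises if no trial survives.
    """
    if window[1] > 0:
        raise ValueError("window must end at or before the color change")
    fs = recording.sfreq
    n_samp = int(round((window[1] - window[0]) * fs))
    breaks = recording.breaks()
    kept, dropped, slabs = [], [], []
    for _, tr in trials.iterrows():
        t0 = tr.change_onset_s + window[0]
        t1 = tr.change_onset_s + window[1]
        i0 = int(round(t0 * fs))
        if i0 < 0 or i0 + n_samp > recording.n_samples:
            dropped.append(int(tr.trial_index))
            continue
        if any(bs < t1 and be > t0 for bs, be in breaks):
            dropped.append(int(tr.trial_index))
            continue
        kept.append(int(tr.trial_index))
        slabs.append(recording.data[:, i0:i0 + n_samp])
    if dropped:
        logger.info("dropped %d/%d trials at epoching: %s",
                    len(dropped), len(trials), dropped)
    if not kept:
        raise ValueError("no eligible trials: every epoch window was out of "
                         "bounds or overlapped a break")
    return EpochSet(data=np.stack(slabs), sfreq=fs,
                    ch_names=list(recording.ch_names), window=window,
                    trial_indices=np.array(kept), dropped_trials=dropped)


def welch_psd(epochs: EpochSet, params: WelchParams | None = None) -> PSDSet:
    """Welch PSD averaged over all tapered segments of all epochs.

    Density scaling: the integral of the PSD over (0, Nyquist) approximates
    the signal power.  Segments are not detrended (the pipeline high-passes
    at 1 Hz upstream).
    """
    if params is None:
        params = WelchParams()
    nperseg = params.nperseg(epochs.sfreq)
    if epochs.data.shape[-1] < nperseg:
        raise ValueError(
            f"epoch length {epochs.data.shape[-1]} < one Welch segment ({nperseg})")
    freqs, pxx = signal.welch(
        epochs.data, fs=epochs.sfreq, window=params.taper, nperseg=nperseg,
        noverlap=params.noverlap(epochs.sfreq), nfft=params.n_fft,
        detrend=False, axis=-1)
    power = pxx.mean(axis=0).T            # (n_freqs, n_channels)
    return PSDSet(freqs=freqs, power=power, ch_names=list(epochs.ch_names))


def normalize_psd(psd: PSDSet, lo: float = 2.0, hi: float = 55.0) -> PSDSet:
    """Divide each channel's PSD by its own area over [lo, hi].

    The trapezoidal area of the result over [lo, hi] is exactly 1 per
    channel, so normalized spectra are invariant to per-channel scaling.
    """
    if psd.normalization != "none":
        raise ValueError(f"PSD already normalized ({psd.normalization})")
    mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    if mask.sum() < 2:
        raise ValueError("normalization range contains fewer than 2 bins")
    area = np.trapezoid(psd.power[mask], psd.freqs[mask], axis=0)
    if np.any(area <= 0):
        bad = [psd.ch_names[i] for i in np.flatnonzero(area <= 0)]
        raise ValueError(f"non-positive PSD area on channels {bad}")
    return PSDSet(freqs=psd.freqs, power=psd.power / area,
                  ch_names=list(psd.ch_names),
                  normalization=f"area({lo:g}-{hi:g})")


def fit_aperiodic(psd: PSDSet, fit_range: tuple[float, float] = (2.0, 55.0),
                  mask_sd: float = 2.5, min_bins: int = 10) -> AperiodicFit:
    """Robust straight-line 1/f fit in log-log space with peak masking.

    Fits log10(power) = offset - exponent * log10(f): an initial
    least-squares line, then bins whose residual exceeds ``+mask_sd`` robust
    SDs (candidate narrowband peaks) are masked and the line refit.  The
    residual spectrum (log10 power minus the fitted line, evaluated on all
    bins in the range) is the periodic component and may be negative.
    """
    sel = (psd.freqs >= fit_range[0]) & (psd.freqs <= fit_range[1])
    f = psd.freqs[sel]
    p = psd.power[sel]
    if np.any(p <= 0):
        raise ValueError("power must be positive over the fit range")
    lf = np.log10(f)
    lp = np.log10(p)
    n_ch = lp.shape[1]
    offset = np.empty(n_ch)
    exponent = np.empty(n_ch)
    residual = np.empty_like(lp)
    for c in range(n_ch):
        slope, intercept = np.polyfit(lf, lp[:, c], 1)
        resid = lp[:, c] - (intercept + slope * lf)
        rsd = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        keep = resid <= mask_sd * rsd if rsd > 0 else np.ones_like(resid, bool)
        if keep.sum() < min_bins:
            raise ValueError(
                f"channel {psd.ch_names[c]}: fewer than {min_bins} bins left "
                "after peak masking")
        slope, intercept = np.polyfit(lf[keep], lp[keep, c], 1)
        offset[c] = intercept
        exponent[c] = -slope
        residual[:, c] = lp[:, c] - (intercept + slope * lf)
    return AperiodicFit(freqs=f, offset=offset, exponent=exponent,
                        residual=residual, ch_names=list(psd.ch_names))


def band_peak_power(psd: PSDSet, band: BandDef, mode: str = "peak") -> np.ndarray:
    """Per-channel peak (default) or mean power within a band.

    Bins are selected by the band's half-open rule, so a frequency on a
    shared edge (e.g. 4 Hz between delta and theta) is counted once.
    """
    mask = band.mask(psd.freqs)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band.name}")
    sub = psd.power[mask]
    if mode == "peak":
        return sub.max(axis=0)
    if mode == "mean":
        return sub.mean(axis=0)
    raise ValueError(f"unknown mode {mode!r}")


def band_power_table(psd: PSDSet, bands: list[BandDef] | None = None,
                     mode: str = "peak") -> pd.DataFrame:
    """Tidy per-channel band power for a list of bands."""
    if bands is None:
        bands = ALL_BANDS
    rows = []
    for band in bands:
        vals = band_peak_power(psd, band, mode=mode)
        for ch, v in zip(psd.ch_names, vals):
            rows.append({"channel": ch, "band": band.name, "value": float(v)})
    return pd.DataFrame(rows)
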