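"""WPLI functional connectivity with a cross-subject permutation null.

The weighted phase lag index between channels x and y at frequency f is

    WPLI_xy(f) = |E{Im(S_xy(f))}| / E{|Im(S_xy(f))|},

where S_xy is the cross-spectrum of the two channels and the expectation runs
over tapered segments pooled across the attention-period epochs.  WPLI lies
in [0, 1]: 0 means no phase coupling or a balanced mix of leading and lagging
phases, 1 means one signal's phase consistently leads the other.  Because the
statistic is built entirely from the imaginary part of the cross-spectrum,
instantaneous (zero-lag) mixtures of a common source — volume conduction —
contribute nothing systematic to it.

Significance thresholds come from a permutation null: each permutation pairs
one random channel from each of two random subjects (genuine coupling cannot
exist across subjects), aligning their epochs by ordinal index.  WPLI values
above the chosen percentile (99.99th by default) of the null are significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .spectral import ALL_BANDS, BandDef, EpochSet, WelchParams


# ---------------------------------------------------------------------------
# segmentation shared with the Welch PSD
# ---------------------------------------------------------------------------

def segment_spectra(epochs: EpochSet, params: WelchParams | None = None
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tapered per-segment spectra of every channel.

    Returns ``(freqs, Z, trial_of_segment)`` where Z has shape
    (n_segments, n_channels, n_freqs) and uses the same segmentation (2 s
    Hamming windows, 50% overlap by default) and one-sided density scaling as
    the Welch PSD, so ``mean(|Z|**2)`` over segments reproduces it.
    """
    if params is None:
        params = WelchParams()
    fs = epochs.sfreq
    nperseg = params.nperseg(fs)
    step = nperseg - params.noverlap(fs)
    n_samp = epochs.data.shape[-1]
    if n_samp < nperseg:
        raise ValueError("epoch shorter than one Welch segment")
    taper = _get_taper(params.taper, nperseg)
    starts = range(0, n_samp - nperseg + 1, step)

    segs, owner = [], []
    for t_idx in range(epochs.n_trials):
        for s0 in starts:
            segs.append(epochs.data[t_idx, :, s0:s0 + nperseg] * taper)
            owner.append(int(epochs.trial_indices[t_idx]))
    x = np.stack(segs)                                   # (n_seg, n_ch, nperseg)
    Z = np.fft.rfft(x, n=params.n_fft, axis=-1)
    freqs = np.fft.rfftfreq(params.n_fft, 1.0 / fs)
    # one-sided density scaling (as in Welch): |Z|^2 * scale integrates to power
    scale = np.full(len(freqs), 2.0 / (fs * (taper ** 2).sum()))
    scale[0] = 1.0 / (fs * (taper ** 2).sum())
    if params.n_fft % 2 == 0:
        scale[-1] = 1.0 / (fs * (taper ** 2).sum())
    Z = Z * np.sqrt(scale)
    return freqs, Z, np.array(owner)


def _get_taper(name: str, n: int) -> np.ndarray:
    from scipy.signal import get_window
    return get_window(name, n, fftbins=True)


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class CrossSpectrumSet:
    """Per-segment cross- and auto-spectra for one channel pair."""

    freqs: np.ndarray
    sxy: np.ndarray                  # (n_segments, n_freqs) complex
    sxx: np.ndarray                  # (n_segments, n_freqs) real
    syy: np.ndarray
    pair: tuple[str, str] = ("x", "y")
    trial_of_segment: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def n_segments(self) -> int:
        return self.sxy.shape[0]


@dataclass
class WPLITable:
    """WPLI per channel pair and frequency bin, plus band aggregates."""

    freqs: np.ndarray
    pairs: list[tuple[str, str]]
    values: np.ndarray               # (n_pairs, n_freqs)
    n_segments: int
    bands: list[BandDef] = field(default_factory=lambda: list(ALL_BANDS))

    def pair_index(self, ch_a: str, ch_b: str) -> int:
        for i, (a, b) in enumerate(self.pairs):
            if {a, b} == {ch_a, ch_b}:
                return i
        raise KeyError(f"pair ({ch_a}, {ch_b}) not present")

    def band_values(self, band: BandDef, statistic: str = "mean") -> np.ndarray:
        mask = band.mask(self.freqs)
        if not mask.any():
            raise ValueError(f"no bins in band {band.name}")
        sub = self.values[:, mask]
        return sub.mean(axis=1) if statistic == "mean" else sub.max(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (a, b) in enumerate(self.pairs):
            row: dict = {"channel_a": a, "channel_b": b,
                         "n_segments": self.n_segments}
            for band in self.bands:
                m, pk, pf = band_aggregate(self.values[i], self.freqs, band)
                row[f"{band.name}_mean"] = m
                row[f"{band.name}_peak"] = pk
                row[f"{band.name}_peak_freq"] = pf
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class NullDistribution:
    """Permutation null of band WPLI with empirical percentile thresholds."""

    n_perm: int
    percentile: float
    seed: int
    band_samples: dict[str, np.ndarray]
    pooled_samples: np.ndarray
    thresholds: dict[str, float]
    pooled_threshold: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def pair_cross_spectra(epochs: EpochSet, ch_x: str, ch_y: str,
                       params: WelchParams | None = None) -> CrossSpectrumSet:
    """Cross-spectrum S_xy = X conj(Y) per tapered segment, pooled over epochs."""
    freqs, Z, owner = segment_spectra(epochs, params)
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 segments for a meaningful expectation")
    ix = epochs.channel_index(ch_x)
    iy = epochs.channel_index(ch_y)
    X, Y = Z[:, ix, :], Z[:, iy, :]
    return CrossSpectrumSet(freqs=freqs, sxy=X * np.conj(Y),
                            sxx=(X * np.conj(X)).real,
                            syy=(Y * np.conj(Y)).real,
                            pair=(ch_x, ch_y), trial_of_segment=owner)


def wpli_from_imag(im_sxy: np.ndarray) -> np.ndarray:
    """WPLI from the imaginary cross-spectrum, segments on axis 0.

    numerator = |mean Im(S_xy)|, denominator = mean |Im(S_xy)|; bins where
    the denominator is zero (e.g. identical signals) are defined as 0.
    """
    im_sxy = np.asarray(im_sxy, dtype=float)
    num = np.abs(im_sxy.mean(axis=0))
    den = np.abs(im_sxy).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def wpli(cross: CrossSpectrumSet) -> np.ndarray:
    """WPLI(f) for one channel pair.

    Bins whose mean |Im(S_xy)| is at machine-precision level relative to the
    cross-spectral magnitude (identical or purely zero-lag signals) take the
    undefined-as-zero convention rather than amplifying rounding noise.
    """
    if cross.n_segments < 2:
        raise ValueError("need at least 2 segments")
    out = wpli_from_imag(cross.sxy.imag)
    guard = 1e-10 * np.abs(cross.sxy).mean(axis=0)
    out[np.abs(cross.sxy.imag).mean(axis=0) <= guard] = 0.0
    return out


def coherence(cross: CrossSpectrumSet) -> np.ndarray:
    """Magnitude of the segment-averaged coherency (includes zero-lag coupling).

    Used as the contrast to WPLI on volume-conduction fixtures: a zero-lag
    common source drives coherence toward 1 while leaving WPLI at noise level.
    """
    num = np.abs(cross.sxy.mean(axis=0))
    den = np.sqrt(cross.sxx.mean(axis=0) * cross.syy.mean(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


def band_aggregate(wpli_f: np.ndarray, freqs: np.ndarray,
                   band: BandDef) -> tuple[float, float, float]:
    """(mean, peak, peak frequency) of a WPLI spectrum over one band.

    Ties at the peak resolve to the lowest frequency.
    """
    mask = band.mask(freqs)
    if not mask.any():
        raise ValueError(f"no bins in band {band.name}")
    sub = np.asarray(wpli_f)[mask]
    f = freqs[mask]
    i = int(np.argmax(sub))          # argmax returns the first (lowest-f) maximum
    return float(sub.mean()), float(sub[i]), float(f[i])


def wpli_all_pairs(epochs: EpochSet, params: WelchParams | None = None,
                   bands: list[BandDef] | None = None) -> WPLITable:
    """WPLI(f) for every unordered channel pair of one subject."""
    freqs, Z, _ = segment_spectra(epochs, params)
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 segments")
    names = epochs.ch_names
    pairs = list(combinations(range(len(names)), 2))
    values = np.empty((len(pairs), len(freqs)))
    for k, (i, j) in enumerate(pairs):
        im = (Z[:, i, :] * np.conj(Z[:, j, :])).imag
        values[k] = wpli_from_imag(im)
    return WPLITable(freqs=freqs,
                     pairs=[(names[i], names[j]) for i, j in pairs],
                     values=values, n_segments=Z.shape[0],
                     bands=list(bands) if bands is not None else list(ALL_BANDS))


def permutation_null(cohort: list[EpochSet], params: WelchParams | None = None,
                     n_perm: int = 10_000, percentile: float = 99.99,
                     seed: int = 0, bands: list[BandDef] | None = None,
                     statistic: str = "mean") -> NullDistribution:
    """Cross-subject permutation null for band WPLI.

    Each permutation draws two distinct subjects uniformly from the whole
    cohort and one uniformly random channel from each; their segment spectra
    are aligned by ordinal index and truncated to the shorter subject, and
    the WPLI of the synthetic pair is reduced to per-band statistics.  The
    threshold is the nearest-rank empirical percentile of the samples
    (per band, and pooled across bands).
    """
    if len(cohort) < 2:
        raise ValueError("permutation null needs at least 2 subjects")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if bands is None:
        bands = list(ALL_BANDS)
    rng = np.random.default_rng(seed)
    spectra = []
    freqs = None
    for ep in cohort:
        f, Z, _ = segment_spectra(ep, params)
        if freqs is None:
            freqs = f
        elif not np.array_equal(freqs, f):
            raise ValueError("subjects must share a frequency grid")
        spectra.append(Z)

    masks = {b.name: b.mask(freqs) for b in bands}
    samples = {b.name: np.empty(n_perm) for b in bands}
    n_subj = len(spectra)
    for p in range(n_perm):
        s1, s2 = rng.choice(n_subj, size=2, replace=False)
        Z1, Z2 = spectra[s1], spectra[s2]
        c1 = rng.integers(Z1.shape[1])
        c2 = rng.integers(Z2.shape[1])
        nseg = min(Z1.shape[0], Z2.shape[0])
        im = (Z1[:nseg, c1, :] * np.conj(Z2[:nseg, c2, :])).imag
        w = wpli_from_imag(im)
        for b in bands:
            sub = w[masks[b.name]]
            samples[b.name][p] = sub.mean() if statistic == "mean" else sub.max()

    pooled = np.concatenate([samples[b.name] for b in bands])
    thresholds = {name: nearest_rank_percentile(v, percentile)
                  for name, v in samples.items()}
    return NullDistribution(
        n_perm=n_perm, percentile=percentile, seed=seed,
        band_samples=samples, pooled_samples=pooled, thresholds=thresholds,
        pooled_threshold=nearest_rank_percentile(pooled, percentile))


def nearest_rank_percentile(samples: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the ceil(q/100 * n)-th smallest sample.

    At the 99.99th percentile with 10,000 samples this is the maximum.
    """
    s = np.sort(np.asarray(samples))
    rank = max(1, math.ceil(percentile / 100.0 * len(s)))
    return float(s[min(rank, len(s)) - 1])


def significant_pairs(table: WPLITable, null: NullDistribution,
                      bands: list[BandDef] | None = None,
                      statistic: str = "mean",
                      threshold_mode: str = "per_band") -> pd.DataFrame:
    """Flag pairs whose band WPLI strictly exceeds the null threshold."""
    if bands is None:
        bands = table.bands
    rows = []
    for band in bands:
        if threshold_mode == "per_band":
            thr = null.thresholds[band.name]
        elif threshold_mode == "pooled":
            thr = null.pooled_threshold
        else:
            raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
        vals = table.band_values(band, statistic=statistic)
        for (a, b), v in zip(table.pairs, vals):
            rows.append({"channel_a": a, "channel_b": b, "band": band.name,
                         "value": float(v), "threshold": thr,
                         "significant": bool(v > thr)})
    return pd.DataFrame(rows)


def significant_pair_counts(flags: pd.DataFrame) -> pd.DataFrame:
    """Per-band counts of significant pairs from a `significant_pairs` frame."""
    return (flags.groupby("band", sort=False)["significant"].sum()
            .rename("n_significant").reset_index())


def high_fc_pairs(values_by_group: dict[str, pd.DataFrame],
                  quartile: float = 0.75
                  ) -> tuple[dict[str, pd.DataFrame], float]:
    """Top-quartile functional-connectivity pair sets per group.

    The threshold is the `quartile` quantile (linear interpolation) of band
    WPLI values pooled across all groups' pairs; each group's high-FC set is
    the pairs strictly above it.  Input frames need columns ``channel_a``,
    ``channel_b`` and ``value``.
    """
    pooled = np.concatenate([df["value"].to_numpy() for df in values_by_group.values()])
    if len(pooled) < 4:
        raise ValueError("need at least 4 pairs to define a quartile")
    thr = float(np.quantile(pooled, quartile))
    out = {g: df.loc[df["value"] > thr].reset_index(drop=True)
           for g, df in values_by_group.items()}
    return out, thr
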