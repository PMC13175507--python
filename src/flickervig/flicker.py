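"""Flicker-response detection and the occluded artifact control.

A channel shows a significant steady-state flicker response when its power at
the stimulation frequency exceeds the mean power in the flanking frequencies
(31-39 and 41-49 Hz) by at least three standard deviations of those flank
bins.  A subject is "modulated" when at least three channels are flagged with
at least one flagged channel in each hemisphere (midline channels count
toward the total but toward neither hemisphere).

The occluded control applies the same detector to a recording made while the
subject's eyes and ears were occluded during stimulation: any channel flagged
there indicates electrical artifact rather than a neural response, and the
subject is marked artifact-suspect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import hemisphere
from .spectral import PSDSet


@dataclass
class ModulationCriterion:
    target_freq: float = 40.0
    flank_ranges: tuple[tuple[float, float], ...] = ((31.0, 39.0), (41.0, 49.0))
    sd_multiplier: float = 3.0
    min_channels: int = 3
    require_bilateral: bool = True
    target_mode: str = "exact"       # "exact" bin, or "window" = max over +-0.5 Hz

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")
        for lo, hi in self.flank_ranges:
            if lo <= self.target_freq <= hi:
                raise ValueError("target frequency must lie outside flank ranges")


@dataclass
class OccludedReport:
    flagged_channels: list[str]
    artifact_suspect: bool
    z_scores: pd.DataFrame = field(default_factory=pd.DataFrame)


def _target_power(psd: PSDSet, criterion: ModulationCriterion) -> np.ndarray:
    diffs = np.abs(psd.freqs - criterion.target_freq)
    if criterion.target_mode == "window":
        mask = diffs <= 0.5
        if not mask.any():
            raise ValueError("no bin within 0.5 Hz of the target frequency")
        return psd.power[mask].max(axis=0)
    i = int(np.argmin(diffs))
    if diffs[i] > 0.25:
        raise ValueError(
            f"no frequency bin at {criterion.target_freq} Hz "
            f"(nearest {psd.freqs[i]:.2f} Hz); use target_mode='window'")
    return psd.power[i]


def channel_modulation(psd: PSDSet,
                       criterion: ModulationCriterion | None = None) -> pd.DataFrame:
    """Per-channel flicker-response z-score and flag.

    z = (power at target bin - mean of flank bins) / SD of flank bins, with
    the flank statistics computed across frequency bins of the same
    (trial-averaged) spectrum; flag = z >= sd_multiplier.
    """
    if criterion is None:
        criterion = ModulationCriterion()
    flank_mask = np.zeros_like(psd.freqs, dtype=bool)
    for lo, hi in criterion.flank_ranges:
        flank_mask |= (psd.freqs >= lo) & (psd.freqs <= hi)
    if flank_mask.sum() < 5:
        raise ValueError("need at least 5 flank bins for the SD estimate")
    target = _target_power(psd, criterion)
    flank = psd.power[flank_mask]
    mean = flank.mean(axis=0)
    sd = flank.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [psd.ch_names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(
            f"zero flank SD on channels {bad}: flank spectrum is constant, "
            "z-score undefined")
    z = (target - mean) / sd
    return pd.DataFrame({
        "channel": psd.ch_names,
        "z_score": z,
        "modulated": z >= criterion.sd_multiplier,
    })


def subject_modulation(channel_flags: pd.DataFrame | dict[str, bool],
                       criterion: ModulationCriterion | None = None) -> bool:
    """Subject-level rule: >= min_channels flagged, both hemispheres hit."""
    if criterion is None:
        criterion = ModulationCriterion()
    if isinstance(channel_flags, pd.DataFrame):
        flags = dict(zip(channel_flags["channel"], channel_flags["modulated"]))
    else:
        flags = dict(channel_flags)
    flagged = [ch for ch, on in flags.items() if on]
    if len(flagged) < criterion.min_channels:
        return False
    if criterion.require_bilateral:
        sides = {hemisphere(ch) for ch in flagged}
        if not {"left", "right"} <= sides:
            return False
    return True


def occluded_check(psd_occluded: PSDSet,
                   criterion: ModulationCriterion | None = None) -> OccludedReport:
    """Artifact control: no channel should respond during occlusion.

    A flagged channel during occlusion means the apparent flicker response is
    electrical noise from the stimulation hardware, not brain activity.
    """
    table = channel_modulation(psd_occluded, criterion)
    flagged = table.loc[table.modulated, "channel"].tolist()
    return OccludedReport(flagged_channels=flagged,
                          artifact_suspect=bool(flagged),
                          z_scores=table)
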