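"""Continuous multi-channel EEG recordings and the 10-20 montage.

A :class:`Recording` holds one subject's continuous signal for one session
phase (baseline, occluded, or stimulation), together with the sampling rate,
channel labels, and an event stream.  Events are a tidy table with columns
``onset_s`` and ``event_type``; the recognised event types are
``trial_start``, ``change_onset``, ``response``, ``break_start`` and
``break_end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Channel labels of the 32-channel BioSemi 10-20 cap, in cap order.
BIOSEMI32 = [
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
]

EVENT_TYPES = ("trial_start", "change_onset", "response", "break_start", "break_end")


def empty_events() -> pd.DataFrame:
    return pd.DataFrame({"onset_s": pd.Series(dtype=float),
                         "event_type": pd.Series(dtype=str)})


@dataclass
class Recording:
    """Continuous EEG signal with metadata.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in volts (or any consistent unit; downstream normalization is
        scale-invariant).
    sfreq : float
        Sampling rate in Hz.
    ch_names : list of str
        Unique channel labels following the 10-20 convention.
    events : DataFrame
        Columns ``onset_s`` (seconds from recording start) and ``event_type``.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    events: pd.DataFrame = field(default_factory=empty_events)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.ch_names)} channel labels for {self.data.shape[0]} rows"
            )
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sfreq

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None

    def breaks(self) -> list[tuple[float, float]]:
        """Return (start_s, end_s) intervals marked by break events."""
        ev = self.events
        starts = ev.loc[ev.event_type == "break_start", "onset_s"].to_numpy()
        ends = ev.loc[ev.event_type == "break_end", "onset_s"].to_numpy()
        if len(starts) != len(ends):
            raise ValueError("unmatched break_start/break_end events")
        return [(float(s), float(e)) for s, e in zip(np.sort(starts), np.sort(ends))]


def hemisphere(label: str) -> str:
    """Classify a 10-20 channel label as ``left``, ``right`` or ``midline``.

    Odd-numbered labels are over the left hemisphere, even-numbered over the
    right, and labels ending in ``z`` lie on the midline.
    """
    if label[-1] in ("z", "Z"):
        return "midline"
    digits = ""
    for ch in reversed(label):
        if ch.isdigit():
            digits = ch + digits
        else:
            break
    if not digits:
        raise ValueError(f"cannot place channel {label!r}: no digit or 'z' suffix")
    return "left" if int(digits) % 2 == 1 else "right"


def hemisphere_map(ch_names: list[str]) -> dict[str, str]:
    """Map every montage channel to its hemisphere."""
    return {name: hemisphere(name) for name in ch_names}
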