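"""File formats: HDF5 recording container, trial TSVs, manifests, config.

The HDF5-style container is the canonical fixture format (signal matrix,
sampling rate, labels, event stream).  EDF/BDF recordings are read through
mne.  Events can also be read from a sidecar TSV with columns ``onset_s`` and
``event_type``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .recording import Recording, empty_events


class UnknownFormatError(ValueError):
    """Unrecognised recording file format."""


class ChannelMismatchError(ValueError):
    """Channel labels do not match the expected montage."""


class MissingEventsError(ValueError):
    """No event stream found for a recording that requires one."""


# ---------------------------------------------------------------------------
# recording container
# ---------------------------------------------------------------------------

def save_recording(recording: Recording, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=recording.data)
        f.attrs["sfreq"] = recording.sfreq
        f.attrs["ch_names"] = np.array([str(c) for c in recording.ch_names],
                                       dtype=h5py.string_dtype())
        ev = f.create_group("events")
        ev.create_dataset("onset_s", data=recording.events["onset_s"].to_numpy(float))
        names = [str(s) for s in recording.events["event_type"]]
        ev.create_dataset(
            "event_type",
            data=np.array(names, dtype="S") if names else np.zeros(0, dtype="S1"))


def load_recording(path: str | Path) -> Recording:
    with h5py.File(Path(path), "r") as f:
        data = f["signal"][()]
        sfreq = float(f.attrs["sfreq"])
        ch_names = [c if isinstance(c, str) else c.decode() for c in f.attrs["ch_names"]]
        events = pd.DataFrame({
            "onset_s": f["events/onset_s"][()],
            "event_type": [e.decode() if isinstance(e, bytes) else e
                           for e in f["events/event_type"][()]],
        }) if "events" in f else empty_events()
    return Recording(data=data, sfreq=sfreq, ch_names=ch_names, events=events)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    missing = {"onset_s", "event_type"} - set(ev.columns)
    if missing:
        raise MissingEventsError(f"events TSV lacks columns {sorted(missing)}")
    return ev[["onset_s", "event_type"]]


def read_recording(path: str | Path, fmt: str | None = None,
                   expected_montage: list[str] | None = None,
                   events_path: str | Path | None = None) -> Recording:
    """Read a recording from the HDF5 container or an EDF/BDF file.

    ``fmt`` is inferred from the suffix when omitted.  If ``expected_montage``
    is given the file's channels must match it exactly.  For EDF/BDF an event
    sidecar TSV can be supplied.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".h5": "hdf5", ".hdf5": "hdf5",
               ".edf": "edf", ".bdf": "bdf"}.get(path.suffix.lower())
    if fmt == "hdf5":
        rec = load_recording(path)
    elif fmt in ("edf", "bdf"):
        import mne
        reader = mne.io.read_raw_edf if fmt == "edf" else mne.io.read_raw_bdf
        raw = reader(path, preload=True, verbose="error")
        rec = Recording(data=raw.get_data(), sfreq=float(raw.info["sfreq"]),
                        ch_names=list(raw.ch_names), events=empty_events())
    else:
        raise UnknownFormatError(f"cannot determine format of {path}")
    if events_path is not None:
        rec.events = read_events_tsv(events_path)
    if expected_montage is not None and list(rec.ch_names) != list(expected_montage):
        raise ChannelMismatchError(
            f"{path.name}: {len(rec.ch_names)} channels do not match the "
            f"expected {len(expected_montage)}-channel montage")
    return rec


# ---------------------------------------------------------------------------
# trial tables
# ---------------------------------------------------------------------------

def save_trials(trials: pd.DataFrame, path: str | Path,
                response_window: float = 1.0) -> None:
    """Write a trial table as TSV.

    Emits the summary columns (first in-window response or NA, premature
    flag) plus a lossless ``press_times`` column (semicolon-separated).
    """
    out = trials[["trial_index", "trial_start_s", "change_onset_s"]].copy()
    resp, prem, press = [], [], []
    for _, tr in trials.iterrows():
        presses = sorted(tr.press_times)
        prem.append(any(p < tr.change_onset_s for p in presses))
        hits = [p for p in presses
                if tr.change_onset_s < p <= tr.change_onset_s + response_window]
        resp.append(hits[0] if hits else np.nan)
        press.append(";".join(f"{p:.6f}" for p in presses))
    out["response_s_or_NA"] = resp
    out["premature_flag"] = prem
    out["press_times"] = press
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def load_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"],
                     dtype={"press_times": str})
    press = [tuple(float(x) for x in s.split(";")) if isinstance(s, str) and s
             else () for s in df["press_times"].fillna("")]
    return pd.DataFrame({
        "trial_index": df["trial_index"].astype(int),
        "trial_start_s": df["trial_start_s"].astype(float),
        "change_onset_s": df["change_onset_s"].astype(float),
        "press_times": press,
    })


# ---------------------------------------------------------------------------
# manifest and config
# ---------------------------------------------------------------------------

def save_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_to_yaml(config) -> str:
    """Serialize a (nested dataclass) config to YAML."""
    return yaml.safe_dump(_listify(dataclasses.asdict(config)), sort_keys=True)


def config_hash(config) -> str:
    return hashlib.sha256(config_to_yaml(config).encode()).hexdigest()[:16]


def save_config(config, path: str | Path) -> None:
    Path(path).write_text(config_to_yaml(config))


def load_config_dict(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}
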