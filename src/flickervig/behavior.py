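"""Psychomotor vigilance task scoring.

Every trial is labeled exactly one of premature / hit / miss:

* premature — any key press before the color change;
* hit — otherwise, first press within the response window (1 s by default)
  after the color change; reaction time is recorded for hits only;
* miss — otherwise.

Accuracy is hits out of total trials; subjects with accuracy below 80% are
considered disengaged and excluded from behavior statistics (the boundary is
strict: exactly 80% is retained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABELS = ("hit", "miss", "premature")


@dataclass
class BehaviorSummary:
    n_trials: int
    n_hits: int
    n_misses: int
    n_premature: int
    accuracy: float
    mean_rt: float | None
    rt_variability: float | None
    included: bool


def classify_trials(trials: pd.DataFrame,
                    response_window: float = 1.0) -> pd.DataFrame:
    """Label each trial and record reaction times for hits.

    Expects columns ``trial_index``, ``trial_start_s``, ``change_onset_s``
    and ``press_times`` (iterable of press times in session seconds).
    Presses after the response window are ignored for the current trial and
    counted in ``n_late_presses``.  A press before the trial start is
    malformed input.
    """
    if response_window <= 0:
        raise ValueError("response_window must be positive")
    labels, rts, late = [], [], []
    for _, tr in trials.iterrows():
        presses = sorted(tr.press_times)
        if presses and presses[0] < tr.trial_start_s:
            raise ValueError(
                f"trial {tr.trial_index}: press at {presses[0]:.3f}s precedes "
                f"trial start {tr.trial_start_s:.3f}s")
        in_window = [p for p in presses
                     if tr.change_onset_s < p <= tr.change_onset_s + response_window]
        n_late = sum(p > tr.change_onset_s + response_window for p in presses)
        if presses and presses[0] < tr.change_onset_s:
            labels.append("premature")
            rts.append(np.nan)
        elif in_window:
            labels.append("hit")
            rts.append(in_window[0] - tr.change_onset_s)
        else:
            labels.append("miss")
            rts.append(np.nan)
        late.append(n_late)
    out = trials.copy()
    out["label"] = labels
    out["rt"] = rts
    out["n_late_presses"] = late
    n_late_total = int(sum(late))
    if n_late_total:
        logger.info("ignored %d presses outside the response window", n_late_total)
    return out


def behavior_summary(labeled: pd.DataFrame,
                     min_accuracy: float = 0.80) -> BehaviorSummary:
    """Per-subject accuracy, mean RT and RT variability (sample SD of hit RTs)."""
    if len(labeled) == 0:
        raise ValueError("need at least one trial")
    counts = labeled["label"].value_counts()
    n_hits = int(counts.get("hit", 0))
    n_misses = int(counts.get("miss", 0))
    n_premature = int(counts.get("premature", 0))
    n_trials = len(labeled)
    accuracy = n_hits / n_trials
    hit_rts = labeled.loc[labeled.label == "hit", "rt"].to_numpy()
    mean_rt = float(hit_rts.mean()) if n_hits else None
    rt_var = float(hit_rts.std(ddof=1)) if n_hits >= 2 else None
    return BehaviorSummary(
        n_trials=n_trials, n_hits=n_hits, n_misses=n_misses,
        n_premature=n_premature, accuracy=accuracy, mean_rt=mean_rt,
        rt_variability=rt_var, included=accuracy >= min_accuracy)


def summaries_frame(summaries: dict[str, tuple[str, BehaviorSummary]]) -> pd.DataFrame:
    """Tidy frame from {subject_id: (group, BehaviorSummary)}."""
    rows = []
    for sid, (group, s) in summaries.items():
        rows.append({"subject": sid, "group": group, "n_trials": s.n_trials,
                     "n_hits": s.n_hits, "n_misses": s.n_misses,
                     "n_premature": s.n_premature, "accuracy": s.accuracy,
                     "mean_rt": s.mean_rt, "rt_variability": s.rt_variability,
                     "included": s.included})
    return pd.DataFrame(rows)


def exclude_outliers(summaries: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects flagged not-included; return (kept, exclusion log)."""
    excluded = summaries.loc[~summaries["included"]].copy()
    excluded["reason"] = "accuracy below engagement threshold"
    kept = summaries.loc[summaries["included"]].reset_index(drop=True)
    if len(excluded):
        logger.info("excluded %d subjects from behavior statistics: %s",
                    len(excluded), excluded["subject"].tolist())
    return kept, excluded.reset_index(drop=True)
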