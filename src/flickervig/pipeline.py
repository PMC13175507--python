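"""End-to-end orchestration: simulate -> filter -> epoch -> PSD -> flicker
check -> connectivity + permutation null -> behavior -> statistics.

``run_pipeline`` executes every stage on a synthetic cohort (or on recordings
read from disk), writes tidy TSV/JSON outputs and a provenance record, and is
deterministic given the global seed: every stochastic stage receives a child
seed derived from it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as fio
from .behavior import behavior_summary, classify_trials, exclude_outliers, summaries_frame
from .connectivity import (high_fc_pairs, permutation_null, significant_pair_counts,
                           significant_pairs, wpli_all_pairs)
from .flicker import ModulationCriterion, channel_modulation, occluded_check, subject_modulation
from .recording import Recording
from .spectral import (ALL_BANDS, CANONICAL_BANDS, LOWER_ALPHA, UPPER_ALPHA,
                       WelchParams, band_power_table, highpass_filter, make_epochs,
                       normalize_psd, resample_recording, welch_psd)
from .stats import kruskal_posthoc, proportion_test, spearman_behavior, tstat_map, two_by_two_counts
from .synthetic import (DEFAULT_GROUP_EFFECTS, GroupEffect, SimConfig, Subject,
                        TaskConfig, simulate_cohort)

logger = logging.getLogger(__name__)

CHANNELS_OF_INTEREST = ("Fp1", "Cz", "Oz")


def default_sim_config() -> SimConfig:
    """Cohort-level simulation defaults: alpha-band coupled posterior pairs."""
    return SimConfig(coupled_pairs=[
        ("O1", "O2", 9.0, np.pi / 2, 0.5),
        ("PO3", "PO4", 9.0, np.pi / 3, 0.45),
        ("P3", "P4", 9.5, np.pi / 2.5, 0.4),
        ("CP5", "CP6", 11.5, np.pi / 2, 0.35),
    ])


@dataclass
class PipelineConfig:
    mode: str = "synthetic"                     # "synthetic" | "real"
    input_dir: str | None = None
    n_per_group: tuple[int, int, int] = (8, 8, 8)
    sim: SimConfig = field(default_factory=default_sim_config)
    task: TaskConfig = field(default_factory=lambda: TaskConfig(
        session_length=410.0, break_schedule=[(200.0, 20.0)]))
    effects: dict[str, GroupEffect] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS))
    welch: WelchParams = field(default_factory=WelchParams)
    criterion: ModulationCriterion = field(default_factory=ModulationCriterion)
    epoch_window: tuple[float, float] = (-4.0, 0.0)
    highpass_hz: float = 1.0
    working_rate: float = 512.0
    norm_range: tuple[float, float] = (2.0, 55.0)
    n_perm: int = 1000
    percentile: float = 99.99
    q_level: float = 0.05
    quartile: float = 0.75
    exclude_unmodulated: bool = True
    include_occluded: bool = True
    seed: int = 0
    log_level: str = "INFO"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write the report bundle; returns the stats report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    cohort_seed, null_seed = (int(s) for s in ss.generate_state(2) % (2 ** 31))

    if config.mode != "synthetic":
        raise NotImplementedError(
            "real-data mode: read recordings with flickervig.io.read_recording "
            "and assemble Subject objects; the orchestrated path covers the "
            "synthetic cohort")

    stage = "simulate"
    try:
        subjects = simulate_cohort(
            config.n_per_group, config.sim, config.task, config.effects,
            seed=cohort_seed, include_occluded=config.include_occluded)

        manifest: dict[str, dict] = {}
        band_rows, mod_rows, wpli_frames = [], [], []
        summaries: dict[str, tuple[str, object]] = {}
        epochsets: dict[str, object] = {}
        norm_psds: dict[str, object] = {}

        for subj in subjects:
            stage = f"process {subj.subject_id}"
            rec = subj.recording
            if rec.sfreq != config.working_rate:
                rec = resample_recording(rec, config.working_rate)
            rec = highpass_filter(rec, config.highpass_hz)
            epochs = make_epochs(rec, subj.trials, config.epoch_window)
            raw_psd = welch_psd(epochs, config.welch)
            norm = normalize_psd(raw_psd, *config.norm_range)

            mod = channel_modulation(raw_psd, config.criterion)
            modulated = subject_modulation(mod, config.criterion)
            for _, r in mod.iterrows():
                mod_rows.append({"subject": subj.subject_id, "group": subj.group,
                                 "channel": r.channel, "z_score": r.z_score,
                                 "modulated": bool(r.modulated)})
            artifact_suspect = False
            if subj.occluded is not None:
                occ = highpass_filter(subj.occluded, config.highpass_hz)
                occ_psd = _continuous_psd(occ, config.welch)
                artifact_suspect = occluded_check(occ_psd, config.criterion).artifact_suspect

            bp = band_power_table(norm, ALL_BANDS, mode="peak")
            bp.insert(0, "subject", subj.subject_id)
            bp.insert(1, "group", subj.group)
            band_rows.append(bp)

            labeled = classify_trials(subj.trials, config.task.response_window)
            summaries[subj.subject_id] = (subj.group, behavior_summary(labeled))

            table = wpli_all_pairs(epochs, config.welch, ALL_BANDS)
            tf = table.to_frame()
            tf.insert(0, "subject", subj.subject_id)
            tf.insert(1, "group", subj.group)
            wpli_frames.append(tf)
            epochsets[subj.subject_id] = epochs
            norm_psds[subj.subject_id] = norm

            manifest[subj.subject_id] = {
                "group": subj.group,
                "modulated": bool(modulated) if subj.group == "40Hz" else True,
                "artifact_suspect": bool(artifact_suspect),
            }

        stage = "flicker exclusion"
        # only 40 Hz-group subjects can fail the flicker-response criterion in
        # the synthetic design (controls are simulated without the brief
        # post-session 40 Hz exposure)
        analyzed = [s for s in subjects
                    if manifest[s.subject_id]["modulated"] or not config.exclude_unmodulated]

        stage = "behavior"
        beh = summaries_frame(summaries)
        beh_kept, beh_excluded = exclude_outliers(beh)
        for sid in manifest:
            manifest[sid]["behavior_included"] = bool(
                beh.loc[beh.subject == sid, "included"].iloc[0])

        stage = "permutation null"
        null = permutation_null([epochsets[s.subject_id] for s in analyzed],
                                config.welch, n_perm=config.n_perm,
                                percentile=config.percentile, seed=null_seed,
                                bands=ALL_BANDS)

        stage = "connectivity significance"
        wpli_df = pd.concat(wpli_frames, ignore_index=True)
        fc_counts = []
        for subj in analyzed:
            sub_tab = wpli_all_pairs(epochsets[subj.subject_id], config.welch, ALL_BANDS)
            flags = significant_pairs(sub_tab, null, ALL_BANDS)
            counts = significant_pair_counts(flags)
            counts.insert(0, "subject", subj.subject_id)
            counts.insert(1, "group", subj.group)
            fc_counts.append(counts)
        fc_counts = pd.concat(fc_counts, ignore_index=True)
        group_band_counts = (fc_counts.groupby(["group", "band"], sort=False)
                             ["n_significant"].sum().reset_index())

        stage = "statistics"
        report = _statistics_report(config, beh_kept, band_rows, wpli_df,
                                    group_band_counts, norm_psds, manifest)

        stage = "write outputs"
        beh.to_csv(out / "behavior.tsv", sep="\t", index=False)
        beh_excluded.to_csv(out / "behavior_exclusions.tsv", sep="\t", index=False)
        pd.concat(band_rows, ignore_index=True).to_csv(
            out / "band_power.tsv", sep="\t", index=False)
        pd.DataFrame(mod_rows).to_csv(out / "modulation.tsv", sep="\t", index=False)
        wpli_df.to_csv(out / "wpli.tsv", sep="\t", index=False,
                       float_format="%.6g")
        group_band_counts.to_csv(out / "fc_pair_counts.tsv", sep="\t", index=False)
        fio.save_manifest(_jsonable(manifest), out / "manifest.json")
        (out / "null.json").write_text(json.dumps(_jsonable({
            "n_perm": null.n_perm, "percentile": null.percentile,
            "seed": null.seed, "thresholds": null.thresholds,
            "pooled_threshold": null.pooled_threshold}), indent=2, sort_keys=True))
        (out / "stats.json").write_text(json.dumps(_jsonable(report), indent=2,
                                                   sort_keys=True))
        (out / "provenance.json").write_text(json.dumps({
            "config_hash": fio.config_hash(config),
            "seed": config.seed, "n_perm": config.n_perm,
            "version": __version__}, indent=2, sort_keys=True))
        fio.save_config(config, out / "config.yaml")
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err
    return report


def _continuous_psd(recording: Recording, welch: WelchParams):
    """Welch PSD of a whole continuous recording (used for occluded phases)."""
    from .spectral import EpochSet
    ep = EpochSet(data=recording.data[None, :, :], sfreq=recording.sfreq,
                  ch_names=list(recording.ch_names), window=(0.0, 0.0),
                  trial_indices=np.array([0]))
    return welch_psd(ep, welch)


def _comparison_dict(gc) -> dict:
    return {"H": gc.h_statistic, "df": gc.df, "p": gc.p_value,
            "posthoc": gc.posthoc.to_dict(orient="records")}


def _statistics_report(config, beh_kept, band_rows, wpli_df,
                       group_band_counts, norm_psds, manifest) -> dict:
    report: dict = {"behavior": {}, "band_power": {}, "correlations": {},
                    "connectivity": {}}

    # --- behavior group comparisons -------------------------------------
    for measure in ("accuracy", "mean_rt", "rt_variability"):
        vals = {g: beh_kept.loc[beh_kept.group == g, measure].dropna().to_numpy()
                for g in beh_kept.group.unique()}
        if all(len(v) >= 3 for v in vals.values()) and len(vals) >= 2:
            report["behavior"][measure] = _comparison_dict(
                kruskal_posthoc(vals, q_level=config.q_level, measure=measure))
    report["behavior"]["group_means"] = (
        beh_kept.groupby("group")[["accuracy", "mean_rt"]].mean()
        .to_dict(orient="index"))

    # --- band power comparisons at the channels of interest -------------
    bp = pd.concat(band_rows, ignore_index=True)
    for band in ("delta", "flicker"):
        report["band_power"][band] = {}
        for ch in CHANNELS_OF_INTEREST:
            sel = bp[(bp.band == band) & (bp.channel == ch)]
            vals = {g: sel.loc[sel.group == g, "value"].to_numpy()
                    for g in sel.group.unique()}
            if all(len(v) >= 3 for v in vals.values()) and len(vals) >= 2:
                report["band_power"][band][ch] = _comparison_dict(
                    kruskal_posthoc(vals, q_level=config.q_level,
                                    measure=f"{band}@{ch}"))

    # --- power-behavior Spearman correlations ---------------------------
    included = beh_kept.set_index("subject")
    feat_rows = bp[bp.subject.isin(included.index)]
    wide = feat_rows.pivot_table(index="subject", columns=["band", "channel"],
                                 values="value")
    canon = [b.name for b in CANONICAL_BANDS]
    canon_cols = [c for c in wide.columns
                  if c[0] in canon and c[1] in CHANNELS_OF_INTEREST]
    flick_cols = [c for c in wide.columns
                  if c[0] == "flicker" and c[1] in CHANNELS_OF_INTEREST]
    for name, cols, family in (("band_power_vs_accuracy", canon_cols, 15),
                               ("flicker_vs_accuracy", flick_cols, 3)):
        if len(wide) >= 5 and cols:
            feats = wide[cols]
            feats.columns = [f"{b}:{c}" for b, c in feats.columns]
            res = spearman_behavior(feats,
                                    included.loc[wide.index, "accuracy"],
                                    family=family, q_level=config.q_level)
            report["correlations"][name] = res.to_dict(orient="records")
    if len(wide) >= 5 and canon_cols:
        feats = wide[canon_cols]
        feats.columns = [f"{b}:{c}" for b, c in feats.columns]
        res = spearman_behavior(feats, included.loc[wide.index, "mean_rt"],
                                family=15, q_level=config.q_level)
        report["correlations"]["band_power_vs_rt"] = res.to_dict(orient="records")

    # --- functional connectivity ----------------------------------------
    report["connectivity"]["significant_pair_counts"] = (
        group_band_counts.to_dict(orient="records"))
    for band in (LOWER_ALPHA, UPPER_ALPHA):
        col = f"{band.name}_mean"
        groups = {g: wpli_df.loc[wpli_df.group == g, ["channel_a", "channel_b", col]]
                  .groupby(["channel_a", "channel_b"], as_index=False).mean()
                  .rename(columns={col: "value"})
                  for g in wpli_df.group.unique()}
        sets, thr = high_fc_pairs(groups, config.quartile)
        entry = {"quartile_threshold": thr,
                 "n_high_fc": {g: int(len(df)) for g, df in sets.items()}}
        for other in ("Light", "Random"):
            if "40Hz" in sets and other in sets:
                counts = two_by_two_counts(
                    len(sets["40Hz"]), len(groups["40Hz"]),
                    len(sets[other]), len(groups[other]))
                try:
                    pt = proportion_test(counts)
                    entry[f"40Hz_vs_{other}"] = {
                        "chi2": pt.chi2, "df": pt.df, "p": pt.p_value,
                        "cramers_v": pt.cramers_v}
                except ValueError:
                    entry[f"40Hz_vs_{other}"] = {"error": "degenerate table"}
        report["connectivity"][band.name] = entry

    # --- per-channel t-statistic maps (40 Hz minus Light) ---------------
    by_group: dict[str, list[np.ndarray]] = {}
    ch_names = None
    for sid, psd in norm_psds.items():
        g = manifest[sid]["group"]
        from .spectral import DELTA, band_peak_power
        by_group.setdefault(g, []).append(band_peak_power(psd, DELTA))
        ch_names = psd.ch_names
    if {"40Hz", "Light"} <= set(by_group) and all(
            len(by_group[g]) >= 2 for g in ("40Hz", "Light")):
        tm = tstat_map(np.array(by_group["40Hz"]), np.array(by_group["Light"]),
                       ch_names)
        report["tstat_map_delta_40Hz_vs_Light"] = tm.to_dict(orient="records")
    return report


def config_from_dict(d: dict) -> PipelineConfig:
    """Rebuild a PipelineConfig from a YAML/JSON dictionary."""
    kw = dict(d)
    if "sim" in kw:
        sim = dict(kw["sim"])
        if sim.get("band_oscillations") is not None:
            sim["band_oscillations"] = [tuple(b) for b in sim["band_oscillations"]]
        if sim.get("coupled_pairs") is not None:
            sim["coupled_pairs"] = [tuple(p) for p in sim["coupled_pairs"]]
        kw["sim"] = SimConfig(**sim)
    if "task" in kw:
        task = dict(kw["task"])
        if task.get("break_schedule") is not None:
            task["break_schedule"] = [tuple(b) for b in task["break_schedule"]]
        kw["task"] = TaskConfig(**task)
    if "effects" in kw:
        kw["effects"] = {g: GroupEffect(**e) for g, e in kw["effects"].items()}
    if "welch" in kw:
        kw["welch"] = WelchParams(**kw["welch"])
    if "criterion" in kw:
        crit = dict(kw["criterion"])
        if crit.get("flank_ranges") is not None:
            crit["flank_ranges"] = tuple(tuple(r) for r in crit["flank_ranges"])
        kw["criterion"] = ModulationCriterion(**crit)
    for key in ("n_per_group", "epoch_window", "norm_range"):
        if key in kw and kw[key] is not None:
            kw[key] = tuple(kw[key])
    return PipelineConfig(**kw)
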