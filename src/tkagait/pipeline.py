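"""End-to-end analysis pipeline: simulate -> kin -> emg -> syn -> stats.

Each stage reads the dataset manifest and/or the previous stage's tabular
output from the results directory and writes plain-text tables, so stages
can be run independently (the CLI exposes one subcommand per stage) or all
at once via :func:`run_pipeline`. Every output row carries subject / group /
activity / cycle keys; a run log, the config snapshot and all seeds are
written beside the results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from . import kinematics as kin
from . import synergies as syn
from . import synthetic as sd
from . import stats as st
from .emg import MUSCLES, RawEMG, process_trials

__all__ = ["simulate", "stage_kin", "stage_emg", "stage_syn", "stage_stats",
           "stage_report", "run_pipeline"]

logger = logging.getLogger("tkagait")

_KIN_PARAMS = ("flexion", "abduction", "internal", "medial_ap", "lateral_ap")


def _setup_run_log(results_dir: Path) -> None:
    results_dir.mkdir(parents=True, exist_ok=True)
    if not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == (results_dir / "run.log").resolve()
        for h in logger.handlers
    ):
        fh = logging.FileHandler(results_dir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
    if not logger.handlers or all(isinstance(h, logging.FileHandler) for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(sh)
    logger.setLevel(logging.INFO)


def _config_hash(config: tio.RunConfig) -> str:
    return hashlib.sha256(json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------

def _cohort_seed(master_seed: int, activity_idx: int, group_idx: int) -> int:
    return int(master_seed) + 1000 * activity_idx + 100 * group_idx


def simulate(config: tio.RunConfig, out_dir: str | Path, seed: int) -> Path:
    """Write a full synthetic dataset (all formats + ground truth + manifest).

    The dataset is staged in a sibling ``.partial`` directory and moved into
    place on success, so a failure never leaves a half-written dataset.
    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    staging = out_dir.parent / (out_dir.name + ".partial")
    tio.remove_partial(staging)
    staging.mkdir(parents=True)
    try:
        manifest = tio.DatasetManifest(
            root=str(staging),
            master_seed=int(seed),
            generator_version=tio.GENERATOR_VERSION,
        )
        ground_truth: dict = {}
        group_sizes = {"stable": config.n_stable, "unstable": config.n_unstable}
        for ai, activity in enumerate(config.activities):
            ground_truth[activity] = {}
            for gi, group in enumerate(sd.GROUP_LABELS):
                width = config.unstable_flexor_width_scale if group == "unstable" else 1.0
                truth = sd.default_truth(activity, flexor_width_scale=width)
                spec = sd.CohortSpec(
                    group_label=group,
                    n_subjects=group_sizes[group],
                    cycles_per_subject=config.cycles_per_subject,
                    activity=activity,
                    seed=_cohort_seed(seed, ai, gi),
                )
                kin_trials = sd.generate_kinematics(spec)
                emg_trials = sd.generate_emg(spec, truth, noise_pct=config.emg_noise_pct)
                force_trials = sd.generate_force(spec, noise_n=5.0)
                gt_group = {
                    "modules_truth": truth.modules,
                    "patterns_truth": truth.patterns,
                    "labels": list(truth.labels),
                    "seed": spec.seed,
                    "subjects": {},
                }
                for s in range(spec.n_subjects):
                    sid = f"{group[:2]}{s:02d}"
                    entry = tio.SubjectEntry(subject_id=sid, group=group, activity=activity)
                    gt_cycles = []
                    for c in range(spec.cycles_per_subject):
                        rel = Path(activity) / group / sid / f"cycle{c}"
                        trial_dir = staging / rel
                        trial_dir.mkdir(parents=True)
                        kt = kin_trials[s][c]
                        et = emg_trials[s][c]
                        ft = force_trials[s][c]
                        tio.write_pose_tsv(trial_dir / "poses.tsv", kt.poses)
                        tio.write_events_json(trial_dir / "events.json", kt.poses.events)
                        tio.write_condyle_csv(
                            trial_dir / "medial_condyle.csv", kt.geometry.medial_points
                        )
                        tio.write_condyle_csv(
                            trial_dir / "lateral_condyle.csv", kt.geometry.lateral_points
                        )
                        tio.write_plane_json(trial_dir / "plane.json", kt.geometry.tibial_plane)
                        tio.write_emg_csv(trial_dir / "emg.csv", et.time_s, et.raw.signals)
                        tio.write_force_csv(trial_dir / "force.csv", ft.time_s, ft.force_n)
                        entry.trials.append(
                            tio.TrialPaths(
                                cycle=c,
                                poses=str(rel / "poses.tsv"),
                                events=str(rel / "events.json"),
                                medial_condyle=str(rel / "medial_condyle.csv"),
                                lateral_condyle=str(rel / "lateral_condyle.csv"),
                                plane=str(rel / "plane.json"),
                                emg=str(rel / "emg.csv"),
                                force=str(rel / "force.csv"),
                            )
                        )
                        gt_cycles.append(
                            {
                                "toe_off_pct": kt.truth["toe_off_pct"],
                                "events": dataclasses.asdict(kt.poses.events),
                                "heelstrike_force_index": ft.heelstrike_index,
                            }
                        )
                    gt_group["subjects"][sid] = {
                        "modules": emg_trials[s][0].modules_subject,
                        "cycles": gt_cycles,
                    }
                    manifest.subjects.append(entry)
                ground_truth[activity][group] = gt_group
        tio.write_json(staging / "ground_truth.json", ground_truth)
        config.save(staging / "config.json")
        tio.write_manifest(staging / "manifest.json", manifest)
        tio.remove_partial(out_dir)
        staging.rename(out_dir)
    except Exception:
        tio.remove_partial(staging)
        raise
    return out_dir / "manifest.json"


# ---------------------------------------------------------------------------
# kinematics stage
# ---------------------------------------------------------------------------

def stage_kin(manifest: tio.DatasetManifest, config: tio.RunConfig, results_dir: str | Path) -> Path:
    """Angles + condylar A-P per trial, 101-point cycles and per-phase RoM tables."""
    results_dir = Path(results_dir)
    _setup_run_log(results_dir)
    cycle_rows, rom_rows = [], []
    for sub in manifest.subjects:
        for tr in sub.trials:
            try:
                events = tio.read_events_json(manifest.resolve(tr.events))
                series = tio.read_pose_tsv(manifest.resolve(tr.poses), events)
                geometry = tio.read_geometry(
                    manifest.resolve(tr.medial_condyle),
                    manifest.resolve(tr.lateral_condyle),
                    manifest.resolve(tr.plane),
                )
                tracks = kin.pose_tracks(series, geometry)
                cycle = kin.time_normalize_cycle(series, tracks)
                rom = kin.rom_summary(cycle)
            except (tio.DataError, ValueError) as exc:
                logger.warning(
                    "skipping trial %s/%s cycle %d: %s",
                    sub.subject_id, sub.activity, tr.cycle, exc,
                )
                continue
            key = dict(
                subject=sub.subject_id, group=sub.group,
                activity=sub.activity, cycle=tr.cycle,
            )
            for i in range(101):
                cycle_rows.append(
                    {**key, "point": i, "toe_off_pct": cycle.toe_off_pct,
                     **{p: cycle.track(p)[i] for p in _KIN_PARAMS}}
                )
            for phase in ("stance", "swing"):
                for param, value in getattr(rom, phase).items():
                    rom_rows.append({**key, "phase": phase, "parameter": param, "rom": value})
    pd.DataFrame(cycle_rows).to_csv(results_dir / "kin_cycles.csv", index=False)
    pd.DataFrame(rom_rows).to_csv(results_dir / "kin_rom.csv", index=False)
    logger.info("kin stage: %d cycle rows, %d RoM rows", len(cycle_rows), len(rom_rows))
    return results_dir / "kin_rom.csv"


# ---------------------------------------------------------------------------
# EMG stage
# ---------------------------------------------------------------------------

def _emg_events_from_pose(events: kin.GaitEvents, pose_rate: float,
                          time_s: np.ndarray, emg_rate: float) -> tuple[int, int, int]:
    """Map pose-frame gait events onto the EMG sample axis via time."""
    t0 = time_s[0]
    idx = []
    for frame in (events.heel_strike_1, events.toe_off, events.heel_strike_2):
        t = frame / pose_rate
        idx.append(int(np.clip(round((t - t0) * emg_rate), 0, len(time_s) - 1)))
    return idx[0], idx[1], idx[2]


def stage_emg(manifest: tio.DatasetManifest, config: tio.RunConfig, results_dir: str | Path) -> Path:
    """Filter, rectify, smooth and normalize EMG into 200-point envelopes."""
    results_dir = Path(results_dir)
    _setup_run_log(results_dir)
    rows = []
    by_subject: dict[tuple, list] = {}
    for sub in manifest.subjects:
        trials = []
        for tr in sub.trials:
            try:
                time_s, signals = tio.read_emg_csv(manifest.resolve(tr.emg))
                events = tio.read_events_json(manifest.resolve(tr.events))
                rate = 1.0 / np.median(np.diff(time_s))
                ev = _emg_events_from_pose(events, 30.0, time_s, rate)
                trials.append((tr.cycle, RawEMG(signals=signals, rate=rate, events=ev)))
            except (tio.DataError, ValueError) as exc:
                logger.warning(
                    "skipping EMG %s/%s cycle %d: %s",
                    sub.subject_id, sub.activity, tr.cycle, exc,
                )
        if trials:
            by_subject[(sub.subject_id, sub.group, sub.activity)] = trials
    for (sid, group, activity), trials in by_subject.items():
        normalized = process_trials(
            [t[1] for t in trials],
            highpass_hz=config.highpass_hz,
            lowpass_hz=config.lowpass_hz,
            order=config.filter_order,
            zero_phase=config.zero_phase,
        )
        for (cyc, _), norm in zip(trials, normalized):
            for p in range(norm.envelopes.shape[1]):
                rows.append(
                    {"subject": sid, "group": group, "activity": activity,
                     "cycle": cyc, "point": p,
                     **{m: norm.envelopes[i, p] for i, m in enumerate(MUSCLES)}}
                )
    pd.DataFrame(rows).to_csv(results_dir / "emg_envelopes.csv", index=False)
    logger.info("emg stage: %d envelope rows", len(rows))
    return results_dir / "emg_envelopes.csv"


# ---------------------------------------------------------------------------
# synergy stage
# ---------------------------------------------------------------------------

def _subject_matrix(df: pd.DataFrame) -> np.ndarray:
    """Stack a subject-activity's cycles into the 8 x (200 * cycles) matrix."""
    blocks = []
    for _, cyc_df in df.sort_values("point").groupby("cycle"):
        blocks.append(cyc_df[list(MUSCLES)].to_numpy().T)
    return np.hstack(blocks)


def stage_syn(config: tio.RunConfig, results_dir: str | Path, seed: int) -> Path:
    """NMF per subject-activity, group-imposed rank, k-means classification."""
    results_dir = Path(results_dir)
    _setup_run_log(results_dir)
    env = pd.read_csv(results_dir / "emg_envelopes.csv")
    rank_rows, class_rows = [], []
    synergy_json: dict = {}
    for activity, act_df in env.groupby("activity"):
        fits_by_subject: dict[str, dict[int, syn.SynergySet]] = {}
        ks_by_group: dict[str, list[int]] = {}
        group_of: dict[str, str] = {}
        for (sid, group), sub_df in act_df.groupby(["subject", "group"]):
            V = _subject_matrix(sub_df)
            sub_seed = seed + zlib.crc32(f"{activity}:{sid}".encode()) % 100_000
            k, fits = syn.rank_scan(
                V, seed=sub_seed, r2_threshold=config.r2_threshold,
                n_restarts=config.nmf_restarts, max_iter=config.nmf_max_iter,
                tol=config.nmf_tol,
            )
            fits_by_subject[sid] = fits
            group_of[sid] = group
            ks_by_group.setdefault(group, []).append(k)
            rank_rows.append(
                {"activity": activity, "group": group, "subject": sid,
                 "k": k, "r_squared": fits[k].r_squared}
            )
            synergy_json.setdefault(activity, {})[sid] = {
                "group": group, "k": k,
                "W": fits[k].modules, "H": fits[k].patterns,
                "r_squared": fits[k].r_squared,
            }
        k_imposed = syn.impose_group_rank(list(ks_by_group.values()))
        logger.info("activity %s: imposed rank %d (group means %s)", activity, k_imposed,
                    {g: float(np.mean(v)) for g, v in ks_by_group.items()})
        for group in sorted(set(group_of.values())):
            sets = {}
            for sid, fits in fits_by_subject.items():
                if group_of[sid] != group:
                    continue
                if k_imposed in fits:
                    sets[sid] = fits[k_imposed]
                else:
                    V = _subject_matrix(act_df[act_df.subject == sid])
                    sets[sid] = syn.nmf(
                        V, k_imposed, seed=seed, n_restarts=config.nmf_restarts,
                        max_iter=config.nmf_max_iter, tol=config.nmf_tol,
                    )
            cls = syn.classify(
                sets, k_imposed, seed=seed, n_restarts=config.kmeans_restarts
            )
            for e in cls.entries:
                class_rows.append(
                    {"activity": activity, "group": group, "subject": e.subject,
                     "synergy": e.index, "cluster": e.cluster, "label": e.label,
                     "classified": e.classified, "fwhm": e.fwhm, "coa": e.coa}
                )
            logger.info(
                "classify %s/%s: k=%d ratio=%.2f labels=%s",
                activity, group, k_imposed, cls.classifiable_ratio, cls.labels,
            )
    pd.DataFrame(rank_rows).to_csv(results_dir / "synergy_ranks.csv", index=False)
    pd.DataFrame(class_rows).to_csv(results_dir / "classification.tsv", sep="\t", index=False)
    tio.write_json(results_dir / "synergies.json", synergy_json)
    return results_dir / "classification.tsv"


# ---------------------------------------------------------------------------
# statistics stage
# ---------------------------------------------------------------------------

def _subject_means(rom: pd.DataFrame) -> pd.DataFrame:
    """Average RoM over cycles within subject (cycles are not treated as
    independent trials)."""
    return (
        rom.groupby(["activity", "group", "subject", "phase", "parameter"])["rom"]
        .mean()
        .reset_index()
    )


def stage_stats(config: tio.RunConfig, results_dir: str | Path, seed: int) -> Path:
    """Group comparisons: RoM t-tests, SPM over curves, FWHM/CoA t-tests, ANOVA."""
    results_dir = Path(results_dir)
    _setup_run_log(results_dir)
    report_rows, spm_rows = [], []

    rom = _subject_means(pd.read_csv(results_dir / "kin_rom.csv"))
    for activity, act_df in rom.groupby("activity"):
        comps = [(ph, pm) for ph in ("stance", "swing")
                 for pm in sorted(act_df.parameter.unique())]
        family = config.kinematic_family_size or len(comps)
        for phase, param in comps:
            sel = act_df[(act_df.phase == phase) & (act_df.parameter == param)]
            g1 = sel[sel.group == "stable"]["rom"].to_numpy()
            g2 = sel[sel.group == "unstable"]["rom"].to_numpy()
            if len(g1) < 2 or len(g2) < 2:
                continue
            try:
                res = st.t_test_pooled(g1, g2).adjust(family)
            except st.DegenerateVarianceError as exc:
                logger.warning("RoM %s/%s/%s: %s", activity, phase, param, exc)
                continue
            report_rows.append(
                {"comparison": f"rom:{activity}:{phase}:{param}", "activity": activity,
                 "metric": "rom", "item": f"{phase}:{param}",
                 "n_stable": len(g1), "n_unstable": len(g2),
                 "statistic": res.statistic, "p": res.p_value,
                 "p_adjusted": res.p_adjusted, "effect_size": res.effect_size}
            )

    curves = pd.read_csv(results_dir / "kin_cycles.csv")
    sub_curves = (
        curves.groupby(["activity", "group", "subject", "point"])[list(_KIN_PARAMS)]
        .mean()
        .reset_index()
    )
    for activity, act_df in sub_curves.groupby("activity"):
        for param in _KIN_PARAMS:
            mats = {}
            for group, g_df in act_df.groupby("group"):
                mats[group] = (
                    g_df.pivot(index="subject", columns="point", values=param)
                    .to_numpy()
                )
            if len(mats) < 2 or any(m.shape[0] < 2 for m in mats.values()):
                continue
            res = st.spm_ttest_1d(
                mats["stable"], mats["unstable"], alpha=config.alpha,
                n_perm=config.n_perm, seed=seed,
            )
            for cl in res.clusters:
                spm_rows.append(
                    {"activity": activity, "parameter": param,
                     "start_pct": cl.start, "end_pct": cl.end,
                     "max_t": cl.max_t, "p": cl.p_value}
                )

    cls_path = results_dir / "classification.tsv"
    cls = pd.read_csv(cls_path, sep="\t") if cls_path.exists() else pd.DataFrame()
    if len(cls):
        classified = cls[cls.classified]
        for activity, act_df in classified.groupby("activity"):
            labels = sorted(act_df.label.unique())
            for metric in ("fwhm", "coa"):
                family = config.timing_family_size or len(labels)
                for label in labels:
                    sel = act_df[act_df.label == label]
                    g1 = sel[sel.group == "stable"][metric].to_numpy()
                    g2 = sel[sel.group == "unstable"][metric].to_numpy()
                    if len(g1) < 2 or len(g2) < 2:
                        logger.warning(
                            "%s %s/%s: too few classified synergies (%d vs %d)",
                            metric, activity, label, len(g1), len(g2),
                        )
                        continue
                    try:
                        res = st.t_test_pooled(g1, g2).adjust(family)
                    except st.DegenerateVarianceError as exc:
                        logger.warning("%s %s/%s: %s", metric, activity, label, exc)
                        continue
                    report_rows.append(
                        {"comparison": f"{metric}:{activity}:{label}",
                         "activity": activity, "metric": metric, "item": label,
                         "n_stable": len(g1), "n_unstable": len(g2),
                         "statistic": res.statistic, "p": res.p_value,
                         "p_adjusted": res.p_adjusted, "effect_size": res.effect_size}
                    )

        # ANOVA on module weights for labels whose timing metrics differ
        syn_json = tio.read_json(results_dir / "synergies.json")
        sig = [r for r in report_rows
               if r["metric"] in ("fwhm", "coa") and (r["p_adjusted"] or 1) < config.alpha]
        for r in sig:
            activity, label = r["activity"], r["item"]
            act_cls = cls[(cls.activity == activity) & (cls.label == label) & cls.classified]
            for mi, muscle in enumerate(MUSCLES):
                groups = []
                for group in sd.GROUP_LABELS:
                    vals = []
                    for _, row in act_cls[act_cls.group == group].iterrows():
                        W = np.asarray(syn_json[activity][row.subject]["W"])
                        vals.append(W[mi, int(row.synergy)])
                    groups.append(np.asarray(vals))
                if any(len(g) < 2 for g in groups):
                    continue
                try:
                    res = st.anova_oneway(*groups)
                except st.DegenerateVarianceError:
                    continue
                report_rows.append(
                    {"comparison": f"anova_weight:{activity}:{label}:{muscle}",
                     "activity": activity, "metric": "anova_weight",
                     "item": f"{label}:{muscle}",
                     "n_stable": len(groups[0]), "n_unstable": len(groups[1]),
                     "statistic": res.statistic, "p": res.p_value,
                     "p_adjusted": None, "effect_size": None}
                )

    pd.DataFrame(report_rows).to_csv(results_dir / "stats_report.tsv", sep="\t", index=False)
    pd.DataFrame(
        spm_rows, columns=["activity", "parameter", "start_pct", "end_pct", "max_t", "p"]
    ).to_csv(results_dir / "spm_clusters.tsv", sep="\t", index=False)
    logger.info("stats stage: %d comparisons, %d SPM clusters", len(report_rows), len(spm_rows))
    return results_dir / "stats_report.tsv"


def stage_report(results_dir: str | Path) -> Path:
    """Collate the stage outputs into a human-readable summary."""
    results_dir = Path(results_dir)
    lines = ["# Pipeline summary", ""]
    ranks = results_dir / "synergy_ranks.csv"
    if ranks.exists():
        df = pd.read_csv(ranks)
        lines.append("## Synergy ranks (mean per group-activity)")
        lines.append(df.groupby(["activity", "group"])["k"].mean().to_string())
        lines.append("")
    cls = results_dir / "classification.tsv"
    if cls.exists():
        df = pd.read_csv(cls, sep="\t")
        ratio = df.groupby(["activity", "group"])["classified"].mean()
        lines.append("## Classifiable synergy ratio")
        lines.append(ratio.to_string())
        lines.append("")
    stats_path = results_dir / "stats_report.tsv"
    if stats_path.exists():
        df = pd.read_csv(stats_path, sep="\t")
        sig = df[(df.p_adjusted.notna()) & (df.p_adjusted < 0.05)]
        lines.append(f"## Significant comparisons (adjusted p < 0.05): {len(sig)}")
        if len(sig):
            lines.append(sig.to_string(index=False))
        lines.append("")
    out = results_dir / "summary.md"
    out.write_text("\n".join(lines) + "\n")
    return out


def run_pipeline(
    manifest_path: str | Path,
    config: tio.RunConfig,
    results_dir: str | Path,
    seed: int,
) -> Path:
    """Run kin -> emg -> syn -> stats -> report on an existing dataset."""
    results_dir = Path(results_dir)
    _setup_run_log(results_dir)
    manifest = tio.read_manifest(manifest_path)
    manifest.validate()
    config.save(results_dir / "config.json")
    logger.info(
        "pipeline start: %d subjects, seed %d, config %s",
        len(manifest.subjects), seed, _config_hash(config),
    )
    stage_kin(manifest, config, results_dir)
    stage_emg(manifest, config, results_dir)
    stage_syn(config, results_dir, seed)
    stage_stats(config, results_dir, seed)
    return stage_report(results_dir)
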