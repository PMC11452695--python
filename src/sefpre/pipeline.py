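"""End-to-end orchestration: session(s) -> structured analysis report.

Runs the full chain — windowed iISI metrics, two-stage factor
classification, PD determination and neuron typing, PD-referenced AUC
tracks with shuffle nulls, eye-bias summaries, hemifield-vs-eye
regressions and (when stimulation sessions are present) stimulation
statistics — and collects everything into one report keyed by neuron id.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (EyeSummary, RegressionResult, classify_shift_direction,
                       detect_divergence, hemifield_vs_eyeshift_anova,
                       population_regression_tests, preprocess_eye,
                       regress_activity_on_eye, stim_behavior_stats)
from .factors import (FactorLabelTrack, TrialFactors, classify_neuron,
                      population_fractions, summarize_epochs)
from .io_schema import Session, select_trials
from .spike_metrics import WindowGrid, spike_counts_matrix, windowed_iisi
from .synthetic import SyntheticConfig, generate_session
from .tuning import (AUCTrack, NeuronType, PDResult, auc_track_with_null,
                     classify_neuron_type, cohort_pd_uniformity,
                     determine_pd, pd_condition_labels, population_auc_test,
                     signed_count_binomial)

logger = logging.getLogger(__name__)

#: Default analysis grids (event, start, stop, width, step in seconds).
CUE_GRID = WindowGrid("cue_on", -0.2, 1.2, 0.010, 0.010)
TARGETS_GRID = WindowGrid("targets_on", -0.2, 0.75, 0.010, 0.010)
ROC_GRID = WindowGrid("cue_on", -0.2, 1.2, 0.100, 0.100)

#: Task epochs, event-relative on the matching grid.
PRESELECTION_EPOCH = (0.0, 1.2)      # cue grid: cue onset -> targets onset
DETERMINATION_EPOCH = (0.0, 0.75)    # targets grid: targets onset -> go


@dataclass
class AnalysisReport:
    """All stage outputs of one pipeline run, cross-linked by neuron id."""

    session_ids: list[str]
    tracks_cue: dict[str, FactorLabelTrack]
    tracks_targets: dict[str, FactorLabelTrack]
    epoch_summary: dict[str, dict]
    fractions_cue: dict[str, np.ndarray]
    fractions_targets: dict[str, np.ndarray]
    pds: dict[str, PDResult]
    types: dict[str, NeuronType]
    pd_uniformity_p: float | None
    auc_tracks: dict[str, AUCTrack]
    auc_population: dict | None
    count_binomial: dict | None
    eye_summaries: list[EyeSummary]
    eye_divergence_onset_s: float | None
    regressions: dict[str, RegressionResult]
    regression_population: dict | None
    eyeshift_anova: dict | None
    stim_summary: object | None
    provenance: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def run_full_analysis(sessions: Session | list[Session] | SyntheticConfig,
                      seed: int = 0, n_perm: int = 1000,
                      n_shuffle: int = 1000) -> AnalysisReport:
    """Run the complete analysis over one or more sessions.

    ``sessions`` may be a single Session, a list of Sessions (eye-bias
    divergence and stimulation statistics need several), or a
    SyntheticConfig to simulate first.  ``seed`` drives every stochastic
    analysis step (permutation and shuffle nulls).
    """
    if isinstance(sessions, SyntheticConfig):
        sessions = [generate_session(sessions)]
    if isinstance(sessions, Session):
        sessions = [sessions]
    if not sessions:
        raise ValueError("no session to analyze")
    warnings: list[str] = []

    recording = [s for s in sessions if not s.stimulation_session]
    stim_sessions = [s for s in sessions if s.stimulation_session]

    tracks_cue: dict[str, FactorLabelTrack] = {}
    tracks_targets: dict[str, FactorLabelTrack] = {}
    epoch_summary: dict[str, dict] = {}
    pds: dict[str, PDResult] = {}
    types: dict[str, NeuronType] = {}
    auc_tracks: dict[str, AUCTrack] = {}
    regressions: dict[str, RegressionResult] = {}
    eyeshift_instr: list[np.ndarray] = []
    eyeshift_eye: list[np.ndarray] = []

    eye_summaries: list[EyeSummary] = []
    for s in sessions:
        if s.eyes:
            try:
                eye_summaries.append(preprocess_eye(
                    s, stim=False if s.stimulation_session else None))
            except ValueError as exc:
                warnings.append(f"session {s.session_id}: eye summary "
                                f"skipped ({exc})")

    for s in recording:
        choice = select_trials(s, task="choice", regular_only=True)
        delayed = select_trials(s, task="delayed")
        factors = TrialFactors.from_trials(choice)
        shift_labels = None
        if s.eyes:
            summary = next((e for e in eye_summaries
                            if e.session_id == s.session_id), None)
            if summary is not None:
                shifts = classify_shift_direction(s, summary)
                shift_labels = [shifts.get(t.trial_id) for t in choice]

        for st in s.spikes:
            nid = st.neuron_id
            if choice:
                iisi_cue = windowed_iisi(st.spike_times_s, choice, CUE_GRID,
                                         nid)
                iisi_tgt = windowed_iisi(st.spike_times_s, choice,
                                         TARGETS_GRID, nid)
                tracks_cue[nid] = classify_neuron(iisi_cue, factors)
                tracks_targets[nid] = classify_neuron(iisi_tgt, factors)
                presel = summarize_epochs(tracks_cue[nid],
                                          {"preselection": PRESELECTION_EPOCH})
                deter = summarize_epochs(tracks_targets[nid],
                                         {"determination": DETERMINATION_EPOCH})
                epoch_summary[nid] = {**presel, **deter}
                if shift_labels is not None and None not in shift_labels:
                    res = hemifield_vs_eyeshift_anova(
                        iisi_cue.values, factors.hemifield, shift_labels)
                    eyeshift_instr.append(res["instruction_modulated"])
                    eyeshift_eye.append(res["eye_modulated"])
            if delayed:
                try:
                    pds[nid] = determine_pd(st.spike_times_s, delayed, nid)
                except ValueError as exc:
                    warnings.append(f"neuron {nid}: PD skipped ({exc})")
                completed = [t for t in delayed if t.t_saccade_on is not None]
                types[nid] = classify_neuron_type(st.spike_times_s, completed,
                                                  nid)
            if choice and pds.get(nid) is not None and pds[nid].has_pd:
                cond = pd_condition_labels(choice, pds[nid])
                counts = spike_counts_matrix(st.spike_times_s, choice,
                                             ROC_GRID)
                try:
                    auc_tracks[nid] = auc_track_with_null(
                        counts, cond, n_perm=n_perm,
                        seed=_derive_seed(seed, nid, 1), grid=ROC_GRID,
                        neuron_id=nid)
                except ValueError as exc:
                    warnings.append(f"neuron {nid}: AUC skipped ({exc})")
                if s.eyes:
                    eye_means = _eye_window_means(s, choice, ROC_GRID)
                    if eye_means is not None:
                        code = np.where(np.asarray(cond) == "pd_included",
                                        1.0, -1.0)
                        regressions[nid] = regress_activity_on_eye(
                            counts, code, eye_means, n_shuffle=n_shuffle,
                            seed=_derive_seed(seed, nid, 2), neuron_id=nid)

    if not pds and recording:
        warnings.append("no delayed-task trials: PD and typing sections empty")
        logger.warning("no delayed-task trials in any recording session")

    fractions_cue = (population_fractions(list(tracks_cue.values()))
                     if tracks_cue else {})
    fractions_targets = (population_fractions(list(tracks_targets.values()))
                         if tracks_targets else {})
    with_pd = [p for p in pds.values() if p.has_pd]
    pd_uniformity_p = (cohort_pd_uniformity(with_pd).p
                       if len(with_pd) >= 3 else None)
    auc_population = (population_auc_test(list(auc_tracks.values()))
                      if auc_tracks else None)

    count_binomial = None
    if auc_tracks:
        counts_list, cond_list = [], []
        for s in recording:
            choice = select_trials(s, task="choice", regular_only=True)
            for st in s.spikes:
                if st.neuron_id in auc_tracks:
                    counts_list.append(spike_counts_matrix(
                        st.spike_times_s, choice, ROC_GRID))
                    cond_list.append(np.asarray(
                        pd_condition_labels(choice, pds[st.neuron_id])))
        count_binomial = signed_count_binomial(counts_list, cond_list)

    regression_population = (population_regression_tests(
        list(regressions.values())) if regressions else None)

    eyeshift_anova = None
    if eyeshift_instr:
        eyeshift_anova = {
            "instruction_fraction": np.mean(eyeshift_instr, axis=0),
            "eye_fraction": np.mean(eyeshift_eye, axis=0),
            "n_neurons": len(eyeshift_instr)}

    divergence = None
    if len(eye_summaries) >= 3:
        divergence = detect_divergence(eye_summaries)

    stim_summary = None
    if len(stim_sessions) >= 2:
        stim_summary = stim_behavior_stats(sessions)

    return AnalysisReport(
        session_ids=[s.session_id for s in sessions],
        tracks_cue=tracks_cue, tracks_targets=tracks_targets,
        epoch_summary=epoch_summary, fractions_cue=fractions_cue,
        fractions_targets=fractions_targets, pds=pds, types=types,
        pd_uniformity_p=pd_uniformity_p, auc_tracks=auc_tracks,
        auc_population=auc_population, count_binomial=count_binomial,
        eye_summaries=eye_summaries, eye_divergence_onset_s=divergence,
        regressions=regressions, regression_population=regression_population,
        eyeshift_anova=eyeshift_anova, stim_summary=stim_summary,
        provenance={"seed": seed, "version": __version__,
                    "n_perm": n_perm, "n_shuffle": n_shuffle},
        warnings=warnings)


def _derive_seed(seed: int, neuron_id: str, tag: int) -> int:
    h = hashlib.sha256(f"{seed}:{neuron_id}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def _eye_window_means(session: Session, trials, grid: WindowGrid
                      ) -> np.ndarray | None:
    """Trial x window mean horizontal eye position on the count grid."""
    out = np.zeros((len(trials), grid.n_windows))
    for i, tr in enumerate(trials):
        trace = session.eye_by_trial(tr.trial_id)
        if trace is None:
            return None
        ev = grid.event_time(tr)
        rel = trace.t_s - ev
        for w, a in enumerate(grid.starts):
            sel = (rel >= a) & (rel < a + grid.width_s)
            out[i, w] = trace.x_deg[sel].mean() if sel.any() else 0.0
    return out


# ---------------------------------------------------------------------------
# Report serialization


def write_report(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Write the report as TSV tables plus a JSON summary; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if report.tracks_cue:
        rows = []
        for nid, track in sorted(report.tracks_cue.items()):
            for w, (raw, lab) in enumerate(zip(track.raw_labels, track.labels)):
                r = track.results[w]
                rows.append({
                    "neuron_id": nid, "window": w,
                    "t_start_s": round(float(track.grid.starts[w]), 6),
                    "raw_label": raw, "label": lab,
                    "p_object_L": r.p_object["L"], "p_object_R": r.p_object["R"],
                    "p_obj_angle_L": r.p_object_angle["L"],
                    "p_obj_angle_R": r.p_object_angle["R"],
                    "p_hemi": r.p_hemi, "p_angle": r.p_angle,
                    "p_interaction": r.p_int})
        p = out_dir / "tracks.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False,
                                  float_format="%.6g")
        written.append(p)

    if report.pds:
        p = out_dir / "pd.tsv"
        pd.DataFrame([{
            "neuron_id": nid, "has_pd": int(r.has_pd),
            "pd_direction": r.pd_direction or "", "anova_p": r.anova_p}
            for nid, r in sorted(report.pds.items())]
        ).to_csv(p, sep="\t", index=False, float_format="%.6g")
        written.append(p)

    if report.types:
        p = out_dir / "types.tsv"
        pd.DataFrame([{
            "neuron_id": nid, "type": r.type, "p_visual": r.p_visual,
            "p_movement": r.p_movement}
            for nid, r in sorted(report.types.items())]
        ).to_csv(p, sep="\t", index=False, float_format="%.6g")
        written.append(p)

    if report.auc_tracks:
        rows = []
        for nid, tr in sorted(report.auc_tracks.items()):
            for w in range(tr.auc.size):
                rows.append({"neuron_id": nid, "window": w,
                             "auc": tr.auc[w], "null_mean": tr.null_mean[w],
                             "null_q975": tr.null_q975[w]})
        p = out_dir / "auc.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False,
                                  float_format="%.6g")
        written.append(p)

    if report.eye_summaries:
        rows = []
        for es in report.eye_summaries:
            for t, l, r in zip(es.time_s, es.mean_left, es.mean_right):
                rows.append({"session_id": es.session_id,
                             "t_s": round(float(t), 6),
                             "mean_left": l, "mean_right": r})
        p = out_dir / "eye_summary.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False,
                                  float_format="%.6g")
        written.append(p)

    summary = summarize_report(report)
    p = out_dir / "report.json"
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(p)
    return written


def summarize_report(report: AnalysisReport) -> dict:
    """Headline numbers of a report as a JSON-serializable dict."""
    out: dict = {"sessions": report.session_ids,
                 "provenance": report.provenance,
                 "n_neurons": len(report.tracks_cue) or len(report.pds)}
    if report.epoch_summary:
        n = len(report.epoch_summary)
        presel = sum(e["preselection"]["potential_space"]
                     for e in report.epoch_summary.values())
        deter = sum(e["determination"]["target_position"]
                    for e in report.epoch_summary.values())
        both = sum(e["preselection"]["potential_space"]
                   and e["determination"]["target_position"]
                   for e in report.epoch_summary.values())
        out["fraction_potential_space_preselection"] = presel / n
        out["fraction_target_position_determination"] = deter / n
        out["fraction_both"] = both / n
    if report.pds:
        with_pd = [p for p in report.pds.values() if p.has_pd]
        out["fraction_with_pd"] = len(with_pd) / len(report.pds)
        out["pd_uniformity_p"] = report.pd_uniformity_p
    if report.types:
        for ty in ("visual", "visuomovement", "movement", "none"):
            out[f"n_type_{ty}"] = sum(t.type == ty
                                      for t in report.types.values())
    if report.auc_population is not None:
        out["n_significant_auc_windows"] = int(
            report.auc_population["significant"].sum())
    if report.eye_divergence_onset_s is not None:
        out["eye_divergence_onset_s"] = report.eye_divergence_onset_s
    if report.stim_summary is not None:
        out["stim_tests"] = {
            name: {"statistic": t.statistic, "p": t.p,
                   "effect": t.effect_size, "effect_name": t.effect_name}
            for name, t in report.stim_summary.tests.items()}
    if report.warnings:
        out["warnings"] = report.warnings
    return out
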