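"""Preferred-direction tuning and PD-referenced population contrasts.

Covers: PD determination from the delayed-saccade task (one-way ANOVA on
0-300 ms spike counts across the six target directions, alpha = 0.05,
unique argmax), visual/visuomovement/movement neuron typing (one-sided
signed-rank on fixed count windows), PD-included vs PD-opposite condition
labels for the choice task, sliding-window ROC/AUC with a label-shuffle
null and an across-neuron population test, count-based binomial tests,
direction x time tuning matrices with PD-referenced population alignment,
and a Rayleigh uniformity test on the cohort's PDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .io_schema import (DIRECTION_ANGLES, DIRECTIONS, TrialRecord,
                        direction_hemifield)
from .spike_metrics import WindowGrid, spike_count, spike_counts_matrix
from .stats import (StatTestResult, auc, auc_matrix, fdr_bh, one_way_anova,
                    rayleigh_uniformity, wilcoxon_one_sided)

logger = logging.getLogger(__name__)

#: Fixed count windows (s, event-relative) used for neuron typing.
VISUAL_WINDOW = (0.0, 0.300)        # after target onset
PRE_VISUAL_WINDOW = (-0.300, 0.0)   # before target onset
PERI_SACCADE_WINDOW = (-0.100, 0.050)
PRE_SACCADE_WINDOW = (-0.350, -0.200)

#: Count window for PD determination (s after target onset).
PD_WINDOW = (0.0, 0.300)
PD_ALPHA = 0.05

MIN_PERMUTATIONS = 100


@dataclass
class PDResult:
    """Preferred direction of one neuron (delayed-saccade task)."""

    neuron_id: str
    has_pd: bool
    pd_direction: str | None
    anova_p: float
    mean_counts: dict[str, float]


@dataclass
class NeuronType:
    """Functional type from visual- and saccade-related activity tests."""

    neuron_id: str
    type: str                    # visual | visuomovement | movement | none
    p_visual: float
    p_movement: float


@dataclass
class AUCTrack:
    """Per-window AUC of one neuron with its label-shuffle null."""

    neuron_id: str
    grid: WindowGrid
    auc: np.ndarray
    null_mean: np.ndarray
    null_q025: np.ndarray
    null_q975: np.ndarray
    n_included: int
    n_opposite: int
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))


# ---------------------------------------------------------------------------
# Preferred direction


def determine_pd(spike_times: np.ndarray, delayed_trials: list[TrialRecord],
                 neuron_id: str = "") -> PDResult:
    """PD from 0-300 ms post-target spike counts across the six directions.

    ``has_pd`` requires a significant one-way ANOVA (alpha = 0.05) across
    directions *and* a unique argmax of the per-direction mean counts; a
    tied maximum yields no PD.
    """
    counts: dict[str, list[int]] = {d: [] for d in DIRECTIONS}
    for tr in delayed_trials:
        counts[tr.target_direction].append(
            spike_count(spike_times, tr, PD_WINDOW, "targets_on"))
    for d, c in counts.items():
        if len(c) < 2:
            raise ValueError(f"direction {d} has fewer than 2 trials")
    groups = [np.asarray(counts[d], dtype=float) for d in DIRECTIONS]
    if all(np.ptp(g) == 0 for g in groups) and \
            np.ptp([g.mean() for g in groups]) == 0:
        res = StatTestResult("one-way ANOVA", np.nan, None, 1.0)
    else:
        res = one_way_anova(groups)
    means = {d: float(np.mean(counts[d])) for d in DIRECTIONS}
    vals = np.array([means[d] for d in DIRECTIONS])
    top = np.flatnonzero(vals == vals.max())
    unique_max = top.size == 1
    has_pd = bool(res.p <= PD_ALPHA and unique_max)
    return PDResult(neuron_id=neuron_id, has_pd=has_pd,
                    pd_direction=DIRECTIONS[top[0]] if has_pd else None,
                    anova_p=float(res.p), mean_counts=means)


def classify_neuron_type(spike_times: np.ndarray,
                         delayed_trials: list[TrialRecord],
                         neuron_id: str = "") -> NeuronType:
    """Visual / visuomovement / movement / none typing.

    Visual-related activity: more spikes 0-300 ms after than 300-0 ms
    before target onset (one-sided Wilcoxon signed-rank, alpha = 0.05).
    Saccade-related: more spikes -100..50 ms around than -350..-200 ms
    before saccade onset.
    """
    vis_post, vis_pre, mov_peri, mov_pre = [], [], [], []
    for tr in delayed_trials:
        vis_post.append(spike_count(spike_times, tr, VISUAL_WINDOW,
                                    "targets_on"))
        vis_pre.append(spike_count(spike_times, tr, PRE_VISUAL_WINDOW,
                                   "targets_on"))
        if tr.t_saccade_on is not None:
            mov_peri.append(spike_count(spike_times, tr, PERI_SACCADE_WINDOW,
                                        "saccade_on") / 0.150)
            mov_pre.append(spike_count(spike_times, tr, PRE_SACCADE_WINDOW,
                                       "saccade_on") / 0.150)
    p_vis = wilcoxon_one_sided(vis_post, vis_pre)
    p_mov = wilcoxon_one_sided(mov_peri, mov_pre) if mov_peri else 1.0
    vis_sig, mov_sig = p_vis <= 0.05, p_mov <= 0.05
    if vis_sig and mov_sig:
        ntype = "visuomovement"
    elif vis_sig:
        ntype = "visual"
    elif mov_sig:
        ntype = "movement"
    else:
        ntype = "none"
    return NeuronType(neuron_id=neuron_id, type=ntype,
                      p_visual=float(p_vis), p_movement=float(p_mov))


def pd_condition_labels(trials: list[TrialRecord], pd: PDResult) -> list[str]:
    """Per-trial 'pd_included' / 'pd_opposite' labels for the choice task
    (equivalently 'pd' / 'anti_pd' by target hemifield for delayed trials).
    """
    if not pd.has_pd:
        raise ValueError(f"neuron {pd.neuron_id} has no PD")
    pd_side = direction_hemifield(pd.pd_direction)
    labels = []
    for tr in trials:
        side = (tr.instructed_hemifield if tr.task == "choice"
                else direction_hemifield(tr.target_direction))
        labels.append("pd_included" if side == pd_side else "pd_opposite")
    return labels


# ---------------------------------------------------------------------------
# ROC / AUC tracks


def auc_track_with_null(counts: np.ndarray, condition: list[str] | np.ndarray,
                        n_perm: int = 1000, seed: int = 0,
                        grid: WindowGrid | None = None,
                        neuron_id: str = "") -> AUCTrack:
    """Per-window AUC (PD-included vs PD-opposite) with a shuffle null.

    ``counts`` is the trial x window spike-count matrix; the null is
    built by permuting the correspondence between trials and condition
    labels ``n_perm`` times (minimum 100 enforced).
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm must be >= {MIN_PERMUTATIONS}")
    counts = np.asarray(counts, dtype=float)
    cond = np.asarray(condition)
    mask = cond == "pd_included"
    n_inc, n_opp = int(mask.sum()), int((~mask).sum())
    if min(n_inc, n_opp) < 5:
        raise ValueError("need at least 5 trials per condition")
    observed = auc_matrix(counts, mask)
    degenerate = np.ptp(counts, axis=0) == 0

    rng = np.random.default_rng(seed)
    ranks = sps.rankdata(counts, axis=0)
    null = np.empty((n_perm, counts.shape[1]))
    offset = n_inc * (n_inc + 1) / 2
    denom = n_inc * n_opp
    for k in range(n_perm):
        perm = rng.permutation(mask)
        null[k] = (ranks[perm].sum(axis=0) - offset) / denom
    return AUCTrack(neuron_id=neuron_id,
                    grid=grid if grid is not None
                    else WindowGrid("cue_on", 0.0, 0.1 * counts.shape[1], 0.1, 0.1),
                    auc=observed,
                    null_mean=null.mean(axis=0),
                    null_q025=np.quantile(null, 0.025, axis=0),
                    null_q975=np.quantile(null, 0.975, axis=0),
                    n_included=n_inc, n_opposite=n_opp,
                    degenerate=degenerate)


def population_auc_test(tracks: list[AUCTrack], alpha: float = 0.05,
                        method: str = "wilcoxon") -> dict:
    """Across-neuron test of observed AUC vs shuffle-null mean per window.

    ``method`` is 'wilcoxon' (signed-rank, default) or 'ttest' (paired t);
    Benjamini-Hochberg correction across windows at ``alpha``.
    """
    obs = np.array([t.auc for t in tracks])
    nul = np.array([t.null_mean for t in tracks])
    n_win = obs.shape[1]
    pvals = np.ones(n_win)
    for w in range(n_win):
        if method == "wilcoxon":
            pvals[w] = wilcoxon_one_sided(obs[:, w], nul[:, w])
        elif method == "ttest":
            d = obs[:, w] - nul[:, w]
            if np.all(d == 0):
                pvals[w] = 1.0
            else:
                pvals[w] = float(sps.ttest_rel(obs[:, w], nul[:, w],
                                               alternative="greater").pvalue)
        else:
            raise ValueError(f"unknown method {method!r}")
    flags = fdr_bh(pvals, alpha)
    return {"mean_auc": obs.mean(axis=0), "mean_null": nul.mean(axis=0),
            "p": pvals, "significant": flags}


def signed_count_binomial(counts_per_neuron: list[np.ndarray],
                          conditions_per_neuron: list[np.ndarray],
                          alpha: float = 0.05) -> dict:
    """Window-wise counts of neurons preferring each condition + binomial test.

    For each neuron and window a two-sample t-test (alpha = 0.05) compares
    PD-included vs PD-opposite counts; per window, the numbers of neurons
    significantly preferring each condition are compared with an exact
    two-sided binomial test against 1/2, Benjamini-Hochberg corrected
    across windows.
    """
    n_win = counts_per_neuron[0].shape[1]
    n_greater_inc = np.zeros(n_win, dtype=int)
    n_greater_opp = np.zeros(n_win, dtype=int)
    for counts, cond in zip(counts_per_neuron, conditions_per_neuron):
        cond = np.asarray(cond)
        inc = counts[cond == "pd_included"]
        opp = counts[cond == "pd_opposite"]
        with np.errstate(invalid="ignore", divide="ignore"):
            res = sps.ttest_ind(inc, opp, axis=0)
        p = np.nan_to_num(res.pvalue, nan=1.0)
        sig = p <= alpha
        diff = inc.mean(axis=0) - opp.mean(axis=0)
        n_greater_inc += sig & (diff > 0)
        n_greater_opp += sig & (diff < 0)
    pvals = np.array([
        sps.binomtest(int(k), int(n), 0.5).pvalue if n > 0 else 1.0
        for k, n in zip(n_greater_inc, n_greater_inc + n_greater_opp)])
    return {"n_greater_included": n_greater_inc,
            "n_greater_opposite": n_greater_opp,
            "p": pvals, "significant": fdr_bh(pvals, alpha)}


# ---------------------------------------------------------------------------
# Tuning matrices


def tuning_matrix(spike_times: np.ndarray, trials: list[TrialRecord],
                  grid: WindowGrid) -> np.ndarray:
    """6 x T direction-by-time mean firing-rate matrix (Hz).

    Rows follow :data:`~sefpre.io_schema.DIRECTIONS`; a direction with no
    trials yields a NaN row.
    """
    rates = spike_counts_matrix(spike_times, trials, grid) / grid.width_s
    dirs = np.array([tr.target_direction for tr in trials], dtype=object)
    out = np.full((6, grid.n_windows), np.nan)
    for i, d in enumerate(DIRECTIONS):
        sel = dirs == d
        if sel.any():
            out[i] = rates[sel].mean(axis=0)
    return out


#: 8-direction circular grid used for the PD-aligned population matrix.
EIGHT_DIRECTIONS = ("LD", "L", "LU", "Up", "RU", "R", "RD", "Down")


def align_tuning_population(matrices: list[np.ndarray], pds: list[PDResult],
                            split_window: int) -> dict:
    """PD-referenced population tuning matrix.

    Before ``split_window`` (the first window at/after choice-target
    onset) each neuron's six rows are reordered so the three directions of
    the PD-included hemifield come first; from ``split_window`` on, rows
    are placed on the 8-point circular grid (45-degree spacing) rotated so
    the PD sits at 0 degrees, with the unsampled Up and Down slots filled
    by linear interpolation of their neighbors.  Returns the means across
    neurons.  Neurons without a PD are excluded with a log message.
    """
    pre_rows, post_rows = [], []
    left_order = ["LU", "L", "LD"]
    right_order = ["RU", "R", "RD"]
    angle_of = dict(DIRECTION_ANGLES)
    eight_angles = {"LD": 225, "L": 180, "LU": 135, "Up": 90,
                    "RU": 45, "R": 0, "RD": 315, "Down": 270}
    for mat, pd_res in zip(matrices, pds):
        if not pd_res.has_pd:
            logger.info("neuron %s lacks a PD; excluded from alignment",
                        pd_res.neuron_id)
            continue
        row_of = {d: mat[i] for i, d in enumerate(DIRECTIONS)}
        pd_side = direction_hemifield(pd_res.pd_direction)
        included = left_order if pd_side == "L" else right_order
        opposite = right_order if pd_side == "L" else left_order
        pre_rows.append(np.array([row_of[d][:split_window]
                                  for d in included + opposite]))

        pd_angle = angle_of[pd_res.pd_direction]
        post = np.full((8, mat.shape[1] - split_window), np.nan)
        for d in DIRECTIONS:
            rel = (angle_of[d] - pd_angle) % 360
            slot = int(round(rel / 45.0)) % 8
            post[slot] = row_of[d][split_window:]
        for slot in range(8):
            if np.isnan(post[slot]).all():
                post[slot] = (post[(slot - 1) % 8] + post[(slot + 1) % 8]) / 2
        post_rows.append(post)
    if not pre_rows:
        raise ValueError("no neuron with a PD to align")
    return {"pre": np.mean(pre_rows, axis=0),
            "post": np.mean(post_rows, axis=0),
            "pre_row_labels": ["included_1", "included_2", "included_3",
                               "opposite_1", "opposite_2", "opposite_3"],
            "post_row_angles": [0, 45, 90, 135, 180, 225, 270, 315],
            "n_neurons": len(pre_rows)}


def cohort_pd_uniformity(pds: list[PDResult]) -> StatTestResult:
    """Rayleigh test on the polar angles of the cohort's PDs."""
    angles = [DIRECTION_ANGLES[p.pd_direction] for p in pds if p.has_pd]
    return rayleigh_uniformity(angles)
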