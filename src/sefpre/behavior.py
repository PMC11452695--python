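"""Eye-position bias analysis and stimulation-experiment statistics.

Eye preprocessing follows the task's fixational-bias logic: per-trial
baseline subtraction (0.5 s before symbolic-cue onset), cue-aligned
condition means for left- vs right-instructed trials, grand-mean
normalization, divergence-onset detection across sessions (pointwise
paired t at alpha = 0.01 sustained for a configurable duration), and
per-trial shift classification at the session's maximal-difference
timepoint.  The module also disentangles hemifield coding from eye
position in neural activity (single vs multiple regression with shuffle
nulls) and computes the stimulation-experiment behavioral statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .io_schema import EyeTrace, Session, TrialRecord, select_trials
from .stats import (StatTestResult, cohen_d_independent, cohen_d_paired,
                    fdr_bh, two_way_anova_matrix, wilcoxon_one_sided)

logger = logging.getLogger(__name__)

BASELINE_S = 0.5                 # pre-cue baseline window
DIVERGENCE_ALPHA = 0.01
DIVERGENCE_MIN_DURATION_S = 0.020  # Results convention; 0.010 also reported
EYE_SAMPLE_RATE = 240.0
STIM_EYE_WINDOW = (0.35, 0.45)   # post-cue window for the stimulation ANOVA


@dataclass
class EyeSummary:
    """Cue-aligned, baseline-subtracted eye-position summary of a session."""

    session_id: str
    time_s: np.ndarray              # relative to cue onset
    mean_left: np.ndarray           # condition means, grand-mean normalized
    mean_right: np.ndarray
    max_diff_time_s: float
    shift_direction: dict[int, str]  # per-trial 'L' / 'R'
    n_left: int = 0
    n_right: int = 0


@dataclass
class RegressionResult:
    """Windowed single- and two-regressor coefficients with shuffle nulls."""

    neuron_id: str
    beta_hemi: np.ndarray            # standardized, single regression
    beta_hemi_eye: np.ndarray        # hemifield coefficient, two-regressor
    beta_eye: np.ndarray
    resid_var: np.ndarray
    null_beta_hemi_mean: np.ndarray
    null_beta_hemi_q975: np.ndarray
    null_beta_hemi_eye_mean: np.ndarray
    null_beta_hemi_eye_q975: np.ndarray
    unstable: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))


@dataclass
class StimBehaviorSummary:
    """Behavioral effects of preselection-period electrical stimulation."""

    session_rates_stim: np.ndarray       # per stimulation session
    session_rates_nonstim: np.ndarray    # per control session
    ipsi_rate_stim: np.ndarray           # within stimulation sessions
    ipsi_rate_nonstim: np.ndarray
    contra_rate_stim: np.ndarray
    contra_rate_nonstim: np.ndarray
    tests: dict[str, StatTestResult]


# ---------------------------------------------------------------------------
# Eye preprocessing


def _trial_eye_grid(trace: EyeTrace, t_cue: float, t_stop: float,
                    ) -> tuple[np.ndarray, np.ndarray] | None:
    """Cue-aligned horizontal samples on [-BASELINE_S, t_stop - t_cue]."""
    rel = trace.t_s - t_cue
    lo, hi = -BASELINE_S, t_stop - t_cue
    if rel[0] > lo + 1e-9 or rel[-1] < hi - 1e-9:
        return None
    grid = np.arange(lo, hi, 1.0 / trace.sample_rate_hz)
    return grid, np.interp(grid, rel, trace.x_deg)


def preprocess_eye(session: Session, stim: bool | None = False) -> EyeSummary:
    """Baseline-subtract, average per condition and grand-mean normalize.

    Uses success choice trials; traces shorter than the baseline window
    are dropped with a log message.  The summary also records the
    maximal-difference timepoint and per-trial shift directions (see
    :func:`classify_shift_direction`).
    """
    trials = select_trials(session, task="choice", outcome="success",
                           stim=stim)
    if not trials:
        raise ValueError("no choice success trials with eye data")
    per_trial: dict[int, np.ndarray] = {}
    hemis: dict[int, str] = {}
    grid = None
    for tr in trials:
        trace = session.eye_by_trial(tr.trial_id)
        if trace is None:
            continue
        t_stop = tr.t_targets_on
        got = _trial_eye_grid(trace, tr.t_cue_on, t_stop)
        if got is None:
            logger.info("trial %d: eye trace too short; dropped", tr.trial_id)
            continue
        g, x = got
        if grid is None or g.size < grid.size:
            grid = g
        baseline = x[g < 0.0].mean()
        per_trial[tr.trial_id] = x - baseline
        hemis[tr.trial_id] = tr.instructed_hemifield
    if grid is None:
        raise ValueError("no usable eye traces in session")
    n = grid.size
    xs = {tid: x[:n] for tid, x in per_trial.items()}
    left = np.array([x for tid, x in xs.items() if hemis[tid] == "L"])
    right = np.array([x for tid, x in xs.items() if hemis[tid] == "R"])
    if left.size == 0 or right.size == 0:
        raise ValueError("need both left- and right-instructed trials")
    mean_l = left.mean(axis=0)
    mean_r = right.mean(axis=0)
    grand = (mean_l + mean_r) / 2
    mean_l, mean_r = mean_l - grand, mean_r - grand

    presel = grid >= 0.0
    diff = mean_r - mean_l
    w = int(np.flatnonzero(presel)[np.argmax(diff[presel])])
    max_diff_time = float(grid[w])

    shift = {tid: ("R" if _signed(xs[tid], w) > 0 else "L")
             for tid in xs}
    return EyeSummary(session_id=session.session_id, time_s=grid,
                      mean_left=mean_l, mean_right=mean_r,
                      max_diff_time_s=max_diff_time, shift_direction=shift,
                      n_left=left.shape[0], n_right=right.shape[0])


def _signed(x: np.ndarray, w: int) -> float:
    """Value at sample w; exact zeros fall through to the next sample."""
    v = x[w]
    k = w
    while v == 0.0 and k + 1 < x.size:
        k += 1
        v = x[k]
    return v if v != 0.0 else 1.0   # deterministic tie rule, logged once


def classify_shift_direction(session: Session,
                             summary: EyeSummary | None = None
                             ) -> dict[int, str]:
    """Per-trial left/right eye-shift labels at the max-difference timepoint."""
    if summary is None:
        summary = preprocess_eye(session)
    return dict(summary.shift_direction)


def detect_divergence(summaries: list[EyeSummary],
                      alpha: float = DIVERGENCE_ALPHA,
                      min_duration_s: float = DIVERGENCE_MIN_DURATION_S
                      ) -> float | None:
    """Onset of the instructed-side eye-position divergence across sessions.

    Pointwise paired t-test (right vs left condition means across
    sessions); the onset is the start of the first run of significant
    timepoints lasting at least ``min_duration_s``.  Returns None when no
    such run exists.
    """
    if len(summaries) < 3:
        raise ValueError("divergence detection needs >= 3 sessions")
    n = min(s.time_s.size for s in summaries)
    t_axis = summaries[0].time_s[:n]
    L = np.array([s.mean_left[:n] for s in summaries])
    R = np.array([s.mean_right[:n] for s in summaries])
    res = sps.ttest_rel(R, L, axis=0)
    sig = (np.nan_to_num(res.pvalue, nan=1.0) <= alpha) & (t_axis >= 0.0)
    dt = float(np.median(np.diff(t_axis)))
    need = max(int(np.ceil(min_duration_s / dt)), 1)
    run = 0
    for i, s in enumerate(sig):
        run = run + 1 if s else 0
        if run >= need:
            return float(t_axis[i - need + 1])
    return None


# ---------------------------------------------------------------------------
# Hemifield vs eye-shift ANOVA on neural activity


def hemifield_vs_eyeshift_anova(iisi_values: np.ndarray,
                                hemifield: list[str], shift: list[str],
                                alpha: float = 0.01, min_run: int = 3) -> dict:
    """Two-way ANOVA (instructed hemifield x eye-shift direction) per window.

    A window is *instruction-modulated* when the hemifield main effect is
    significant (p < alpha) in a run of at least ``min_run`` consecutive
    windows, and *eye-modulated* when the shift main effect or the
    interaction is.  Windows with an empty design cell are skipped (NaN).
    """
    res = two_way_anova_matrix(np.asarray(iisi_values, float),
                               np.asarray(hemifield, object),
                               np.asarray(shift, object))
    p_hemi, p_shift, p_int = res["p_a"], res["p_b"], res["p_int"]
    hemi_sig = _run_filter(np.nan_to_num(p_hemi, nan=1.0) < alpha, min_run)
    eye_raw = (np.nan_to_num(p_shift, nan=1.0) < alpha) | \
              (np.nan_to_num(p_int, nan=1.0) < alpha)
    eye_sig = _run_filter(eye_raw, min_run)
    return {"p_hemi": p_hemi, "p_shift": p_shift, "p_int": p_int,
            "instruction_modulated": hemi_sig, "eye_modulated": eye_sig}


def _run_filter(flags: np.ndarray, min_run: int) -> np.ndarray:
    out = np.zeros_like(flags)
    n = flags.size
    i = 0
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            if j - i >= min_run:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# Regression: hemifield condition vs eye position


def regress_activity_on_eye(counts: np.ndarray, condition_code: np.ndarray,
                            eye_position: np.ndarray, n_shuffle: int = 1000,
                            seed: int = 0, neuron_id: str = "",
                            ) -> RegressionResult:
    """Single vs two-regressor OLS of windowed spike counts, with nulls.

    ``condition_code`` is +1 for PD-included and -1 for PD-opposite
    trials; ``eye_position`` is the mean horizontal eye position in the
    same window as each count.  All variables are z-scored per window so
    the single-regression coefficient is the correlation with the
    condition and the two-regressor coefficients are standardized partial
    regression weights.  The null permutes the correspondence between
    activity and the regressors ``n_shuffle`` times.
    """
    counts = np.asarray(counts, dtype=float)
    code = np.asarray(condition_code, dtype=float)
    eye = np.asarray(eye_position, dtype=float)
    n, n_win = counts.shape
    if n < 10:
        raise ValueError("need at least 10 trials")
    if np.ptp(code) == 0:
        raise ValueError("condition regressor is constant")

    def zscore(x, axis=0):
        sd = x.std(axis=axis, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        return (x - x.mean(axis=axis)) / sd

    zc = zscore(code)
    ze = zscore(eye) if eye.ndim == 1 else zscore(eye, axis=0)
    zy = zscore(counts, axis=0)

    def betas(y):
        """Standardized single and two-regressor coefficients per window."""
        if ze.ndim == 1:
            ze_w = np.broadcast_to(ze[:, None], y.shape)
        else:
            ze_w = ze
        r_yc = (y * zc[:, None]).mean(axis=0)
        r_ye = (y * ze_w).mean(axis=0)
        r_ce = (zc[:, None] * ze_w).mean(axis=0)
        denom = 1.0 - r_ce ** 2
        unstable = np.abs(r_ce) > 0.999
        denom = np.where(unstable, np.nan, denom)
        b_hemi_eye = (r_yc - r_ye * r_ce) / denom
        b_eye = (r_ye - r_yc * r_ce) / denom
        return r_yc, b_hemi_eye, b_eye, unstable

    b_hemi, b_hemi_eye, b_eye, unstable = betas(zy)
    resid = zy - b_hemi_eye * zc[:, None] - b_eye * (
        ze[:, None] if ze.ndim == 1 else ze)
    resid_var = resid.var(axis=0)

    rng = np.random.default_rng(seed)
    null_h = np.empty((n_shuffle, n_win))
    null_he = np.empty((n_shuffle, n_win))
    for k in range(n_shuffle):
        perm = rng.permutation(n)
        bh, bhe, _, _ = betas(zy[perm])
        null_h[k], null_he[k] = bh, bhe
    return RegressionResult(
        neuron_id=neuron_id, beta_hemi=b_hemi, beta_hemi_eye=b_hemi_eye,
        beta_eye=b_eye, resid_var=resid_var,
        null_beta_hemi_mean=null_h.mean(axis=0),
        null_beta_hemi_q975=np.quantile(null_h, 0.975, axis=0),
        null_beta_hemi_eye_mean=null_he.mean(axis=0),
        null_beta_hemi_eye_q975=np.quantile(null_he, 0.975, axis=0),
        unstable=unstable)


def population_regression_tests(results: list[RegressionResult],
                                alpha: float = 0.05) -> dict:
    """Across-neuron comparisons of the regression coefficients per window.

    beta_hemi vs beta_hemi,eye with a paired t-test (the direct
    disentanglement contrast) and each coefficient against its shuffle
    null with a one-sided signed-rank test; Benjamini-Hochberg across
    windows.
    """
    bh = np.array([r.beta_hemi for r in results])
    bhe = np.array([r.beta_hemi_eye for r in results])
    nh = np.array([r.null_beta_hemi_mean for r in results])
    nhe = np.array([r.null_beta_hemi_eye_mean for r in results])
    n_win = bh.shape[1]
    p_pair = np.ones(n_win)
    p_h_null = np.ones(n_win)
    p_he_null = np.ones(n_win)
    for w in range(n_win):
        d = bh[:, w] - bhe[:, w]
        if np.any(d != 0):
            p_pair[w] = float(sps.ttest_rel(bh[:, w], bhe[:, w]).pvalue)
        p_h_null[w] = wilcoxon_one_sided(bh[:, w], nh[:, w])
        p_he_null[w] = wilcoxon_one_sided(bhe[:, w], nhe[:, w])
    return {
        "mean_beta_hemi": bh.mean(axis=0),
        "mean_beta_hemi_eye": bhe.mean(axis=0),
        "p_paired": p_pair, "paired_significant": fdr_bh(p_pair, alpha),
        "p_hemi_vs_null": p_h_null,
        "hemi_vs_null_significant": fdr_bh(p_h_null, alpha),
        "p_hemi_eye_vs_null": p_he_null,
        "hemi_eye_vs_null_significant": fdr_bh(p_he_null, alpha),
    }


# ---------------------------------------------------------------------------
# Stimulation statistics


def _correct_rate(trials: list[TrialRecord]) -> float:
    done = [t for t in trials if t.outcome in ("success", "wrong_choice")]
    if not done:
        return np.nan
    return sum(t.outcome == "success" for t in done) / len(done)


def _eye_window_mean(session: Session, trials: list[TrialRecord],
                     window: tuple[float, float]) -> float:
    vals = []
    for tr in trials:
        trace = session.eye_by_trial(tr.trial_id)
        if trace is None:
            continue
        rel = trace.t_s - tr.t_cue_on
        base = trace.x_deg[(rel >= -BASELINE_S) & (rel < 0)].mean()
        sel = (rel >= window[0]) & (rel < window[1])
        if sel.any():
            vals.append(trace.x_deg[sel].mean() - base)
    return float(np.mean(vals)) if vals else np.nan


def stim_behavior_stats(sessions: list[Session],
                        eye_window: tuple[float, float] = STIM_EYE_WINDOW,
                        ) -> StimBehaviorSummary:
    """Behavioral statistics of the electrical-stimulation experiment.

    (i) session-level correct rate, stimulation vs control sessions
    (two-sample t, pooled-SD Cohen's d); (ii) within stimulation
    sessions, paired stim vs non-stim correct rates separately for
    ipsilateral and contralateral trials (paired t, d = mean/SD of
    differences); (iii) two-way ANOVA (stimulation x trial type) on the
    baseline-subtracted horizontal eye position averaged over
    ``eye_window`` after cue onset, with eta-squared effect sizes.
    """
    stim_sessions = [s for s in sessions if s.stimulation_session]
    ctrl_sessions = [s for s in sessions if not s.stimulation_session]
    if len(stim_sessions) < 2:
        raise ValueError("need >= 2 stimulation sessions")

    def rate(s, **kw):
        return _correct_rate(select_trials(s, task="choice", outcome=None, **kw))

    sess_stim = np.array([rate(s) for s in stim_sessions])
    sess_ctrl = np.array([rate(s) for s in ctrl_sessions])

    ipsi, contra = {}, {}
    eye_cells: dict[tuple[bool, str], list[float]] = {
        (st, ty): [] for st in (False, True) for ty in ("ipsi", "contra")}
    for s in stim_sessions:
        ipsi_side = "L" if s.hemisphere == "L" else "R"
        contra_side = "R" if ipsi_side == "L" else "L"
        for st in (False, True):
            ipsi.setdefault(st, []).append(
                rate(s, stim=st, hemifield=ipsi_side))
            contra.setdefault(st, []).append(
                rate(s, stim=st, hemifield=contra_side))
            for ty, side in (("ipsi", ipsi_side), ("contra", contra_side)):
                trials = select_trials(s, task="choice", outcome="success",
                                       stim=st, hemifield=side)
                if not trials:
                    logger.info("session %s: empty cell stim=%s side=%s",
                                s.session_id, st, side)
                    continue
                eye_cells[(st, ty)].append(
                    _eye_window_mean(s, trials, eye_window))

    tests: dict[str, StatTestResult] = {}
    if len(ctrl_sessions) >= 2:
        t, p = sps.ttest_ind(sess_ctrl, sess_stim)
        tests["session_correct_rate"] = StatTestResult(
            "two-sample t", float(t), len(sess_ctrl) + len(sess_stim) - 2,
            float(p), cohen_d_independent(sess_ctrl, sess_stim), "cohen_d")
    for name, cells in (("ipsi", ipsi), ("contra", contra)):
        non, st = np.array(cells[False]), np.array(cells[True])
        ok = ~(np.isnan(non) | np.isnan(st))
        non, st = non[ok], st[ok]
        if non.size >= 2:
            t, p = sps.ttest_rel(non, st)
            tests[f"{name}_stim_vs_nonstim"] = StatTestResult(
                "paired t", float(t), non.size - 1, float(p),
                cohen_d_paired(non - st), "cohen_d")

    y, f_stim, f_type = [], [], []
    for (st, ty), vals in eye_cells.items():
        for v in vals:
            if not np.isnan(v):
                y.append(v)
                f_stim.append("stim" if st else "nonstim")
                f_type.append(ty)
    if len(set(f_stim)) == 2 and len(set(f_type)) == 2:
        res = two_way_anova_matrix(np.array(y)[:, None],
                                   np.array(f_stim, object),
                                   np.array(f_type, object))
        ss_a, ss_b, ss_int, ss_err = (x[0] for x in res["ss"])
        ss_tot = ss_a + ss_b + ss_int + ss_err
        dfa, dfb, dfi, dfe = res["df"]
        tests["eye_stim_effect"] = StatTestResult(
            "two-way ANOVA F", float(res["F_a"][0]), (dfa, dfe),
            float(res["p_a"][0]),
            float(ss_a / ss_tot) if ss_tot > 0 else 0.0, "eta_squared")
        tests["eye_trialtype_effect"] = StatTestResult(
            "two-way ANOVA F", float(res["F_b"][0]), (dfb, dfe),
            float(res["p_b"][0]),
            float(ss_b / ss_tot) if ss_tot > 0 else 0.0, "eta_squared")

    return StimBehaviorSummary(
        session_rates_stim=sess_stim, session_rates_nonstim=sess_ctrl,
        ipsi_rate_stim=np.array(ipsi.get(True, [])),
        ipsi_rate_nonstim=np.array(ipsi.get(False, [])),
        contra_rate_stim=np.array(contra.get(True, [])),
        contra_rate_nonstim=np.array(contra.get(False, [])),
        tests=tests)
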