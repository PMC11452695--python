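"""Eye preprocessing, shift classification, regression disentanglement,
stimulation statistics."""

import numpy as np
import pytest

from sefpre.behavior import (EyeSummary, classify_shift_direction,
                             detect_divergence, hemifield_vs_eyeshift_anova,
                             population_regression_tests, preprocess_eye,
                             regress_activity_on_eye, stim_behavior_stats)
from sefpre.io_schema import EyeTrace, Session
from sefpre.synthetic import EyeModelSpec, SyntheticConfig, generate_session
from tests.conftest import make_choice_trial


def _session_with_traces(offset=0.0, n=8):
    """Four L- and four R-instructed success trials with flat traces."""
    trials, eyes = [], []
    for i in range(n):
        cue = "L1" if i % 2 == 0 else "R1"
        tr = make_choice_trial(i, cue_id=cue,
                               direction="L" if cue == "L1" else "R",
                               t0=20.0 * i)
        trials.append(tr)
        n_samp = int(2.2 * 240)
        eyes.append(EyeTrace(trial_id=i, sample_rate_hz=240.0,
                             t0_s=tr.t_cue_on - 0.7,
                             x_deg=np.full(n_samp, offset),
                             y_deg=np.zeros(n_samp)))
    return Session("s", trials, [], eyes)


def _eye_session(seed, eye_model=None, n_blocks=10):
    cfg = SyntheticConfig(session_id=f"es{seed}", n_neurons={},
                          n_choice_blocks=n_blocks, n_delayed_blocks=0,
                          p_correct=1.0, p_fixation_break=0.0,
                          eye_model=eye_model or EyeModelSpec(),
                          master_seed=seed)
    return generate_session(cfg)


# ---------------------------------------------------------------------------
# preprocessing


def test_constant_offset_traces_process_to_zero():
    summary = preprocess_eye(_session_with_traces(offset=0.35))
    assert np.allclose(summary.mean_left, 0.0, atol=1e-12)
    assert np.allclose(summary.mean_right, 0.0, atol=1e-12)


def test_preprocessing_invariant_to_global_offset():
    s0 = preprocess_eye(_session_with_traces(offset=0.0))
    s1 = preprocess_eye(_session_with_traces(offset=1.3))
    assert np.allclose(s0.mean_left, s1.mean_left)
    assert np.allclose(s0.mean_right, s1.mean_right)


def test_condition_means_recover_generated_bias():
    spec = EyeModelSpec(ou_sigma_deg=0.02, opposite_shift_prob=0.0)
    summary = preprocess_eye(_eye_session(60, spec))
    plateau = summary.time_s > 0.6
    assert summary.mean_right[plateau].mean() == pytest.approx(0.14, abs=0.03)
    assert summary.mean_left[plateau].mean() == pytest.approx(-0.14, abs=0.03)
    # normalization leaves the condition difference untouched
    assert np.all(summary.mean_right[plateau] - summary.mean_left[plateau]
                  > 0.2)


# ---------------------------------------------------------------------------
# shift classification


def test_shift_direction_follows_instruction_without_flips():
    spec = EyeModelSpec(ou_sigma_deg=0.03, opposite_shift_prob=0.0)
    session = _eye_session(61, spec)
    shifts = classify_shift_direction(session)
    hemi = {t.trial_id: t.instructed_hemifield for t in session.trials}
    agree = np.mean([shifts[tid] == hemi[tid] for tid in shifts])
    assert agree > 0.95


def test_shift_direction_recovers_opposite_probability():
    spec = EyeModelSpec(ou_sigma_deg=0.03, opposite_shift_prob=0.30)
    sessions = [_eye_session(70 + k, spec) for k in range(3)]
    opp = n = 0
    for s in sessions:
        shifts = classify_shift_direction(s)
        hemi = {t.trial_id: t.instructed_hemifield for t in s.trials}
        opp += sum(shifts[tid] != hemi[tid] for tid in shifts)
        n += len(shifts)
    phat = opp / n
    assert abs(phat - 0.30) < 3 * np.sqrt(0.3 * 0.7 / n) + 0.02


# ---------------------------------------------------------------------------
# divergence detection


def _stub_summaries(diff_fn, n_sessions=6, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(-0.5, 1.2, 1 / 240)
    out = []
    for k in range(n_sessions):
        d = diff_fn(t) / 2
        noise = rng.normal(0, 0.002, size=t.size)
        out.append(EyeSummary(session_id=f"s{k}", time_s=t,
                              mean_left=-d + noise,
                              mean_right=d + rng.normal(0, 0.002, t.size),
                              max_diff_time_s=0.5, shift_direction={}))
    return out


def test_divergence_onset_detected_at_ramp_start():
    onset = detect_divergence(_stub_summaries(
        lambda t: 0.1 * np.clip((t - 0.2) / 0.1, 0, 1)))
    assert onset is not None
    assert 0.17 <= onset <= 0.28


def test_divergence_null_traces_give_none():
    assert detect_divergence(_stub_summaries(lambda t: 0.0 * t)) is None


def test_divergence_single_isolated_timepoint_rejected():
    def spike_diff(t):
        d = np.zeros_like(t)
        d[np.argmin(np.abs(t - 0.3))] = 0.5
        return d

    assert detect_divergence(_stub_summaries(spike_diff)) is None


def test_divergence_needs_three_sessions():
    with pytest.raises(ValueError):
        detect_divergence(_stub_summaries(lambda t: t)[:2])


def test_divergence_generator_recovery():
    sessions = [_eye_session(80 + k) for k in range(8)]
    onset = detect_divergence([preprocess_eye(s) for s in sessions])
    assert onset is not None
    assert abs(onset - 0.17) <= 0.03


# ---------------------------------------------------------------------------
# hemifield vs eye-shift ANOVA


def _labels(n, rng):
    hemi = np.array(["L", "R"])[rng.integers(0, 2, n)]
    shift = np.where(rng.uniform(size=n) < 0.75, hemi,
                     np.where(hemi == "L", "R", "L"))
    return list(hemi), list(shift)


def test_instruction_driven_activity_flags_instruction_not_eye(rng):
    n, n_win = 160, 30
    hemi, shift = _labels(n, rng)
    y = rng.normal(10, 1, size=(n, n_win))
    y[np.array(hemi) == "L"] += 3.0
    res = hemifield_vs_eyeshift_anova(y, hemi, shift)
    assert res["instruction_modulated"].mean() > 0.9
    assert res["eye_modulated"].mean() < 0.2


def test_eye_driven_activity_flags_eye(rng):
    n, n_win = 160, 30
    hemi, shift = _labels(n, rng)
    y = rng.normal(10, 1, size=(n, n_win))
    y[np.array(shift) == "L"] += 3.0
    res = hemifield_vs_eyeshift_anova(y, hemi, shift)
    assert res["eye_modulated"].mean() > 0.9


def test_null_activity_flags_nothing(rng):
    n, n_win = 160, 40
    hemi, shift = _labels(n, rng)
    y = rng.normal(10, 1, size=(n, n_win))
    res = hemifield_vs_eyeshift_anova(y, hemi, shift)
    assert res["instruction_modulated"].mean() < 0.1
    assert res["eye_modulated"].mean() < 0.1


# ---------------------------------------------------------------------------
# regression disentanglement


def test_beta_hemi_unbiased_on_code_driven_counts(rng):
    beta_true = 1.0 / np.sqrt(1.0 + 4.0)   # corr for y = code + N(0, 2)
    est = []
    for _ in range(300):
        code = np.tile([1.0, -1.0], 50)
        eye = rng.normal(0, 0.1, size=100)
        y = (5.0 + code + rng.normal(0, 2.0, size=100))[:, None]
        res = regress_activity_on_eye(y, code, eye, n_shuffle=2, seed=1)
        est.append(res.beta_hemi[0])
    se = np.std(est) / np.sqrt(len(est))
    assert abs(np.mean(est) - beta_true) < 3 * se + 1e-3


def test_eye_driven_counts_attenuate_beta_hemi_eye(rng):
    code = np.tile([1.0, -1.0], 60)
    eye = 0.1 * code + rng.normal(0, 0.1, size=120)
    y = (10.0 + 20.0 * eye + rng.normal(0, 0.5, size=120))[:, None]
    res = regress_activity_on_eye(y, code, eye, n_shuffle=50, seed=2)
    assert res.beta_hemi[0] > 0.3                     # spurious correlation
    assert abs(res.beta_hemi_eye[0]) < 0.5 * res.beta_hemi[0]
    assert res.beta_eye[0] > 0.5


def test_hemifield_driven_counts_keep_beta_under_eye_control(rng):
    code = np.tile([1.0, -1.0], 60)
    eye = 0.1 * code + rng.normal(0, 0.1, size=120)
    y = (10.0 + 2.0 * code + rng.normal(0, 1.0, size=120))[:, None]
    res = regress_activity_on_eye(y, code, eye, n_shuffle=50, seed=3)
    assert res.beta_hemi_eye[0] == pytest.approx(res.beta_hemi[0], abs=0.15)


def test_shuffle_null_centered_at_zero(rng):
    code = np.tile([1.0, -1.0], 30)
    eye = rng.normal(size=60)
    y = rng.normal(size=(60, 2))
    res = regress_activity_on_eye(y, code, eye, n_shuffle=400, seed=4)
    assert np.all(np.abs(res.null_beta_hemi_mean) < 0.05)
    assert np.all(np.abs(res.null_beta_hemi_eye_mean) < 0.05)


def test_regression_requires_enough_trials():
    with pytest.raises(ValueError):
        regress_activity_on_eye(np.ones((5, 2)), np.ones(5) * 0,
                                np.zeros(5))


# ---------------------------------------------------------------------------
# stimulation statistics


def _stim_cohort(seed, n_stim=4, n_ctrl=4, ipsi_inc=0.05):
    eye = EyeModelSpec(stim_contra_shift_deg=0.10)
    sessions = []
    for k in range(n_stim):
        sessions.append(generate_session(SyntheticConfig(
            session_id=f"stim{k}", n_neurons={}, n_choice_blocks=5,
            n_delayed_blocks=0, stimulation_session=True, p_correct=0.90,
            stim_ipsi_error_increase=ipsi_inc, eye_model=eye,
            master_seed=seed + k)))
    for k in range(n_ctrl):
        sessions.append(generate_session(SyntheticConfig(
            session_id=f"ctrl{k}", n_neurons={}, n_choice_blocks=5,
            n_delayed_blocks=0, cue_duration_s=0.12, p_correct=0.90,
            master_seed=seed + 100 + k)))
    return sessions


def test_stim_behavior_stats_structure():
    summary = stim_behavior_stats(_stim_cohort(500))
    assert summary.session_rates_stim.size == 4
    assert summary.session_rates_nonstim.size == 4
    for arr in (summary.ipsi_rate_stim, summary.ipsi_rate_nonstim,
                summary.contra_rate_stim, summary.contra_rate_nonstim):
        assert np.all((arr >= 0) & (arr <= 1))
    assert {"session_correct_rate", "ipsi_stim_vs_nonstim",
            "contra_stim_vs_nonstim", "eye_stim_effect",
            "eye_trialtype_effect"} <= set(summary.tests)
    eta = summary.tests["eye_stim_effect"].effect_size
    assert 0.0 <= eta <= 1.0


def test_stim_behavior_needs_two_stim_sessions():
    with pytest.raises(ValueError):
        stim_behavior_stats(_stim_cohort(600, n_stim=1, n_ctrl=2))
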