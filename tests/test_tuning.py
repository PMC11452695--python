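"""PD determination, neuron typing, AUC tracks, tuning-matrix alignment."""

import numpy as np
import pytest

from sefpre.io_schema import DIRECTIONS, select_trials
from sefpre.spike_metrics import WindowGrid
from sefpre.synthetic import SyntheticConfig, generate_session, make_neuron_spec
from sefpre.tuning import (PDResult, align_tuning_population,
                           auc_track_with_null, classify_neuron_type,
                           determine_pd, pd_condition_labels,
                           population_auc_test, signed_count_binomial,
                           tuning_matrix)
from tests.conftest import make_delayed_trial


def _delayed_trials(n_per_dir=5, spacing=20.0):
    trials = []
    tid = 0
    for rep in range(n_per_dir):
        for d in DIRECTIONS:
            trials.append(make_delayed_trial(tid, d, t0=spacing * tid + 5.0))
            tid += 1
    return trials


def _train_with_counts(trials, count_of):
    """Spike train with ``count_of(trial, rep)`` spikes 0-300 ms post target."""
    times = []
    for i, tr in enumerate(trials):
        k = count_of(tr, i)
        if k:
            times.append(tr.t_targets_on + 0.001 + 0.298 * np.arange(k) / max(k, 1))
    return np.sort(np.concatenate(times)) if times else np.zeros(0)


# ---------------------------------------------------------------------------
# preferred direction


def test_determine_pd_recovers_strong_direction():
    trials = _delayed_trials(6)
    spikes = _train_with_counts(
        trials, lambda tr, i: (20 if tr.target_direction == "L" else 5) + i % 3)
    res = determine_pd(spikes, trials, "n0")
    assert res.has_pd and res.pd_direction == "L"
    assert res.anova_p <= 0.05


def test_determine_pd_identical_distributions_no_pd():
    trials = _delayed_trials(5)
    spikes = _train_with_counts(trials, lambda tr, i: 6 + i % 2)
    res = determine_pd(spikes, trials)
    assert not res.has_pd and res.pd_direction is None


def test_determine_pd_tied_maximum_no_pd():
    trials = _delayed_trials(6)

    def count(tr, i):
        if tr.target_direction in ("L", "R"):
            return 20 + (i // 6) % 2          # exact two-way tie on means
        return 2 + (i // 6) % 2

    res = determine_pd(_train_with_counts(trials, count), trials)
    assert res.mean_counts["L"] == res.mean_counts["R"]
    assert not res.has_pd


def test_determine_pd_missing_direction_errors():
    trials = [t for t in _delayed_trials(3) if t.target_direction != "LU"]
    with pytest.raises(ValueError, match="LU"):
        determine_pd(np.array([1.0]), trials)


def test_determine_pd_generator_recovery():
    spec = make_neuron_spec("hemifield_spatial", pd_direction="RD")
    cfg = SyntheticConfig(neuron_specs=[spec], n_choice_blocks=0,
                          n_delayed_blocks=10, p_correct=1.0,
                          p_fixation_break=0.0, master_seed=33)
    s = generate_session(cfg)
    res = determine_pd(s.spikes[0].spike_times_s,
                       select_trials(s, task="delayed"))
    assert res.has_pd and res.pd_direction == "RD"


# ---------------------------------------------------------------------------
# neuron typing


def _typed_session(archetype, seed, **overrides):
    spec = make_neuron_spec(archetype, **overrides)
    cfg = SyntheticConfig(neuron_specs=[spec], n_choice_blocks=0,
                          n_delayed_blocks=10, p_correct=1.0,
                          p_fixation_break=0.0, master_seed=seed)
    s = generate_session(cfg)
    return s.spikes[0].spike_times_s, select_trials(s, task="delayed")


def test_visual_archetype_typed_visual():
    spikes, trials = _typed_session("target_position", 44, det_gain=0.0)
    assert classify_neuron_type(spikes, trials).type == "visual"


def test_movement_archetype_typed_movement():
    spikes, trials = _typed_session("movement", 45)
    assert classify_neuron_type(spikes, trials).type == "movement"


def test_null_archetype_typed_none():
    spikes, trials = _typed_session("null", 46)
    assert classify_neuron_type(spikes, trials).type == "none"


# ---------------------------------------------------------------------------
# PD condition labels


def _pd(direction):
    return PDResult("n", True, direction, 0.01, {})


def test_pd_condition_labels_hand_cases():
    from tests.conftest import make_choice_trial
    left = make_choice_trial(0, cue_id="L1", direction="L")
    right = make_choice_trial(1, cue_id="R1", direction="R", t0=30.0)
    assert pd_condition_labels([left], _pd("LU")) == ["pd_included"]
    assert pd_condition_labels([left], _pd("R")) == ["pd_opposite"]
    # hemifield swap flips the labels
    inc_l = pd_condition_labels([left, right], _pd("L"))
    inc_r = pd_condition_labels([left, right], _pd("R"))
    assert inc_l == ["pd_included", "pd_opposite"]
    assert inc_r == ["pd_opposite", "pd_included"]


def test_pd_condition_labels_without_pd_errors():
    from tests.conftest import make_choice_trial
    with pytest.raises(ValueError):
        pd_condition_labels([make_choice_trial()],
                            PDResult("n", False, None, 0.5, {}))


# ---------------------------------------------------------------------------
# AUC tracks


def test_auc_track_shuffled_labels_centered_at_half(rng):
    counts = rng.poisson(8.0, size=(60, 10)).astype(float)
    cond = np.array(["pd_included"] * 30 + ["pd_opposite"] * 30)
    rng.shuffle(cond)
    track = auc_track_with_null(counts, cond, n_perm=300, seed=7)
    assert np.all(np.abs(track.null_mean - 0.5) < 0.05)
    assert np.all((track.auc >= 0) & (track.auc <= 1))


def test_auc_track_minimum_permutations_enforced():
    counts = np.ones((12, 3))
    cond = ["pd_included"] * 6 + ["pd_opposite"] * 6
    with pytest.raises(ValueError):
        auc_track_with_null(counts, cond, n_perm=1)


def test_auc_track_needs_five_trials_per_condition():
    counts = np.ones((8, 3))
    cond = ["pd_included"] * 4 + ["pd_opposite"] * 4
    with pytest.raises(ValueError):
        auc_track_with_null(counts, cond, n_perm=100)


def test_population_auc_null_rarely_significant(rng):
    tracks = []
    for k in range(25):
        counts = rng.poisson(8.0, size=(60, 8)).astype(float)
        cond = np.array(["pd_included"] * 30 + ["pd_opposite"] * 30)
        rng.shuffle(cond)
        tracks.append(auc_track_with_null(counts, cond, n_perm=100, seed=k))
    res = population_auc_test(tracks)
    assert res["significant"].sum() <= 1


# ---------------------------------------------------------------------------
# binomial counts


def test_signed_count_binomial_strong_imbalance(rng):
    counts, conds = [], []
    cond = np.array(["pd_included"] * 20 + ["pd_opposite"] * 20)
    for i in range(10):
        c = rng.normal(10.0, 1.0, size=(40, 4))
        if i < 9:
            c[:20] += 6.0     # 9 neurons prefer included, 1 prefers opposite
        else:
            c[20:] += 6.0
        counts.append(c)
        conds.append(cond)
    res = signed_count_binomial(counts, conds)
    assert res["n_greater_included"].tolist() == [9] * 4
    assert res["n_greater_opposite"].tolist() == [1] * 4
    import math
    expect = 2 * sum(math.comb(10, j) for j in (9, 10)) / 2 ** 10
    assert res["p"][0] == pytest.approx(expect)
    assert res["significant"].all()


def test_signed_count_binomial_no_significant_neurons(rng):
    cond = np.array(["pd_included"] * 20 + ["pd_opposite"] * 20)
    counts = [rng.normal(10.0, 1.0, size=(40, 3)) for _ in range(4)]
    res = signed_count_binomial(counts, [cond] * 4)
    zero = (res["n_greater_included"] + res["n_greater_opposite"]) == 0
    assert np.all(res["p"][zero] == 1.0)


# ---------------------------------------------------------------------------
# tuning matrices


def test_tuning_matrix_constant_neuron_flat():
    trials = _delayed_trials(4)
    # 20 Hz regular train, offset so no spike sits on a window boundary
    spikes = np.arange(0.013, 800.0, 0.05)
    grid = WindowGrid("targets_on", 0.0, 0.5, 0.2, 0.01)
    mat = tuning_matrix(spikes, trials, grid)
    assert mat.shape == (6, grid.n_windows)
    assert np.allclose(mat, 20.0, atol=1.0)


def test_tuning_matrix_row_max_at_pd():
    spec = make_neuron_spec("target_position", pd_direction="LU")
    cfg = SyntheticConfig(neuron_specs=[spec], n_choice_blocks=0,
                          n_delayed_blocks=10, p_correct=1.0,
                          p_fixation_break=0.0, master_seed=8)
    s = generate_session(cfg)
    grid = WindowGrid("targets_on", 0.0, 0.4, 0.2, 0.05)
    mat = tuning_matrix(s.spikes[0].spike_times_s,
                        select_trials(s, task="delayed"), grid)
    visual = mat[:, 2:].mean(axis=1)          # windows covering the transient
    assert DIRECTIONS[int(np.argmax(visual))] == "LU"


def test_tuning_matrix_missing_direction_is_nan():
    trials = [t for t in _delayed_trials(3) if t.target_direction != "Rx"]
    trials = [t for t in trials if t.target_direction != "RD"]
    grid = WindowGrid("targets_on", 0.0, 0.4, 0.2, 0.1)
    mat = tuning_matrix(np.array([5.0, 6.0]), trials, grid)
    assert np.isnan(mat[DIRECTIONS.index("RD")]).all()


def test_align_single_neuron_pd_R_rotation_is_identity():
    mat = np.arange(6.0)[:, None] * np.ones((1, 4))
    res = align_tuning_population([mat], [_pd("R")], split_window=2)
    # post rows on the 8-grid: PD (R) sits at 0 deg
    post = res["post"]
    assert post[0, 0] == mat[DIRECTIONS.index("R"), 2]
    assert post[1, 0] == mat[DIRECTIONS.index("RU"), 2]


def test_align_up_slot_interpolates_LU_RU_mean():
    mat = np.zeros((6, 4))
    for i, d in enumerate(DIRECTIONS):
        mat[i] = i + 1.0
    res = align_tuning_population([mat], [_pd("R")], split_window=2)
    post = res["post"]
    up = post[2, 0]                   # 90 deg relative to PD = absolute Up
    lu = mat[DIRECTIONS.index("LU"), 2]
    ru = mat[DIRECTIONS.index("RU"), 2]
    assert up == pytest.approx((lu + ru) / 2)


def test_align_mirror_neurons_give_identical_rows():
    # tuning depends only on the angle relative to the PD
    def make(pd_dir):
        from sefpre.io_schema import DIRECTION_ANGLES
        pd_angle = DIRECTION_ANGLES[pd_dir]
        mat = np.zeros((6, 4))
        for i, d in enumerate(DIRECTIONS):
            rel = (DIRECTION_ANGLES[d] - pd_angle) % 360
            mat[i] = np.cos(np.deg2rad(rel)) + 2.0
        return mat

    res = align_tuning_population([make("R"), make("L")],
                                  [_pd("R"), _pd("L")], split_window=2)
    single = align_tuning_population([make("R")], [_pd("R")], split_window=2)
    assert np.allclose(res["pre"], single["pre"])
    assert np.allclose(res["post"], single["post"])


def test_align_excludes_neurons_without_pd():
    mat = np.ones((6, 4))
    res = align_tuning_population(
        [mat, mat], [_pd("R"), PDResult("x", False, None, 0.9, {})],
        split_window=2)
    assert res["n_neurons"] == 1
    with pytest.raises(ValueError):
        align_tuning_population([mat], [PDResult("x", False, None, 0.9, {})],
                                split_window=2)
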