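"""Synthetic session generator.

Emulates the two oculomotor tasks and the statistical structure the
analysis pipeline assumes: block-randomized saccadic choice trials (4
symbolic cues x choice-target angles, 12 regular + 4 additional per
block), visually guided delayed saccades to six directions at 10 degrees
eccentricity, inhomogeneous-Poisson spiking with direction tuning and
hemifield / object / angle selectivity, fixational eye drift with a small
instructed-side bias emerging shortly after cue onset, and
stimulation-induced contralateral eye drift plus an ipsilateral error-rate
increase.

Everything is reproducible from a single master seed via counter-based
per-neuron x per-trial substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import signal as sp_signal

from .io_schema import (CUE_TO_HEMIFIELD, CUES, DIRECTION_ANGLES, DIRECTIONS,
                        EyeTrace, Session, SpikeTrain, TrialRecord,
                        direction_hemifield, targets_for_angle)

ARCHETYPES = ("hemifield_spatial", "hemifield_conceptual", "object_selective",
              "angle_selective", "target_position", "movement", "null")

#: Additional (non-regular) choice-target angles: +-5..40 deg in 5-deg steps.
ADDITIONAL_ANGLES = tuple(float(a) for a in range(-40, 45, 5) if a % 45 != 0)

# Visual transient kernel: latency, flat peak, exponential decay (s).
KVIS_LATENCY = 0.080
KVIS_FLAT = 0.150
KVIS_DECAY_TAU = 0.200
# Peri-saccadic kernel: Gaussian bump centered 20 ms before saccade onset.
KMOV_CENTER = -0.020
KMOV_SIGMA = 0.040


@dataclass
class NeuronSpec:
    """Ground-truth response profile of one synthetic neuron."""

    archetype: str
    baseline_hz: float = 10.0
    pd_direction: str | None = None
    kappa: float = 2.5
    vis_gain: float = 0.0
    hemi_gain: float = 1.0
    mov_gain: float = 0.0
    det_gain: float = 0.0   # sustained tuned gain, target onset -> go
    obj_gains: dict[str, float] = field(default_factory=dict)
    angle_gains: dict[float, float] = field(default_factory=dict)
    preferred_side: str | None = None
    eye_gain_per_deg: float = 0.0
    neuron_id: str = ""

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.baseline_hz < 0 or self.kappa < 0 or self.vis_gain < 0 \
                or self.mov_gain < 0 or self.hemi_gain < 1:
            raise ValueError("gains out of range")
        if self.archetype == "hemifield_spatial" and self.pd_direction is None:
            raise ValueError("hemifield_spatial neurons need a pd_direction")
        if self.archetype == "null":
            if (self.hemi_gain != 1 or self.vis_gain != 0 or self.mov_gain != 0
                    or self.det_gain != 0 or self.obj_gains or self.angle_gains
                    or self.eye_gain_per_deg != 0):
                raise ValueError("null archetype must have neutral gains")
        if self.preferred_side is None:
            if self.pd_direction is not None:
                self.preferred_side = direction_hemifield(self.pd_direction)
            elif self.archetype == "hemifield_conceptual":
                raise ValueError("hemifield_conceptual needs a preferred_side")


@dataclass
class EyeModelSpec:
    """Fixational eye model: OU drift plus an instructed-side bias ramp."""

    ou_tau_s: float = 0.4
    ou_sigma_deg: float = 0.06
    bias_amp_deg: float = 0.14
    bias_onset_s: float = 0.17
    bias_ramp_s: float = 0.20
    opposite_shift_prob: float = 0.25
    stim_contra_shift_deg: float = 0.0
    stim_ramp_s: float = 0.40

    def __post_init__(self) -> None:
        if min(self.ou_tau_s, self.ou_sigma_deg, self.bias_amp_deg,
               self.bias_onset_s, self.stim_contra_shift_deg,
               self.opposite_shift_prob) < 0:
            raise ValueError("eye model parameters must be non-negative")
        if self.opposite_shift_prob > 0.5:
            raise ValueError("opposite_shift_prob must be <= 0.5")


@dataclass
class SyntheticConfig:
    """Study-condition parameters of a synthetic session."""

    session_id: str = "synthetic"
    n_neurons: dict[str, int] = field(default_factory=dict)
    neuron_specs: list[NeuronSpec] | None = None
    n_choice_blocks: int = 10
    n_delayed_blocks: int = 10
    stimulation_session: bool = False
    cue_duration_s: float | None = None   # 0.7 s; 0.12 s in stimulation sessions
    delay_s: float = 0.5
    fixation_hold_s: float = 1.0
    go_delay_range_s: tuple[float, float] = (0.75, 1.2)
    saccade_latency_range_s: tuple[float, float] = (0.15, 0.30)
    iti_range_s: tuple[float, float] = (3.6, 4.5)
    p_correct: float = 0.97
    p_fixation_break: float = 0.01
    stim_ipsi_error_increase: float = 0.05
    stim_contra_error_increase: float = 0.01
    distractor_weight: float = 0.5
    eye_model: EyeModelSpec = field(default_factory=EyeModelSpec)
    monkey: str = "S"
    hemisphere: str = "L"
    master_seed: int = 0

    def resolved_cue_duration(self) -> float:
        if self.cue_duration_s is not None:
            return self.cue_duration_s
        return 0.12 if self.stimulation_session else 0.70

    def build_specs(self) -> list[NeuronSpec]:
        if self.neuron_specs is not None:
            return self.neuron_specs
        return default_cohort(self.n_neurons, self.master_seed)


def default_cohort(counts: dict[str, int], seed: int) -> list[NeuronSpec]:
    """Build neuron specs for the requested archetype counts.

    Preferred directions are dealt round-robin from a seeded shuffle of the
    six canonical directions so cohort PDs stay close to uniform.
    """
    rng = np.random.default_rng([seed, 2**20])
    dirs = list(rng.permutation(DIRECTIONS))
    specs: list[NeuronSpec] = []
    k = 0
    for archetype in ARCHETYPES:
        for _ in range(int(counts.get(archetype, 0))):
            pd_dir = dirs[k % 6]
            k += 1
            specs.append(make_neuron_spec(archetype, pd_direction=pd_dir))
    for i, sp in enumerate(specs):
        sp.neuron_id = f"n{i:03d}"
    return specs


def make_neuron_spec(archetype: str, pd_direction: str = "R",
                     **overrides) -> NeuronSpec:
    """A NeuronSpec with the package's default gains for an archetype."""
    base: dict = {"archetype": archetype, "baseline_hz": 10.0}
    if archetype == "hemifield_spatial":
        base.update(pd_direction=pd_direction, vis_gain=3.0, hemi_gain=2.0,
                    det_gain=2.0)
    elif archetype == "hemifield_conceptual":
        base.update(hemi_gain=2.0,
                    preferred_side=direction_hemifield(pd_direction))
    elif archetype == "object_selective":
        base.update(obj_gains={"L1": 1.8, "L2": 1.0, "R1": 1.8, "R2": 1.0})
    elif archetype == "angle_selective":
        base.update(angle_gains={-45.0: 1.0, 0.0: 1.6, 45.0: 2.2})
    elif archetype == "target_position":
        base.update(pd_direction=pd_direction, vis_gain=3.0, det_gain=2.0)
    elif archetype == "movement":
        base.update(mov_gain=30.0)
    base.update(overrides)
    return NeuronSpec(**base)


# ---------------------------------------------------------------------------
# Rate model


def _kvis(tau: np.ndarray) -> np.ndarray:
    """Visual transient kernel (unitless, peak 1)."""
    out = np.zeros_like(tau)
    flat = (tau >= KVIS_LATENCY) & (tau < KVIS_LATENCY + KVIS_FLAT)
    decay = tau >= KVIS_LATENCY + KVIS_FLAT
    out[flat] = 1.0
    out[decay] = np.exp(-(tau[decay] - KVIS_LATENCY - KVIS_FLAT)
                        / KVIS_DECAY_TAU)
    return out


def _kmov(tau: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * ((tau - KMOV_CENTER) / KMOV_SIGMA) ** 2)


def _von_mises(theta_deg: float, pd_deg: float, kappa: float) -> float:
    """Von Mises tuning normalized to 1 at the preferred direction."""
    return float(np.exp(kappa * (np.cos(np.deg2rad(theta_deg - pd_deg)) - 1)))


class RateProfile:
    """Piecewise firing-rate function lambda(t) for one neuron and trial."""

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], lam_max: float):
        self._fn = fn
        self.lam_max = float(lam_max)

    def __call__(self, t) -> np.ndarray:
        return self._fn(np.asarray(t, dtype=float))


def _target_polar_angles(trial: TrialRecord) -> tuple[float, float | None]:
    """(chosen, distractor) target polar angles in degrees."""
    if trial.task == "delayed":
        return DIRECTION_ANGLES[trial.target_direction], None
    angle = trial.target_angle_deg if trial.target_angle_deg is not None else 0.0
    chosen_side = direction_hemifield(trial.target_direction)
    chosen = angle if chosen_side == "R" else angle + 180.0
    return chosen, chosen + 180.0


def rate_profile(spec: NeuronSpec, trial: TrialRecord,
                 eye: EyeTrace | None = None,
                 distractor_weight: float = 0.5) -> RateProfile:
    """Firing-rate function of a synthetic neuron on one trial.

    lambda(t) = baseline * H(t) * (1 + vis_gain * fdir * kvis) * O(t) * A(t)
    * E(t) + mov_gain * kmov(t - t_saccade), where H applies the sustained
    hemifield gain during [cue on, targets on] when the instructed
    hemifield matches the neuron's preferred side, fdir is von Mises
    direction tuning of the visual transient (the unchosen choice target
    adds a ``distractor_weight``-weighted transient), O and A are the
    per-cue and per-angle multipliers, and E is an optional multiplicative
    coupling to horizontal eye position.
    """
    base = spec.baseline_hz
    hemi_on = (trial.task == "choice" and spec.hemi_gain != 1.0
               and trial.instructed_hemifield is not None
               and trial.instructed_hemifield == spec.preferred_side)
    theta_chosen, theta_distr = _target_polar_angles(trial)
    if spec.pd_direction is not None:
        pd_angle = DIRECTION_ANGLES[spec.pd_direction]
        f_chosen = _von_mises(theta_chosen, pd_angle, spec.kappa)
        f_distr = (_von_mises(theta_distr, pd_angle, spec.kappa)
                   if theta_distr is not None else 0.0)
    else:
        f_chosen, f_distr = 1.0, 1.0 if theta_distr is not None else 0.0

    obj_gain = 1.0
    if spec.obj_gains and trial.cue_id is not None:
        obj_gain = spec.obj_gains.get(trial.cue_id, 1.0)
    ang_gain = 1.0
    if spec.angle_gains and trial.target_angle_deg is not None:
        ang_gain = spec.angle_gains.get(trial.target_angle_deg, 1.0)

    t_cue_on, t_cue_off = trial.t_cue_on, trial.t_cue_off
    t_targets, t_go = trial.t_targets_on, trial.t_go
    t_sac = trial.t_saccade_on

    eye_t = eye_x = None
    if spec.eye_gain_per_deg != 0.0 and eye is not None:
        eye_t, eye_x = eye.t_s, eye.x_deg

    def fn(t: np.ndarray) -> np.ndarray:
        lam = np.full_like(t, float(base))
        if spec.vis_gain > 0:
            tau = t - t_targets
            drive = spec.vis_gain * f_chosen * _kvis(tau)
            if theta_distr is not None and distractor_weight > 0:
                drive = drive + distractor_weight * spec.vis_gain \
                    * f_distr * _kvis(tau)
            lam = lam * (1.0 + drive)
        if spec.det_gain > 0:
            # sustained direction-tuned elevation through target determination
            in_det = (t >= t_targets + KVIS_LATENCY) & (t < t_go)
            lam = np.where(in_det,
                           lam * (1.0 + spec.det_gain * f_chosen), lam)
        if hemi_on and t_cue_on is not None:
            in_presel = (t >= t_cue_on) & (t < t_targets)
            lam = np.where(in_presel, lam * spec.hemi_gain, lam)
        if obj_gain != 1.0 and t_cue_on is not None:
            in_cue = (t >= t_cue_on) & (t < t_cue_off)
            lam = np.where(in_cue, lam * obj_gain, lam)
        if ang_gain != 1.0:
            in_det = (t >= t_targets) & (t < t_go)
            lam = np.where(in_det, lam * ang_gain, lam)
        if eye_t is not None:
            x = np.interp(t, eye_t, eye_x, left=0.0, right=0.0)
            lam = lam * np.maximum(1.0 + spec.eye_gain_per_deg * x, 0.0)
        if spec.mov_gain > 0 and t_sac is not None:
            lam = lam + spec.mov_gain * _kmov(t - t_sac)
        return np.maximum(lam, 0.0)

    eye_factor = 1.0
    if eye_x is not None and eye_x.size:
        # outside the trace the eye factor is 1, so 1 belongs in the bound
        eye_factor = max(1.0,
                         1.0 + spec.eye_gain_per_deg * float(np.max(eye_x)),
                         1.0 + spec.eye_gain_per_deg * float(np.min(eye_x))
                         ) + 1e-9
    lam_max = (base
               * max(spec.hemi_gain, 1.0)
               * (1.0 + spec.vis_gain * (1.0 + distractor_weight))
               * (1.0 + spec.det_gain)
               * max([1.0, *spec.obj_gains.values()] if spec.obj_gains else [1.0])
               * max([1.0, *spec.angle_gains.values()] if spec.angle_gains else [1.0])
               * eye_factor
               + spec.mov_gain)
    return RateProfile(fn, lam_max)


def sample_spikes(rate: RateProfile | Callable, t_range: tuple[float, float],
                  rng: np.random.Generator,
                  lam_max: float | None = None) -> np.ndarray:
    """Inhomogeneous Poisson sample on ``t_range`` by thinning.

    ``lam_max`` must bound the rate on the interval (taken from the
    profile when available); candidate points from a homogeneous Poisson
    process at ``lam_max`` are accepted with probability lambda(t)/lam_max.
    """
    if lam_max is None:
        lam_max = getattr(rate, "lam_max", None)
    if lam_max is None or not np.isfinite(lam_max):
        raise ValueError("sample_spikes needs a finite rate bound")
    t0, t1 = t_range
    if lam_max <= 0 or t1 <= t0:
        return np.zeros(0)
    n = rng.poisson(lam_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n))
    lam = np.asarray(rate(cand), dtype=float)
    if np.any(lam > lam_max * (1 + 1e-9)):
        raise ValueError("rate exceeds the supplied bound")
    keep = rng.uniform(0.0, lam_max, size=n) < lam
    return cand[keep]


# ---------------------------------------------------------------------------
# Eye model


def generate_eye_trace(trial: TrialRecord, spec: EyeModelSpec,
                       rng: np.random.Generator,
                       sample_rate_hz: float = 240.0) -> EyeTrace:
    """Simulated eye trace: OU drift + instructed-side bias (+ stim drift).

    x(t) = OU + side * bias_amp * ramp(t - cue_on - bias_onset) with the
    side flipped per trial with probability ``opposite_shift_prob``; a
    stimulated trial adds a contralateral (positive-x) ramp from cue
    onset.  The trace covers 0.7 s before cue onset (0.5 s baseline plus
    margin) through the go signal and is clipped to the 2.5-degree
    fixation window.
    """
    anchor = trial.t_cue_on if trial.t_cue_on is not None else trial.t_targets_on
    t0 = anchor - 0.7
    t1 = trial.t_go + 0.05
    n = int(np.ceil((t1 - t0) * sample_rate_hz)) + 1
    t = t0 + np.arange(n) / sample_rate_hz

    dt = 1.0 / sample_rate_hz
    rho = np.exp(-dt / spec.ou_tau_s) if spec.ou_tau_s > 0 else 0.0
    innov_sd = spec.ou_sigma_deg * np.sqrt(1 - rho ** 2)

    def ou() -> np.ndarray:
        # exact stationary AR(1) discretization, vectorized via lfilter
        z = rng.standard_normal(n)
        driven = sp_signal.lfilter([1.0], [1.0, -rho], innov_sd * z)
        x0 = spec.ou_sigma_deg * z[0] - innov_sd * z[0]
        return driven + x0 * rho ** np.arange(n)

    x = ou()
    y = ou()

    if trial.task == "choice" and trial.instructed_hemifield is not None \
            and trial.t_cue_on is not None:
        side = 1.0 if trial.instructed_hemifield == "R" else -1.0
        if rng.uniform() < spec.opposite_shift_prob:
            side = -side
        ramp = np.clip((t - trial.t_cue_on - spec.bias_onset_s)
                       / max(spec.bias_ramp_s, 1e-9), 0.0, 1.0)
        x = x + side * spec.bias_amp_deg * ramp
    if trial.stim and spec.stim_contra_shift_deg > 0 and trial.t_cue_on is not None:
        sramp = np.clip((t - trial.t_cue_on) / max(spec.stim_ramp_s, 1e-9),
                        0.0, 1.0)
        x = x + spec.stim_contra_shift_deg * sramp

    lim = 2.45
    return EyeTrace(trial_id=trial.trial_id, sample_rate_hz=sample_rate_hz,
                    t0_s=t0, x_deg=np.clip(x, -lim, lim),
                    y_deg=np.clip(y, -lim, lim))


# ---------------------------------------------------------------------------
# Session assembly


def _substream(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(master_seed) & 0x7FFFFFFF, *key])


def _sample_outcome(rng, p_success: float, p_fixbreak: float) -> str:
    """Fixation breaks first; p_success is the correct rate among choices."""
    if rng.uniform() < p_fixbreak:
        return "fixation_break"
    return "success" if rng.uniform() < p_success else "wrong_choice"


def generate_session(config: SyntheticConfig) -> Session:
    """Generate a complete synthetic session from a config.

    Trial sequence: ``n_choice_blocks`` blocks of the saccadic choice task
    (12 regular + 4 additional types, shuffled within block; doubled with
    a stimulated copy of each type in stimulation sessions) followed by
    ``n_delayed_blocks`` blocks of the delayed saccade task (6 directions
    shuffled).  Fully deterministic given ``master_seed``.
    """
    specs = config.build_specs()
    if not specs and config.n_choice_blocks == 0 and config.n_delayed_blocks == 0:
        raise ValueError("nothing to generate: no neurons and no blocks")

    seed = config.master_seed
    trial_rng = _substream(seed, 0)
    cue_dur = config.resolved_cue_duration()
    ipsi_side = "L" if config.hemisphere == "L" else "R"

    trials: list[TrialRecord] = []
    clock = 1.0     # spike/eye sampling precedes fixation onset by < 1 s
    trial_id = 0

    def push_choice(cue: str, angle: float, stim: bool) -> None:
        nonlocal clock, trial_id
        hemi = CUE_TO_HEMIFIELD[cue]
        t_fix_on = clock
        t_fix_acq = t_fix_on + 0.2
        t_cue_on = t_fix_acq + config.fixation_hold_s
        t_cue_off = t_cue_on + cue_dur
        t_targets = t_cue_off + config.delay_s
        t_go = t_targets + trial_rng.uniform(*config.go_delay_range_s)
        p = config.p_correct
        if stim:
            p -= (config.stim_ipsi_error_increase if hemi == ipsi_side
                  else config.stim_contra_error_increase)
        outcome = _sample_outcome(trial_rng, p, config.p_fixation_break)
        right_dir, left_dir = targets_for_angle(angle)
        chosen_side = hemi if outcome != "wrong_choice" else \
            ("L" if hemi == "R" else "R")
        direction = right_dir if chosen_side == "R" else left_dir
        if outcome in ("success", "wrong_choice"):
            t_sac = t_go + trial_rng.uniform(*config.saccade_latency_range_s)
            t_rew = t_sac + 0.45 if outcome == "success" else None
        else:
            t_sac = t_rew = None
        trials.append(TrialRecord(
            trial_id=trial_id, task="choice", cue_id=cue,
            instructed_hemifield=hemi, target_angle_deg=angle,
            target_direction=direction,
            regular_trial=angle in (-45.0, 0.0, 45.0),
            t_fix_on=t_fix_on, t_fix_acquired=t_fix_acq, t_cue_on=t_cue_on,
            t_cue_off=t_cue_off, t_targets_on=t_targets, t_go=t_go,
            t_saccade_on=t_sac, t_reward=t_rew, outcome=outcome, stim=stim))
        trial_id += 1
        end = t_sac if t_sac is not None else t_go
        clock = end + 0.9 + trial_rng.uniform(*config.iti_range_s)

    def push_delayed(direction: str) -> None:
        nonlocal clock, trial_id
        t_fix_on = clock
        t_fix_acq = t_fix_on + 0.2
        t_targets = t_fix_acq + config.fixation_hold_s
        t_go = t_targets + trial_rng.uniform(*config.go_delay_range_s)
        outcome = _sample_outcome(trial_rng, config.p_correct,
                                  config.p_fixation_break)
        if outcome == "wrong_choice":    # no distractor in the delayed task
            outcome = "success"
        if outcome == "success":
            t_sac = t_go + trial_rng.uniform(*config.saccade_latency_range_s)
            t_rew = t_sac + 0.45
        else:
            t_sac = t_rew = None
        trials.append(TrialRecord(
            trial_id=trial_id, task="delayed", cue_id=None,
            instructed_hemifield=None, target_angle_deg=None,
            target_direction=direction, regular_trial=False,
            t_fix_on=t_fix_on, t_fix_acquired=t_fix_acq, t_cue_on=None,
            t_cue_off=None, t_targets_on=t_targets, t_go=t_go,
            t_saccade_on=t_sac, t_reward=t_rew, outcome=outcome, stim=False))
        trial_id += 1
        end = t_sac if t_sac is not None else t_go
        clock = end + 0.9 + trial_rng.uniform(*config.iti_range_s)

    for _ in range(config.n_choice_blocks):
        block: list[tuple[str, float]] = [(c, a) for c in CUES
                                          for a in (-45.0, 0.0, 45.0)]
        extra_angles = trial_rng.choice(len(ADDITIONAL_ANGLES), size=4,
                                        replace=False)
        block += [(c, ADDITIONAL_ANGLES[i])
                  for c, i in zip(CUES, extra_angles)]
        if config.stimulation_session:
            typed = [(c, a, s) for (c, a) in block for s in (False, True)]
        else:
            typed = [(c, a, False) for (c, a) in block]
        order = trial_rng.permutation(len(typed))
        for k in order:
            push_choice(*typed[k])

    for _ in range(config.n_delayed_blocks):
        for k in trial_rng.permutation(6):
            push_delayed(DIRECTIONS[k])

    eyes = [generate_eye_trace(tr, config.eye_model,
                               _substream(seed, 2, tr.trial_id))
            for tr in trials]
    eye_by_trial = {ey.trial_id: ey for ey in eyes}

    spikes: list[SpikeTrain] = []
    for j, spec in enumerate(specs):
        if not spec.neuron_id:
            spec.neuron_id = f"n{j:03d}"
        times = []
        for tr in trials:
            prof = rate_profile(spec, tr, eye=eye_by_trial[tr.trial_id],
                                distractor_weight=config.distractor_weight)
            t_end = (tr.t_saccade_on if tr.t_saccade_on is not None
                     else tr.t_go) + 0.6
            times.append(sample_spikes(prof, (tr.t_fix_on - 0.4, t_end),
                                       _substream(seed, 1, j, tr.trial_id)))
        all_times = np.concatenate(times) if times else np.zeros(0)
        all_times = np.unique(all_times)
        spikes.append(SpikeTrain(neuron_id=spec.neuron_id,
                                 session_id=config.session_id,
                                 spike_times_s=all_times,
                                 monkey=config.monkey))

    session = Session(session_id=config.session_id, trials=trials,
                      spikes=spikes, eyes=eyes, monkey=config.monkey,
                      hemisphere=config.hemisphere,
                      stimulation_session=config.stimulation_session)
    session.validate()
    return session
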