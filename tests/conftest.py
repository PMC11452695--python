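"""Shared fixtures: hand-built trial records and a small synthetic session."""

from __future__ import annotations

import numpy as np
import pytest

from sefpre.io_schema import Session, SpikeTrain, TrialRecord
from sefpre.synthetic import SyntheticConfig, generate_session


def make_choice_trial(trial_id: int = 0, cue_id: str = "L1",
                      angle: float = 0.0, direction: str = "L",
                      outcome: str = "success", t0: float = 10.0,
                      stim: bool = False) -> TrialRecord:
    """A choice trial with standard timing starting at ``t0``."""
    hemi = "L" if cue_id.startswith("L") else "R"
    return TrialRecord(
        trial_id=trial_id, task="choice", cue_id=cue_id,
        instructed_hemifield=hemi, target_angle_deg=angle,
        target_direction=direction,
        regular_trial=angle in (-45.0, 0.0, 45.0),
        t_fix_on=t0, t_fix_acquired=t0 + 0.2, t_cue_on=t0 + 1.2,
        t_cue_off=t0 + 1.9, t_targets_on=t0 + 2.4, t_go=t0 + 3.3,
        t_saccade_on=t0 + 3.5 if outcome in ("success", "wrong_choice") else None,
        t_reward=t0 + 3.95 if outcome == "success" else None,
        outcome=outcome, stim=stim)


def make_delayed_trial(trial_id: int, direction: str,
                       t0: float = 10.0) -> TrialRecord:
    return TrialRecord(
        trial_id=trial_id, task="delayed", cue_id=None,
        instructed_hemifield=None, target_angle_deg=None,
        target_direction=direction, regular_trial=False,
        t_fix_on=t0, t_fix_acquired=t0 + 0.2, t_cue_on=None, t_cue_off=None,
        t_targets_on=t0 + 1.2, t_go=t0 + 2.1, t_saccade_on=t0 + 2.3,
        t_reward=t0 + 2.75, outcome="success", stim=False)


@pytest.fixture(scope="session")
def mixed_session() -> Session:
    """One synthetic session with every archetype represented."""
    cfg = SyntheticConfig(
        n_neurons={"hemifield_spatial": 3, "hemifield_conceptual": 2,
                   "object_selective": 1, "angle_selective": 1,
                   "target_position": 2, "movement": 1, "null": 2},
        master_seed=11)
    return generate_session(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
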