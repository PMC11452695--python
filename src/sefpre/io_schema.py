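"""Session data model and tab-separated on-disk dialect.

A *session* is one recording (or stimulation) day: a table of behavioral
trials from the saccadic choice task and the visually guided delayed
saccade task, sorted spike-timestamp trains for each isolated neuron, and
240 Hz horizontal/vertical eye traces segmented per trial.

Conventions
-----------
* All times are seconds relative to session start, stored as doubles;
  per-trial alignment is always computed on the fly, never stored.
* Degrees of visual angle throughout; positive x is rightward, i.e.
  contralateral to a left-hemisphere recording.
* Trial ids are 0-based integers.
* On disk a session is three UTF-8 TSV tables (``trials.tsv``,
  ``spikes.tsv``, ``eye.tsv``); the trials table opens with a versioned
  comment header carrying the session metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FORMAT_VERSION = "sefpre-session v1"

#: The six canonical target directions on the 10-degree circle.
DIRECTIONS = ("RU", "R", "RD", "LD", "L", "LU")

#: Polar angle (deg, 0 = right, counterclockwise) of each direction.
DIRECTION_ANGLES = {"R": 0.0, "RU": 45.0, "LU": 135.0, "L": 180.0,
                    "LD": 225.0, "RD": 315.0}

LEFT_DIRECTIONS = frozenset({"LU", "L", "LD"})
RIGHT_DIRECTIONS = frozenset({"RU", "R", "RD"})

#: Fixed symbolic-cue -> instructed-hemifield mapping.
CUE_TO_HEMIFIELD = {"L1": "L", "L2": "L", "R1": "R", "R2": "R"}

CUES = ("L1", "L2", "R1", "R2")
REGULAR_ANGLES = (-45.0, 0.0, 45.0)
OUTCOMES = ("success", "wrong_choice", "fixation_break", "no_response")

#: Radius of the fixation window used by the task (deg).
FIXATION_WINDOW_DEG = 2.5


def direction_hemifield(direction: str) -> str:
    """Hemifield ('L' or 'R') containing a canonical direction."""
    if direction in LEFT_DIRECTIONS:
        return "L"
    if direction in RIGHT_DIRECTIONS:
        return "R"
    raise ValueError(f"unknown direction {direction!r}")


def targets_for_angle(angle_deg: float) -> tuple[str, str]:
    """(right, left) nearest canonical directions for a choice-target angle.

    The two choice targets sit diametrically opposite on the 10-degree
    circle; the right-hemifield target lies at polar angle ``angle_deg``
    and the left one at ``angle_deg + 180``.  Regular angles (-45, 0, 45)
    map exactly onto canonical directions; the additional angles
    (multiples of 5 degrees in +-5..40) map to the nearest one.
    """
    right = min(("RD", "R", "RU"),
                key=lambda d: abs(((DIRECTION_ANGLES[d] + 180) % 360) - 180
                                  - angle_deg))
    opposite = {"RD": "LU", "R": "L", "RU": "LD"}
    return right, opposite[right]


@dataclass
class TrialRecord:
    """One behavioral trial of either task."""

    trial_id: int
    task: str                      # 'choice' | 'delayed'
    cue_id: str | None             # L1/L2/R1/R2, None for delayed task
    instructed_hemifield: str | None   # 'L' | 'R', None for delayed task
    target_angle_deg: float | None     # choice-target line angle, None for delayed
    target_direction: str          # chosen (choice) / presented (delayed) target
    regular_trial: bool
    t_fix_on: float
    t_fix_acquired: float
    t_cue_on: float | None      # None for delayed-saccade trials (no cue)
    t_cue_off: float | None
    t_targets_on: float
    t_go: float
    t_saccade_on: float | None
    t_reward: float | None
    outcome: str
    stim: bool = False

    def validate(self) -> None:
        if self.task not in ("choice", "delayed"):
            raise ValueError(f"trial {self.trial_id}: bad task {self.task!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"trial {self.trial_id}: bad outcome {self.outcome!r}")
        if self.target_direction not in DIRECTIONS:
            raise ValueError(
                f"trial {self.trial_id}: bad direction {self.target_direction!r}")
        if self.task == "choice":
            if self.cue_id not in CUES:
                raise ValueError(f"trial {self.trial_id}: bad cue {self.cue_id!r}")
            if CUE_TO_HEMIFIELD[self.cue_id] != self.instructed_hemifield:
                raise ValueError(
                    f"trial {self.trial_id}: cue {self.cue_id} maps to "
                    f"{CUE_TO_HEMIFIELD[self.cue_id]}, not "
                    f"{self.instructed_hemifield}")
            if self.target_angle_deg is None:
                raise ValueError(f"trial {self.trial_id}: choice trial lacks angle")
            if self.regular_trial != (self.target_angle_deg in REGULAR_ANGLES):
                raise ValueError(
                    f"trial {self.trial_id}: regular_trial flag inconsistent "
                    f"with angle {self.target_angle_deg}")
        if self.t_cue_on is not None:
            if not (self.t_fix_acquired < self.t_cue_on < self.t_cue_off
                    < self.t_targets_on < self.t_go):
                raise ValueError(
                    f"trial {self.trial_id}: event times out of order")
        else:
            if self.task == "choice":
                raise ValueError(
                    f"trial {self.trial_id}: choice trial lacks cue times")
            if not (self.t_fix_acquired < self.t_targets_on < self.t_go):
                raise ValueError(
                    f"trial {self.trial_id}: event times out of order")
        if self.outcome in ("success", "wrong_choice"):
            if self.t_saccade_on is None or not self.t_saccade_on > self.t_go:
                raise ValueError(
                    f"trial {self.trial_id}: completed trial needs "
                    f"t_saccade_on > t_go")


@dataclass
class SpikeTrain:
    """Sorted spike timestamps of one isolated neuron in one session."""

    neuron_id: str
    session_id: str
    spike_times_s: np.ndarray
    monkey: str = ""
    site_xy_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)

    def validate(self) -> None:
        t = self.spike_times_s
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError(f"neuron {self.neuron_id}: spike times not "
                             "strictly increasing")
        if t.size and t[0] < 0:
            raise ValueError(f"neuron {self.neuron_id}: negative spike time")


@dataclass
class EyeTrace:
    """Per-trial eye position sampled at a fixed rate (nominally 240 Hz)."""

    trial_id: int
    sample_rate_hz: float
    t0_s: float
    x_deg: np.ndarray
    y_deg: np.ndarray

    def __post_init__(self) -> None:
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)

    def validate(self) -> None:
        if len(self.x_deg) != len(self.y_deg):
            raise ValueError(f"eye trace {self.trial_id}: x/y length mismatch")
        if not self.sample_rate_hz > 0:
            raise ValueError(f"eye trace {self.trial_id}: bad sample rate")

    @property
    def t_s(self) -> np.ndarray:
        """Sample times (s, session clock)."""
        return self.t0_s + np.arange(len(self.x_deg)) / self.sample_rate_hz


@dataclass
class Session:
    """One session: trials, spike trains, eye traces and metadata."""

    session_id: str
    trials: list[TrialRecord] = field(default_factory=list)
    spikes: list[SpikeTrain] = field(default_factory=list)
    eyes: list[EyeTrace] = field(default_factory=list)
    monkey: str = ""
    hemisphere: str = "L"
    stimulation_session: bool = False

    def validate(self) -> None:
        trial_ids = set()
        for tr in self.trials:
            tr.validate()
            if tr.trial_id in trial_ids:
                raise ValueError(f"duplicate trial id {tr.trial_id}")
            trial_ids.add(tr.trial_id)
        for st in self.spikes:
            st.validate()
        for ey in self.eyes:
            ey.validate()
            if ey.trial_id not in trial_ids:
                raise ValueError(
                    f"eye trace references absent trial id {ey.trial_id}")
        # cue -> hemifield must be a function within the session
        seen: dict[str, str] = {}
        for tr in self.trials:
            if tr.task == "choice":
                prev = seen.setdefault(tr.cue_id, tr.instructed_hemifield)
                if prev != tr.instructed_hemifield:
                    raise ValueError(
                        f"cue {tr.cue_id} maps to both hemifields")

    def trial_by_id(self, trial_id: int) -> TrialRecord:
        for tr in self.trials:
            if tr.trial_id == trial_id:
                return tr
        raise KeyError(trial_id)

    def eye_by_trial(self, trial_id: int) -> EyeTrace | None:
        for ey in self.eyes:
            if ey.trial_id == trial_id:
                return ey
        return None


# ---------------------------------------------------------------------------
# Trial selection


def select_trials(
    session: Session,
    *,
    task: str | None = None,
    outcome: str | None = "success",
    regular_only: bool = False,
    stim: bool | None = None,
    cue_id: str | None = None,
    hemifield: str | None = None,
    angle: float | None = None,
) -> list[TrialRecord]:
    """Order-preserving trial filter.

    ``outcome`` defaults to ``"success"`` because every neural analysis in
    the pipeline uses success trials only; pass ``outcome=None`` to keep
    all outcomes.  Contradictory predicates simply yield an empty list.
    """
    out: list[TrialRecord] = []
    for tr in session.trials:
        if task is not None and tr.task != task:
            continue
        if outcome is not None and tr.outcome != outcome:
            continue
        if regular_only and not tr.regular_trial:
            continue
        if stim is not None and tr.stim != stim:
            continue
        if cue_id is not None and tr.cue_id != cue_id:
            continue
        if hemifield is not None and tr.instructed_hemifield != hemifield:
            continue
        if angle is not None and (tr.target_angle_deg is None
                                  or tr.target_angle_deg != angle):
            continue
        out.append(tr)
    if not out:
        logger.info("select_trials: no trial matched the given predicates")
    return out


# ---------------------------------------------------------------------------
# TSV dialect

_TRIAL_COLS = [
    "trial_id", "task", "cue_id", "instructed_hemifield", "target_angle_deg",
    "target_direction", "regular_trial", "t_fix_on", "t_fix_acquired",
    "t_cue_on", "t_cue_off", "t_targets_on", "t_go", "t_saccade_on",
    "t_reward", "outcome", "stim",
]


def write_session(session: Session, directory: str | Path) -> list[Path]:
    """Write a validated session as trials/spikes/eye TSV tables.

    Returns the written file paths.  ``load_session`` on the result gives
    back a field-identical session up to float round-trip.
    """
    if not session.trials:
        raise ValueError("refusing to write a session with no trials")
    session.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    rows = []
    for tr in session.trials:
        rows.append({
            "trial_id": tr.trial_id, "task": tr.task, "cue_id": tr.cue_id,
            "instructed_hemifield": tr.instructed_hemifield,
            "target_angle_deg": tr.target_angle_deg,
            "target_direction": tr.target_direction,
            "regular_trial": int(tr.regular_trial),
            "t_fix_on": tr.t_fix_on, "t_fix_acquired": tr.t_fix_acquired,
            "t_cue_on": tr.t_cue_on, "t_cue_off": tr.t_cue_off,
            "t_targets_on": tr.t_targets_on, "t_go": tr.t_go,
            "t_saccade_on": tr.t_saccade_on, "t_reward": tr.t_reward,
            "outcome": tr.outcome, "stim": int(tr.stim),
        })
    trials_df = pd.DataFrame(rows, columns=_TRIAL_COLS)
    header = (f"# {FORMAT_VERSION}\tsession_id={session.session_id}"
              f"\tmonkey={session.monkey}\themisphere={session.hemisphere}"
              f"\tstimulation_session={int(session.stimulation_session)}\n")
    trials_path = directory / "trials.tsv"
    with open(trials_path, "w", encoding="utf-8") as fh:
        fh.write(header)
        trials_df.to_csv(fh, sep="\t", index=False)

    spike_rows = []
    for st in session.spikes:
        sx, sy = st.site_xy_mm if st.site_xy_mm is not None else (np.nan, np.nan)
        if st.spike_times_s.size == 0:
            # sentinel row so spikeless neurons survive the round trip
            spike_rows.append({"neuron_id": st.neuron_id, "monkey": st.monkey,
                               "site_x_mm": sx, "site_y_mm": sy,
                               "spike_time_s": np.nan})
        for t in st.spike_times_s:
            spike_rows.append({"neuron_id": st.neuron_id, "monkey": st.monkey,
                               "site_x_mm": sx, "site_y_mm": sy,
                               "spike_time_s": t})
    spikes_path = directory / "spikes.tsv"
    pd.DataFrame(
        spike_rows,
        columns=["neuron_id", "monkey", "site_x_mm", "site_y_mm", "spike_time_s"],
    ).to_csv(spikes_path, sep="\t", index=False)

    eye_rows = []
    for ey in session.eyes:
        eye_rows.append(pd.DataFrame({
            "trial_id": ey.trial_id,
            "sample_rate_hz": ey.sample_rate_hz,
            "t0_s": ey.t0_s,
            "sample_index": np.arange(len(ey.x_deg)),
            "x_deg": ey.x_deg,
            "y_deg": ey.y_deg,
        }))
    eye_path = directory / "eye.tsv"
    if eye_rows:
        pd.concat(eye_rows, ignore_index=True).to_csv(
            eye_path, sep="\t", index=False)
    else:
        pd.DataFrame(columns=["trial_id", "sample_rate_hz", "t0_s",
                              "sample_index", "x_deg", "y_deg"]
                     ).to_csv(eye_path, sep="\t", index=False)
    return [trials_path, spikes_path, eye_path]


def _none_if_nan(v):
    if v is None:
        return None
    if isinstance(v, float) and math.isnan(v):
        return None
    if isinstance(v, str) and v == "":
        return None
    return v


def load_session(directory: str | Path) -> Session:
    """Load and validate a session written by :func:`write_session`."""
    directory = Path(directory)
    trials_path = directory / "trials.tsv"
    spikes_path = directory / "spikes.tsv"
    eye_path = directory / "eye.tsv"
    for p in (trials_path, spikes_path, eye_path):
        if not p.exists():
            raise FileNotFoundError(f"missing session file: {p}")

    with open(trials_path, encoding="utf-8") as fh:
        header = fh.readline()
    if not header.startswith(f"# {FORMAT_VERSION}"):
        raise ValueError(f"unrecognized trials.tsv header: {header!r}")
    meta = dict(tok.split("=", 1) for tok in header.strip().split("\t")[1:])

    trials_df = pd.read_csv(trials_path, sep="\t", comment="#",
                            float_precision="round_trip")
    trials = []
    for row in trials_df.itertuples(index=False):
        angle = _none_if_nan(row.target_angle_deg)
        trials.append(TrialRecord(
            trial_id=int(row.trial_id),
            task=row.task,
            cue_id=_none_if_nan(row.cue_id),
            instructed_hemifield=_none_if_nan(row.instructed_hemifield),
            target_angle_deg=None if angle is None else float(angle),
            target_direction=row.target_direction,
            regular_trial=bool(row.regular_trial),
            t_fix_on=float(row.t_fix_on),
            t_fix_acquired=float(row.t_fix_acquired),
            t_cue_on=_none_if_nan(row.t_cue_on),
            t_cue_off=_none_if_nan(row.t_cue_off),
            t_targets_on=float(row.t_targets_on),
            t_go=float(row.t_go),
            t_saccade_on=_none_if_nan(row.t_saccade_on),
            t_reward=_none_if_nan(row.t_reward),
            outcome=row.outcome,
            stim=bool(row.stim),
        ))

    spikes_df = pd.read_csv(spikes_path, sep="\t", float_precision="round_trip")
    spikes = []
    if len(spikes_df):
        for neuron_id, grp in spikes_df.groupby("neuron_id", sort=False):
            times = grp["spike_time_s"].to_numpy(dtype=float)
            times = times[~np.isnan(times)]
            if not np.all(np.diff(times) > 0):
                raise ValueError(
                    f"neuron {neuron_id}: non-monotonic spike times on disk")
            sx = grp["site_x_mm"].iloc[0]
            site = None if math.isnan(sx) else (float(sx),
                                                float(grp["site_y_mm"].iloc[0]))
            spikes.append(SpikeTrain(
                neuron_id=str(neuron_id),
                session_id=meta.get("session_id", ""),
                spike_times_s=times,
                monkey=str(_none_if_nan(grp["monkey"].iloc[0]) or ""),
                site_xy_mm=site,
            ))

    eye_df = pd.read_csv(eye_path, sep="\t", float_precision="round_trip")
    eyes = []
    if len(eye_df):
        for trial_id, grp in eye_df.groupby("trial_id", sort=False):
            grp = grp.sort_values("sample_index")
            eyes.append(EyeTrace(
                trial_id=int(trial_id),
                sample_rate_hz=float(grp["sample_rate_hz"].iloc[0]),
                t0_s=float(grp["t0_s"].iloc[0]),
                x_deg=grp["x_deg"].to_numpy(dtype=float),
                y_deg=grp["y_deg"].to_numpy(dtype=float),
            ))

    session = Session(
        session_id=meta.get("session_id", ""),
        trials=trials,
        spikes=spikes,
        eyes=eyes,
        monkey=meta.get("monkey", ""),
        hemisphere=meta.get("hemisphere", "L"),
        stimulation_session=bool(int(meta.get("stimulation_session", "0"))),
    )
    session.validate()
    return session
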