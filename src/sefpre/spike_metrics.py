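"""Aligned windowed measures derived from spike trains.

The instantaneous rate measure used throughout is the inverse interspike
interval (iISI): between two consecutive spikes the rate is the reciprocal
of that interval; before the first and after the last spike of a trial it
is zero, and trains with fewer than two spikes carry no rate at all.  A
window's value is the *time average* of this step function over the
window, which has a convenient closed form: the cumulative integral of the
iISI jumps by exactly 1 over each interspike interval, so it is the
piecewise-linear "fractional interval count" interpolated between spikes.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .io_schema import TrialRecord

logger = logging.getLogger(__name__)

#: Alignment events a window grid may reference on a TrialRecord.
ALIGN_EVENTS = {
    "fix_acquired": "t_fix_acquired",
    "cue_on": "t_cue_on",
    "targets_on": "t_targets_on",
    "saccade_on": "t_saccade_on",
    "go": "t_go",
}


@dataclass(frozen=True)
class WindowGrid:
    """A sliding-window grid anchored to a trial event.

    Offsets are in seconds relative to the event; windows are half-open
    ``[start, start + width)`` and advance by ``step``.
    """

    align_event: str
    start_s: float
    stop_s: float
    width_s: float = 0.010
    step_s: float = 0.010

    def __post_init__(self) -> None:
        if self.align_event not in ALIGN_EVENTS:
            raise ValueError(f"unknown align event {self.align_event!r}")
        if self.width_s <= 0 or self.step_s <= 0:
            raise ValueError("window width and step must be positive")
        if self.start_s >= self.stop_s:
            raise ValueError("grid start must precede stop")

    @property
    def n_windows(self) -> int:
        return int(np.floor((self.stop_s - self.start_s - self.width_s)
                            / self.step_s + 1e-9)) + 1

    @property
    def starts(self) -> np.ndarray:
        """Event-relative window start offsets."""
        return self.start_s + self.step_s * np.arange(self.n_windows)

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.width_s / 2

    def event_time(self, trial: TrialRecord) -> float | None:
        return getattr(trial, ALIGN_EVENTS[self.align_event])


@dataclass
class IISISeries:
    """Trial x window matrix of mean iISI values (s^-1) for one neuron."""

    neuron_id: str
    grid: WindowGrid
    values: np.ndarray
    trial_ids: list[int]


@dataclass
class NormalizationRecord:
    """Min-max range used to map a neuron's rate onto [0, 1]."""

    fr_min: float
    fr_max: float
    normalizable: bool


def iisi_function(spike_times: np.ndarray):
    """Step function t -> iISI(t) for one trial's sorted spike times.

    Returns a vectorized callable.  Strictly between consecutive spikes
    s_i < t < s_{i+1} the value is 1/(s_{i+1} - s_i); outside the span of
    the train (or for trains with < 2 spikes) it is 0.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("spike times must be strictly increasing")
    if t.size < 2:
        return lambda x: np.zeros_like(np.asarray(x, dtype=float))
    rates = 1.0 / np.diff(t)

    def f(x):
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(t, x, side="right") - 1
        inside = (idx >= 0) & (idx < rates.size) & (x > t[0]) & (x < t[-1])
        out = np.zeros_like(x)
        out[inside] = rates[idx[inside]]
        return out

    return f


def _iisi_cumulative(spikes: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Integral of the iISI step function from -inf to each query time."""
    if spikes.size < 2:
        return np.zeros_like(query)
    counts = np.arange(spikes.size, dtype=float)
    return np.interp(query, spikes, counts, left=0.0, right=counts[-1])


def windowed_iisi(
    spike_times: np.ndarray,
    trials: list[TrialRecord],
    grid: WindowGrid,
    neuron_id: str = "",
) -> IISISeries:
    """Mean iISI of one neuron in every grid window of every trial.

    Trials missing the grid's alignment event are dropped with a warning.
    """
    spikes = np.asarray(spike_times, dtype=float)
    if spikes.size and np.any(np.diff(spikes) <= 0):
        raise ValueError("spike times must be strictly increasing")
    starts = grid.starts
    kept: list[int] = []
    rows = []
    for tr in trials:
        ev = grid.event_time(tr)
        if ev is None:
            logger.warning("trial %d lacks event %s; dropped",
                           tr.trial_id, grid.align_event)
            continue
        a = ev + starts
        b = a + grid.width_s
        fa = _iisi_cumulative(spikes, a)
        fb = _iisi_cumulative(spikes, b)
        rows.append((fb - fa) / grid.width_s)
        kept.append(tr.trial_id)
    values = np.asarray(rows, dtype=float).reshape(len(kept), grid.n_windows)
    return IISISeries(neuron_id=neuron_id, grid=grid, values=values,
                      trial_ids=kept)


def spike_count(
    spike_times: np.ndarray,
    trial: TrialRecord,
    window: tuple[float, float],
    align_event: str = "targets_on",
) -> int:
    """Spike count in the half-open event-relative window [a, b)."""
    a, b = window
    if not a < b:
        raise ValueError("window start must precede stop")
    ev = getattr(trial, ALIGN_EVENTS[align_event])
    if ev is None:
        raise ValueError(
            f"trial {trial.trial_id} lacks event {align_event}")
    t = np.asarray(spike_times, dtype=float)
    return int(np.count_nonzero((t >= ev + a) & (t < ev + b)))


def spike_counts_matrix(
    spike_times: np.ndarray,
    trials: list[TrialRecord],
    grid: WindowGrid,
) -> np.ndarray:
    """Trial x window spike-count matrix on a grid (half-open windows)."""
    t = np.asarray(spike_times, dtype=float)
    starts = grid.starts
    out = np.zeros((len(trials), grid.n_windows))
    for i, tr in enumerate(trials):
        ev = grid.event_time(tr)
        if ev is None:
            raise ValueError(
                f"trial {tr.trial_id} lacks event {grid.align_event}")
        a = ev + starts
        out[i] = (np.searchsorted(t, a + grid.width_s, side="left")
                  - np.searchsorted(t, a, side="left"))
    return out


def normalize_activity(
    condition_series: dict[str, np.ndarray],
) -> tuple[dict[str, np.ndarray], NormalizationRecord]:
    """Min-max normalize a neuron's rate series across conditions.

    The minimum and maximum are taken jointly over all condition series
    (the full task range supplied by the caller), and the same affine map
    (FR_t - FR_min) / (FR_max - FR_min) is applied to every condition, so
    the global minimum maps to 0 and the global maximum to 1.  A constant
    neuron is flagged non-normalizable and returned unchanged.
    """
    allv = np.concatenate([np.ravel(v) for v in condition_series.values()])
    fr_min = float(np.min(allv))
    fr_max = float(np.max(allv))
    if fr_max <= fr_min:
        return dict(condition_series), NormalizationRecord(fr_min, fr_max, False)
    scale = fr_max - fr_min
    out = {k: (np.asarray(v, dtype=float) - fr_min) / scale
           for k, v in condition_series.items()}
    return out, NormalizationRecord(fr_min, fr_max, True)


def spike_density(spike_times: np.ndarray, kernel_sigma_s: float = 0.020):
    """Gaussian-kernel spike density function (visualization only).

    Returns a callable rate function whose integral over the real line
    equals the number of spikes.
    """
    if kernel_sigma_s <= 0:
        raise ValueError("kernel sigma must be positive")
    t = np.asarray(spike_times, dtype=float)
    norm = 1.0 / (kernel_sigma_s * np.sqrt(2 * np.pi))

    def f(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if t.size == 0:
            return np.zeros_like(x)
        z = (x[:, None] - t[None, :]) / kernel_sigma_s
        return norm * np.exp(-0.5 * z ** 2).sum(axis=1)

    return f
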