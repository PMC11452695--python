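"""Time-resolved classification of neurons by task factor.

Each neuron's windowed iISI (10 ms windows, 10 ms step) on regular
success trials of the saccadic choice task is classified window by window
into one of six categories by a two-stage set of two-way ANOVAs:

* Stage 1 (alpha = 0.005 per cue pair) asks whether activity depends on
  the *visual identity* of the symbolic cue.  For each hemifield's cue
  pair (L1 vs L2, R1 vs R2) a two-way ANOVA with object and choice-target
  angle (-45/0/45 deg) as factors is run.  A significant object main
  effect in either pair labels the window ``object``; object and angle
  main effects together, or their interaction, label it
  ``object_and_choice`` (which takes precedence).

* Stage 2 (alpha = 0.01), run only when stage 1 assigned nothing, is a
  two-way ANOVA with instructed hemifield and angle as factors:
  hemifield-only -> ``potential_space``; angle-only -> ``choice_targets``;
  both mains or the interaction -> ``target_position``; else ``none``.

A category is only retained where it persists for at least three
consecutive windows; shorter runs become ``none``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spike_metrics import IISISeries, WindowGrid
from .stats import fdr_bh, two_way_anova_matrix  # noqa: F401  (fdr re-export)

CATEGORIES = ("object", "object_and_choice", "potential_space",
              "choice_targets", "target_position", "none")

ALPHA_STAGE1 = 0.005
ALPHA_STAGE2 = 0.01
MIN_RUN = 3


@dataclass
class WindowAnovaResult:
    """Per-window p-values of both ANOVA stages and the raw category."""

    p_object: dict[str, float]       # per cue pair: 'L', 'R'
    p_object_angle: dict[str, float]
    p_object_int: dict[str, float]
    p_hemi: float
    p_angle: float
    p_int: float
    raw_category: str
    diagnostic: str | None = None


@dataclass
class FactorLabelTrack:
    """Per-window raw and persistence-filtered category labels."""

    neuron_id: str
    grid: WindowGrid
    raw_labels: list[str]
    labels: list[str]
    results: list[WindowAnovaResult] = field(default_factory=list)


@dataclass
class TrialFactors:
    """Per-trial design labels for the classification ANOVAs."""

    cue_id: list[str]
    hemifield: list[str]
    angle: list[float]

    @classmethod
    def from_trials(cls, trials) -> "TrialFactors":
        return cls(cue_id=[t.cue_id for t in trials],
                   hemifield=[t.instructed_hemifield for t in trials],
                   angle=[t.target_angle_deg for t in trials])


def _stage_categories(p_obj, p_ang, p_int, p_hemi2, p_ang2, p_int2):
    """Vectorized category decision for arrays of window p-values."""
    n = p_hemi2.shape[-1]
    cats = np.full(n, "none", dtype=object)

    sig1 = lambda p: np.nan_to_num(p, nan=1.0) <= ALPHA_STAGE1
    obj_main = np.zeros(n, dtype=bool)
    obj_and_choice = np.zeros(n, dtype=bool)
    for pair in ("L", "R"):
        o, a, i = sig1(p_obj[pair]), sig1(p_ang[pair]), sig1(p_int[pair])
        obj_main |= o
        obj_and_choice |= (o & a) | i
    cats[obj_main] = "object"
    cats[obj_and_choice] = "object_and_choice"   # precedence over object

    stage2_open = ~(obj_main | obj_and_choice)
    sig2 = lambda p: np.nan_to_num(p, nan=1.0) <= ALPHA_STAGE2
    h, a, i = sig2(p_hemi2), sig2(p_ang2), sig2(p_int2)
    cats[stage2_open & h & ~a & ~i] = "potential_space"
    cats[stage2_open & a & ~h & ~i] = "choice_targets"
    cats[stage2_open & ((h & a) | i)] = "target_position"
    return cats


def classify_windows(iisi: IISISeries, factors: TrialFactors) -> FactorLabelTrack:
    """Raw per-window classification of one neuron (no persistence filter).

    ``iisi`` must hold regular success trials only; ``factors`` gives the
    matching per-trial cue, hemifield and angle labels.
    """
    Y = np.asarray(iisi.values, dtype=float)
    cue = np.asarray(factors.cue_id, dtype=object)
    hemi = np.asarray(factors.hemifield, dtype=object)
    angle = np.asarray(factors.angle, dtype=float)
    if not (len(cue) == len(hemi) == len(angle) == Y.shape[0]):
        raise ValueError("factor labels do not match the iISI trial count")
    n_win = Y.shape[1]

    nanrow = np.full(n_win, np.nan)
    p_obj, p_ang1, p_int1 = {}, {}, {}
    diagnostic = None
    for pair, cues in (("L", ("L1", "L2")), ("R", ("R1", "R2"))):
        sel = np.isin(cue, cues)
        try:
            res = two_way_anova_matrix(Y[sel], cue[sel], angle[sel])
            p_obj[pair], p_ang1[pair], p_int1[pair] = \
                res["p_a"], res["p_b"], res["p_int"]
        except ValueError as exc:
            p_obj[pair] = p_ang1[pair] = p_int1[pair] = nanrow
            diagnostic = f"stage-1 pair {pair}: {exc}"
    try:
        res2 = two_way_anova_matrix(Y, hemi, angle)
        p_hemi, p_ang2, p_int2 = res2["p_a"], res2["p_b"], res2["p_int"]
    except ValueError as exc:
        p_hemi = p_ang2 = p_int2 = nanrow
        diagnostic = f"stage-2: {exc}"

    cats = _stage_categories(p_obj, p_ang1, p_int1, p_hemi, p_ang2, p_int2)
    results = [
        WindowAnovaResult(
            p_object={p: float(p_obj[p][w]) for p in ("L", "R")},
            p_object_angle={p: float(p_ang1[p][w]) for p in ("L", "R")},
            p_object_int={p: float(p_int1[p][w]) for p in ("L", "R")},
            p_hemi=float(p_hemi[w]), p_angle=float(p_ang2[w]),
            p_int=float(p_int2[w]), raw_category=str(cats[w]),
            diagnostic=diagnostic)
        for w in range(n_win)
    ]
    raw = [str(c) for c in cats]
    return FactorLabelTrack(neuron_id=iisi.neuron_id, grid=iisi.grid,
                            raw_labels=raw, labels=raw.copy(),
                            results=results)


def classify_window(values: np.ndarray, factors: TrialFactors) -> WindowAnovaResult:
    """Classify a single window (vector of per-trial mean iISI values)."""
    series = IISISeries(neuron_id="", grid=WindowGrid("cue_on", 0.0, 0.010),
                        values=np.asarray(values, dtype=float)[:, None],
                        trial_ids=list(range(len(values))))
    return classify_windows(series, factors).results[0]


def persistence_filter(labels: list[str], min_run: int = MIN_RUN) -> list[str]:
    """Replace runs shorter than ``min_run`` identical windows with 'none'."""
    out = list(labels)
    n = len(out)
    i = 0
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        if out[i] != "none" and (j - i) < min_run:
            for k in range(i, j):
                out[k] = "none"
        i = j
    return out


def classify_neuron(iisi: IISISeries, factors: TrialFactors,
                    min_run: int = MIN_RUN) -> FactorLabelTrack:
    """Full per-neuron classification: raw ANOVA labels + persistence rule."""
    track = classify_windows(iisi, factors)
    track.labels = persistence_filter(track.raw_labels, min_run)
    return track


def population_fractions(tracks: list[FactorLabelTrack]) -> dict[str, np.ndarray]:
    """Per-window fraction of neurons carrying each persistent category."""
    if not tracks:
        raise ValueError("population_fractions needs at least one track")
    grid = tracks[0].grid
    if any(t.grid != grid for t in tracks):
        raise ValueError("tracks do not share a window grid")
    n_win = grid.n_windows
    lab = np.array([t.labels for t in tracks], dtype=object)
    return {cat: (lab == cat).mean(axis=0)
            for cat in CATEGORIES if cat != "none"}


def summarize_epochs(track: FactorLabelTrack,
                     epochs: dict[str, tuple[float, float]]
                     ) -> dict[str, dict[str, bool]]:
    """Whether the neuron carried each category during each epoch.

    ``epochs`` maps epoch name to an event-relative [start, stop) interval
    on the track's grid; a category counts if any persistent-labeled
    window overlaps the epoch.
    """
    starts = track.grid.starts
    ends = starts + track.grid.width_s
    out: dict[str, dict[str, bool]] = {}
    for name, (a, b) in epochs.items():
        if b <= starts[0] or a >= ends[-1]:
            raise ValueError(f"epoch {name!r} outside the grid coverage")
        inside = (ends > a) & (starts < b)
        labels = np.array(track.labels, dtype=object)[inside]
        out[name] = {cat: bool(np.any(labels == cat))
                     for cat in CATEGORIES if cat != "none"}
    return out
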