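# sefpre

Analysis pipeline for single-unit and behavioral data from the
supplementary eye field (SEF) recorded while monkeys preselect a *region*
of visual space — a potential target space — from a foveal symbolic cue,
before any saccade target exists.

## The scientific problem

In the saccadic choice task, a colored shape at fixation (one of four
symbolic cues, `L1 L2 R1 R2`) instructs the animal to later choose a
target in the left or right hemifield. After a 700 ms cue and a 500 ms
delay (the *preselection period*), two choice targets appear at mirror
positions on a 10° circle, their connecting line tilted at an angle
between −45° and 45° (the *target determination period*); the specific
target becomes identifiable only then. A separate visually guided delayed
saccade task with six target directions (`RU R RD LD L LU`) characterizes
each neuron's preferred direction (PD) and visual/movement response
profile.

The package implements the complete analysis chain for this paradigm:

* **Windowed iISI metrics** — spiking converted to inverse-interspike-
  interval rate, averaged in 10 ms sliding windows aligned to task events.
* **Two-stage factor classification** — per window, two-way ANOVAs first
  test cue *identity* within each hemifield pair (object × angle,
  α = 0.005); only windows without object selectivity proceed to
  hemifield × angle (α = 0.01), labeling each window `object`,
  `object_and_choice`, `potential_space`, `choice_targets`,
  `target_position` or `none`. A label must persist in ≥ 3 consecutive
  windows to count.
* **PD-referenced population analysis** — PD from a one-way ANOVA on
  0–300 ms post-target spike counts (unique argmax); trials split into
  PD-included vs PD-opposite; min–max normalization
  (FR_t − FR_min)/(FR_max − FR_min); per-window ROC analysis with AUC,
  a 1000-permutation label-shuffle null and an across-neuron
  signed-rank test, Benjamini–Hochberg corrected; signed neuron counts
  compared with exact binomial tests; direction × time tuning matrices
  rotated so PDs align, with Up/Down interpolated on an 8-point circular
  grid; Rayleigh test of PD uniformity.
* **Eye-position confound analysis** — baseline-subtracted, cue-aligned
  eye traces; divergence onset by pointwise paired t-tests (α = 0.01
  sustained ≥ 20 ms); per-trial shift classification at the session's
  maximal-difference timepoint; hemifield × eye-shift two-way ANOVAs on
  activity; and the disentangling regressions
  `count = β_hemi·hemi + ε` vs
  `count = β_hemi,eye·hemi + β_eye·eye + ε` with shuffle nulls.
* **Stimulation statistics** — correct-rate comparisons between and
  within stimulation sessions (two-sample / paired t with Cohen's d) and
  a stimulation × trial-type ANOVA on fixational eye position (η²).
* **Synthetic session generator** — inhomogeneous-Poisson neurons (von
  Mises direction tuning, sustained hemifield gain, object/angle gains,
  peri-saccadic bumps), Ornstein–Uhlenbeck fixational drift with a small
  (~0.14°) instructed-side bias emerging ~0.17 s after cue onset, and
  stimulation-induced contralateral drift plus an ipsilateral error
  increase — fully reproducible from one master seed.

## Worked example

```python
import json
from sefpre import SyntheticConfig, generate_session, run_full_analysis
from sefpre.pipeline import summarize_report

cfg = SyntheticConfig(
    n_neurons={"hemifield_spatial": 6, "hemifield_conceptual": 4,
               "target_position": 4, "movement": 2, "null": 4},
    master_seed=7)
report = run_full_analysis(generate_session(cfg), seed=1,
                           n_perm=300, n_shuffle=300)
print(json.dumps(summarize_report(report), indent=2, sort_keys=True))
```

prints

```json
{
  "fraction_both": 0.3,
  "fraction_potential_space_preselection": 0.5,
  "fraction_target_position_determination": 0.5,
  "fraction_with_pd": 0.5,
  "n_neurons": 20,
  "n_significant_auc_windows": 12,
  "n_type_movement": 3,
  "n_type_none": 7,
  "n_type_visual": 10,
  "n_type_visuomovement": 0,
  "pd_uniformity_p": 1.0,
  "provenance": {"n_perm": 300, "n_shuffle": 300, "seed": 1,
                 "version": "0.1.0"},
  "sessions": ["synthetic"]
}
```

Half the cohort (the 10 hemifield-selective neurons of 20) carries a
persistent `potential_space` label during the preselection period, and
half (the direction-tuned neurons) a `target_position` label after the
choice targets appear; `fraction_both` is the subset doing both in
sequence. Ten neurons have a PD (spatial + target-position archetypes),
distributed uniformly over the six directions (Rayleigh p = 1.0), and 12
of the 14 100-ms windows show population AUC above the shuffle null —
the PD-included > PD-opposite activity difference during cue and delay.

A command-line interface wraps the same chain:

```sh
sefpre simulate --config cfg.yaml --seed 2 --out session/
sefpre run --session session/ --seed 2 --perms 1000 --out report/
```

`run` writes `tracks.tsv`, `pd.tsv`, `types.tsv`, `auc.tsv`,
`eye_summary.tsv` and `report.json`.

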