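# Methods

This note documents the models, statistical procedures and design
choices behind `sefpre`, in the order data flow through the pipeline.

## Task and data model

A session holds trials of two oculomotor tasks. In the **saccadic choice
task** a symbolic cue (`L1`/`L2` → left, `R1`/`R2` → right) instructs a
hemifield; after the cue (700 ms; 120 ms in stimulation sessions) and a
500 ms delay, two choice targets appear at diametrically opposite points
of a 10° circle, their connecting line at an angle of −45°…45° in 5°
steps. Blocks contain 12 regular trials (4 cues × angles −45/0/45) and 4
additional trials at other angles; the regular angles are the only ones
entering angle-factor statistics. In the **visually guided delayed
saccade task** a single target appears at one of six directions
(`RU R RD LD L LU`, polar angles 45/0/315/225/180/135°). Left hemifield =
{LU, L, LD}; positive x = rightward = contralateral to a left-hemisphere
recording. All times are seconds on the session clock; alignment is
computed, never stored. Only success trials enter neural analyses.

## Windowed iISI

Instantaneous rate is the inverse interspike interval: between
consecutive spikes the rate is 1/ISI, zero before the first and after
the last spike of a trial, and identically zero for trains with fewer
than two spikes (the treatment of the leading/trailing interval is
isolated in one function so an alternative convention can be swapped).
A window's value is the time average of this step function. Because the
integral of the iISI rises by exactly 1 per interspike interval, the
cumulative integral is the piecewise-linear interpolant of the spike
index over spike times, which makes windowed means exact and cheap
(`np.interp` at window edges, no discretization). Window membership for
spike *counts* is half-open [a, b), so counts are additive over
partitions.

One property worth knowing: per-trial window iISI values are heavy
tailed (the value inside a long interval is the reciprocal of a
length-biased exponential), so per-window F-tests at 10 ms resolution
have modest power and behave conservatively. The persistence rule below
is what turns weak per-window evidence into reliable labels.

## Two-stage factor classification

For each neuron, regular success choice trials are classified per 10 ms
window (step 10 ms):

1. **Stage 1, α = 0.005 per cue pair.** For each hemifield's cue pair
   (L1 vs L2; R1 vs R2), a two-way ANOVA with object and choice-target
   angle (−45/0/45) as factors. Object main effect in ≥ 1 pair →
   `object`; object *and* angle mains, or their interaction →
   `object_and_choice` (precedence over `object`, since such a window
   conveys both factors).
2. **Stage 2, α = 0.01**, only where stage 1 assigned nothing: two-way
   ANOVA with instructed hemifield and angle. Hemifield-only →
   `potential_space`; angle-only → `choice_targets`; both mains or the
   interaction → `target_position`; otherwise `none`.
3. **Persistence:** a label counts only when the same raw category holds
   in ≥ 3 consecutive windows; shorter runs become `none`. The filter is
   idempotent. No multiplicity correction is applied across windows —
   the persistence rule is the control at this stage.

ANOVAs use type-II sums of squares computed by projection (QR bases of
the nested design matrices applied to the whole trial × window response
matrix at once; the trials, hence the projections, are shared by all
windows of a neuron). The implementation is verified against
`statsmodels.anova_lm(typ=2)` in the tests. Windows with zero residual
variance (e.g. all-zero iISI) and windows whose design has an empty cell
are labeled `none` with a diagnostic.

Grid defaults: cue-aligned [−0.2, 1.2] s and targets-aligned
[−0.2, 0.75] s. The *preselection* epoch is cue onset → targets onset on
the cue grid; *target determination* is targets onset → go on the
targets grid. Epoch membership uses an any-overlap rule on persistent
labels. The spans are package defaults, configurable per grid.

## PD and population contrasts

* **PD:** one-way ANOVA (α = 0.05) on 0–300 ms post-target spike counts
  across the six delayed-task directions; the PD is the unique argmax of
  the per-direction means — a tied maximum yields no PD.
* **Neuron typing:** one-sided Wilcoxon signed-rank (α = 0.05 each) on
  paired counts: visual-related = 0–300 ms after vs 300–0 ms before
  target onset; saccade-related = −100…50 ms around vs −350…−200 ms
  before saccade onset. Visual ∧ ¬movement → visual; both →
  visuomovement; movement ∧ ¬visual → movement; else none. scipy's
  automatic exact/normal switch is used; all-zero difference sets are
  non-significant by convention.
* **PD-included/opposite:** choice trials grouped by whether the
  instructed hemifield contains the PD.
* **AUC tracks:** per 100 ms window, the Mann–Whitney probability
  (ties = ½) that a PD-included count exceeds a PD-opposite count,
  against a null built by permuting the trial–condition correspondence
  (default 1000, minimum 100 permutations). The population test compares
  observed vs null-mean AUC across neurons per window — Wilcoxon
  signed-rank by default, paired t optionally — with Benjamini–Hochberg
  across windows at α = 0.05.
* **Signed counts:** per neuron and window a two-sample t-test (α =
  0.05) with its sign; per window, the counts of neurons preferring each
  condition meet an exact two-sided binomial test against ½, BH across
  windows. Zero significant neurons gives p = 1.
* **Normalization:** (FR_t − FR_min)/(FR_max − FR_min) with the extremes
  taken jointly over both conditions across the whole task range;
  constant neurons are flagged non-normalizable and excluded from
  population averages.
* **Tuning matrices:** 200 ms windows, 10 ms step, 6 directions × time.
  For the population, pre-target rows are reordered PD-included-hemifield
  first; post-target rows are placed on an 8-point, 45°-spaced circular
  grid rotated so the PD sits at 0°, with the unsampled Up/Down slots
  linearly interpolated from their neighbors.
* **PD uniformity:** Rayleigh test (via `pingouin.circ_rayleigh`) on the
  PDs' polar angles.

FDR control is Benjamini–Hochberg throughout (the field default when a
procedure is not otherwise specified). Effect sizes: Cohen's d with
pooled SD for two-sample contrasts, mean/SD of differences for paired
ones (matching the dof structure of the reported t statistics), and
η² = SS_effect/SS_total for ANOVAs.

## Eye analysis

Per trial, the mean over the 0.5 s before cue onset is subtracted; trials
are cue-aligned, averaged per instructed hemifield, and both condition
means are normalized by subtracting their grand mean. Divergence onset
across sessions is the first run of pointwise paired t-tests (α = 0.01)
significant for at least 20 ms (a 10 ms threshold is also exposed; both
conventions appear in the field, and the stricter one is the default).
Per-trial shift direction is the sign of the baseline-subtracted
horizontal position at the session's maximal L/R-difference timepoint;
an exact zero falls through to the next sample (documented deterministic
tie rule).

The disentangling regressions use z-scored variables per 100 ms window:
`β_hemi` is then the correlation of counts with the PD-condition code
(+1 included / −1 opposite), and `β_hemi,eye`, `β_eye` are standardized
coefficients of the two-regressor OLS. With standardized OLS (not
partial correlations) the hemifield coefficient is unbiased under
correlated regressors, which is exactly what makes the comparison
meaningful: eye-independent coding leaves β_hemi,eye ≈ β_hemi, while
eye-driven activity collapses β_hemi,eye toward 0 with β_eye ≠ 0.
Collinearity |r| > 0.999 flags the window unstable. Nulls permute the
activity rows (1000 default). Population comparisons: β_hemi vs
β_hemi,eye by paired t (the direct contrast), each against its shuffle
null by one-sided signed-rank, BH across windows.

## Stimulation statistics

Correct rate = successes / completed choices. (i) Session-level rates,
stimulation vs control sessions: two-sample t, pooled-SD d. (ii) Within
stimulation sessions, stim vs non-stim trials separately for ipsi- and
contralateral instructions: paired t across sessions, d from the
difference distribution. (iii) Two-way ANOVA (stimulation × trial type)
on the baseline-subtracted horizontal eye position averaged over
0.35–0.45 s after cue onset (configurable), η² per effect. The 120 ms
stimulation-session cue duration is read from the trial timestamps, not
assumed.

## Synthetic generator

The generator emulates the statistical structure the analyses assume,
not biophysics. Spiking is an inhomogeneous Poisson process sampled by
thinning (refractoriness would not change rank/ANOVA statistics at these
rates; the thinning output is checked against a time-rescaling sampler).
The rate model is

λ(t) = baseline · H(t) · (1 + vis_gain · f_dir · k_vis(t − t_targets))
· (1 + det_gain · f_dir) · O(cue) · A(angle) · E(eye)
+ mov_gain · k_mov(t − t_saccade)

with f_dir a von Mises tuning curve normalized to 1 at the PD; H the
sustained hemifield gain on [cue on, targets on) when the instructed
hemifield matches the neuron's preferred side; k_vis a transient with
80 ms latency, 150 ms plateau and 200 ms exponential decay; det_gain a
sustained direction-tuned elevation from 80 ms after target onset until
the go signal (SEF neurons hold tuned activity through the delay — a
transient alone gives unrealistically flickery window labels); O and A
per-cue and per-angle multipliers; E an optional multiplicative coupling
to horizontal eye position (the control archetype for the regression
analysis); k_mov a Gaussian bump (σ = 40 ms) peaking 20 ms before
saccade onset. The unchosen choice target adds a half-weight transient
(configurable), mimicking responses to distractors in the PD.

Defaults, chosen once by power reasoning at the study's conditions:
baseline 10 Hz; vis_gain 3 and κ = 2.5 (strong but broadly tuned visual
transients, as typical for SEF); hemi_gain 2; det_gain 2; mov_gain
30 Hz. Archetypes: `hemifield_spatial` (PD + sustained hemifield gain),
`hemifield_conceptual` (side preference without direction tuning),
`object_selective`, `angle_selective`, `target_position` (tuned but no
preselection gain), `movement`, `null`.

Eye traces are a stationary Ornstein–Uhlenbeck drift (σ = 0.06°,
τ = 0.4 s — small fixational drift) plus an instructed-side bias of
0.14° ramping in from 0.17 s after cue onset over 0.2 s, the side
flipped per trial with probability 0.25 (the middle of the observed
11–42% opposite-shift range); stimulated trials add a contralateral ramp
(0.1° default). Traces are clipped to the 2.5° fixation window. Task
structure: 12 + 4 trial types per block, shuffled (stimulation sessions
double each type with a stimulated copy); outcomes are sampled (fixation
breaks first, then correct with p_correct among completed choices, minus
the stimulation-induced ipsilateral decrement), which emulates the
re-queueing of failed types without modeling it. Determinism comes from
counter-based substreams: `default_rng([master_seed, stream, index])`
per trial, per neuron × trial, and per eye trace.

What the generator does **not** emulate — and hence what passing
recovery tests cannot show about recorded data: non-Poisson spiking
statistics (bursting, refractoriness, rate drifts across the session),
correlated noise across neurons, microsaccades and saccadic intrusions
in the eye signal, session-to-session heterogeneity of effect sizes, and
any systematic relation between neural activity and saccade metrics.

## Verification sizes and numerical choices

The test suite checks the core statistics against literal-definition
oracles (exhaustive pair enumeration for AUC, a hand-walked step-up rule
for FDR, direct binomial summation), calibrates the classifier on 500
null-model neurons (the per-window stage-2 false-label rate stays under
the 3 × 0.01 union bound; the persistent-label false-positive fraction
is bounded by an independent Monte-Carlo replication of the null
pipeline, because adjacent 10 ms iISI windows are strongly dependent and
no independent-window bound applies), and verifies parameter recovery on
200-neuron cohorts (hemifield gain 1.5 recovered as `potential_space`
in ≥ 90%, exact PD recovery ≥ 95%, eye-bias onset within ±30 ms,
opposite-shift proportion within binomial uncertainty) plus regression
disentanglement (100 neurons) and stimulation-effect recovery (16 + 16
sessions). These sizes keep the whole suite around half a minute while
leaving the binomial margins comfortable.

Numerical details: F-tests guard zero residual variance with a relative
threshold (1e−12 × mean square); negative sums of squares from floating
cancellation are clipped at 0; AUC uses midranks; BH never rejects NaN
p-values and excludes them from the test count; thinning validates the
supplied rate bound and rejects unbounded profiles; TSV round trips use
shortest-repr floats with round-trip parsing, so write → load is exact.

## Known limitations

* The exact epoch spans and the stitch between cue- and saccade-aligned
  grids in time-resolved displays are package defaults, not canonical.
* The iISI convention outside the first/last spike (set to 0 here) is a
  documented choice; alternatives exist.
* With small cohorts (< ~20 neurons with a PD) the across-neuron
  signed-rank tests have little resolution; population flags should be
  read accordingly.
* The import surface reads only the package's TSV dialect; adapters for
  other acquisition formats must map onto the `Session` schema.
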