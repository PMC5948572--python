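# Methods

This note documents the models, defaults and design choices behind
`fallban`, and what the synthetic study conditions do and do not show.

## Trial model and log dialect

A trial is one 15 s execution of one of 14 movement types: 11 ADLs
(applauding, raising both arms, emulating a phone call, opening a
door, sitting on a chair and getting up, walking, bending, hopping,
lying down on / standing up from a bed, going up/down stairs, jogging)
and 3 falls (forwards, backwards, lateral). Up to five sensing points
report triaxial acceleration in g: motes at chest, waist, wrist and
ankle sampling at 20 Hz, plus a smartphone in a trouser pocket at
200 Hz. Mote axes are mounted with X along gravity in upright rest;
the phone's vertical axis is Y. Log files are plain text, one trial
per file: `%`-prefixed `key: value` header lines (subject traits,
movement type, per-device kind and rate) followed by CSV rows
`timestamp_ms,device_id,tag,x,y,z`, devices interleaved by timestamp.
Timestamps are milliseconds on disk and seconds in memory; duplicate
timestamps within a device keep file order (BLE bursts can share a
timestamp); rows tagged as gyroscope/magnetometer are ignored. A
configurable column map admits foreign CSV layouts. When the header
lacks a sampling rate it is estimated as the reciprocal median
positive inter-sample gap.

## Synthetic trial generator

Each movement type has a template: ordered phases shaping the
signal-magnitude (SMV) profile — constant, sinusoid, ramp,
valley-then-spike, spike-train — plus a gravity-tilt schedule. A trace
is the profile times a unit gravity direction tilting from the
vertical axis toward a template azimuth, with additive Gaussian jitter
(σ = 0.03 g at the trunk). Fall templates encode the canonical
phenomenology: random onset (uniform in 4–8 s), a 0.3 s free-fall
valley at 0.2 g, a 0.1 s impact spike at 4 g, and a persistent 90°
orientation change. Hard negatives are built in: hopping produces
2.5 g spike trains without orientation change; lying down on a bed
produces a 90° tilt without impact; jogging and stairs are sustained
high-amplitude oscillations. Quiet ADLs are low-amplitude sinusoids
(walking ±0.3 g at 2 Hz).

Position realism is mechanistic rather than calibrated: limb-mounted
nodes receive an attenuated, per-trace-random fraction of the
whole-body dynamic (ankle draws its scale from U(0.35, 1.0), chest
from U(0.85, 1.10)), transfer only part of the trunk orientation
change, and pick up Poisson-distributed spurious motion bursts
(cos²-shaped, 0.25 s, amplitudes up to 4.5 g at the ankle) along
random directions, plus larger jitter. These mechanisms reproduce the
qualitative ordering found on real recordings — trunk sensors best,
ankle worst, pocket/wrist intermediate — without claiming any real
dataset's numbers; the per-position parameters are package defaults,
explicitly not fitted to UMAFall.

Subjects are drawn from a fixed roster of 19 volunteers (ages 18–68);
the two participants over 65 are never assigned fall trials. Each
trial consumes an independent RNG stream keyed by
`(seed, trial_index)` with a type-major global index, so a given trial
is bit-reproducible and unaffected by count changes elsewhere. Default
per-type counts total 746 trials.

What passing tests on these data show: that the pipeline's inference
machinery (window localization, features, fusion, factorial ANOVA,
post-hoc selection) behaves correctly and recovers structure that is
present by construction. What they do not show: biomechanical realism
of mattress impacts, inter-subject variability of real movement, pocket
slippage dynamics, or the numeric performance levels attainable on
real recordings.

## Window and features

The analysis window is the earliest N_W-sample window (N_W =
round(t_W · f_s), t_W = 0.5 s, so 10 samples at 20 Hz and 100 at
200 Hz; each sensor is processed at its native rate) maximizing
Awdiff, the norm of per-axis (max − min) ranges; ties go to the
earliest start for determinism. Within the window: μSMV is the mean
sample norm; σSMV the population (1/N_W) standard deviation of the
norm; μSMVdiff and μθ sum over the N_W − 1 strictly in-window
consecutive pairs while keeping a 1/N_W normalization — stepping one
sample past the window would read out of bounds at trace end, and the
two conventions differ only by the constant factor (N_W − 1)/N_W,
which is irrelevant to classifier input after standardization; the
arccos argument of the rotation angle is clamped to [−1, 1] against
floating-point drift, and zero-norm pairs contribute 0 with a logged
warning. μAp averages the norm of the two non-vertical components,
using each device's vertical-axis convention.

## Detectors

The four classifiers are deliberately thin wrappers over scikit-learn:
SVC with RBF kernel, C = 1, `gamma="scale"` (the non-linear default; the
kernel is exposed in config since only "non-linear" is specified by
the underlying method); KNeighborsClassifier with k = 9 and Euclidean
distance (k reduced with a warning if the training set is smaller;
even-k ties resolve to "fall", conservative toward sensitivity, by
thresholding the neighbor vote fraction at 0.5); GaussianNB;
DecisionTreeClassifier with Gini splits and no depth limit. SVM and
k-NN operate on train-set z-scored features (distance/kernel methods
need comparable scales); trees and Naive Bayes see raw features.
Zero-variance features are dropped from standardized models with a
warning. Fusion is AND by default — a fall is declared only when every
considered position declares one — with OR available; on any fixed
test set AND-growth is monotone (sensitivity non-increasing,
specificity non-decreasing), which the suite asserts.

## Evaluation design

The default split reserves a fixed per-type number of training trials
(183 total) and deals the remaining 563 into six blocks, stratified by
movement type with a rotating round-robin so per-type block counts
differ by at most one and block totals stay near 94. Each
(algorithm, feature subset, sensor subset) cell is scored per block
with √(Se·Sp); per-position predictions are cached per
(algorithm, feature subset), so the full 4 × 63 × 31 × 6 grid needs
only 1 260 model fits and completes in well under a minute.

For the feature study, Se and Sp are first averaged over the sensor
combinations (unweighted mean over the N_cs supplied combos) and the
geometric mean is taken of the averaged pair — that order of
operations is part of the protocol. The sensor study fixes each
algorithm's optimal feature subset and varies the 31 sensor combos.

**ANOVA.** Percent contributions are SS_term/SS_total · 100 with the
within-cell SS as "error". Sums of squares are computed by
sequentially orthogonalizing the ±1-coded contrast columns (mains
first, then interactions by ascending order, lexicographic within an
order) against the centered response. For a complete balanced design
this reproduces the classical orthogonal decomposition exactly (a
hand-computed 2×2 toy and a statsmodels `anova_lm` cross-check pin
this down); for the incomplete 63-of-64-cell feature design — the
all-absent cell cannot exist, since a classifier needs at least one
input — the columns are no longer orthogonal and one term is aliased,
so the sequential convention makes the decomposition well-defined and
conservation (terms + error + remainder = 100%) exact by construction.
Unbalanced designs are rejected; zero total variance sets a degenerate
flag.

**Post hoc.** Cell means carry intervals of half-width
q(0.95, k, df) · √(s²/n) / 2, with s² the pooled within-cell variance
and q the studentized range quantile, so non-overlap is exactly a
Tukey-significant difference. The optimal cell is the
lowest-dimension one among those overlapping the best mean (ties:
higher mean, then lexicographic id) — preferring fewer
features/sensors at equal statistical performance.

**Diagnostics.** Residuals (observation minus cell mean) are paired
with normal quantiles at the (i − 0.375)/(n + 0.25) plotting positions,
and homoscedasticity uses the 4:1 max/min cell-variance heuristic for
balanced designs; cells with variance below a floor (default 1e-6,
e.g. a metric pinned at 1.0) are excluded from the ratio, which is
vacuously passed if fewer than two live cells remain. An optional
y^α response transformation is available as a pre-ANOVA hook, off by
default.

## Numerical and interface choices

- `round(t_W · f_s)` uses floor(x + 0.5), avoiding banker's-rounding
  surprises at exact halves.
- Argmax ties (window location, posthoc flags) always resolve
  deterministically (earliest index / lexicographic id).
- The CLI stages exchange plain CSV so each stage is independently
  testable; `run` writes a manifest with package version, seed and
  config hash, and identical seed + config reproduce byte-identical
  metric CSVs.
- Problem sizes used throughout the suite and the acceptance script
  are the default study conditions themselves (746 trials, full
  factorial grid); smaller fixtures (4 trials per type) are used where
  only interface behavior is under test.

## Known limitations

- The generator's confusability structure is qualitative; absolute
  metric levels (e.g. trunk sensors near 1.0) are properties of the
  synthetic conditions, not predictions for real data.
- Subject identity is not used by the split, so inter-subject
  generalization is not measured (trials of one subject may appear in
  both training and test).
- Gyroscope and magnetometer channels are parsed-and-ignored; no
  features are derived from them.
- The sequential-SS convention assigns shared variance of
  non-orthogonal terms to the earlier (lower-order) term; with the
  single missing cell the effect is negligible, but heavily truncated
  designs would make ordering matter.
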