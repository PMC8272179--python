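# Methods

## Pipeline model

The package treats fall detection as a four-stage pipeline over tri-axial
waist-accelerometer records, each record holding exactly one activity with a
ground-truth class (fall / ADL) and an activity-type label.

**AVM.** All stages operate on the acceleration vector magnitude
`AVM[i] = sqrt(ax² + ay² + az²)` in g units.  The AVM is orientation-free: a
resting sensor reads 1 g however it is worn, which is why no
orientation-dependent feature is used anywhere.

**Quality control.**  Two record-level exclusions: max AVM strictly above
30 g (beyond what ±8 g / ±16 g MEMS accelerometers can produce across three
axes, hence a sensor error) for either class, and max AVM strictly below
1.1 g for fall records only (barely above the 1 g rest level, so no impact
was captured; real-world falls show peaks of at least ~1.6 g).  Equality
with a bound keeps the record.  QC operates on the AVM, never on per-axis
maxima.

**Event detection.**  Sample `i` is a potential fall event iff
`AVM[i] > θ` (strict) and every sample in the quiet window
`(i, i + 2.5 s·fs]` is strictly below θ.  Falling is non-repetitive;
periodic activities keep re-crossing the threshold and never present a quiet
window.  Within a run of consecutive above-threshold samples only the last
can qualify.  Boundary choices:

* *Quiet window truncated by the record end counts as quiet* (default,
  `DetectorConfig.allow_truncated_quiet`).  Under this rule the trailing
  crossing of any record qualifies; such events are almost always discarded
  anyway by the 4 s margin requirement below, which is stricter than the
  2.5 s quiet window.  Setting the flag to False requires the full quiet
  window inside the record.
* Time-to-sample conversions use `round(t·fs)` throughout (symmetric error
  across sampling rates).
* Event counts are **not** monotone in θ in general: removing a bridging
  medium crossing can split one crossing cluster into two, so raising the
  threshold can add an event.  The detector is instead validated against a
  brute-force per-candidate scan; monotonicity holds (and is tested) for
  isolated peaks.

**Event labeling.**  Events in ADL records are ADL.  In fall records, events
at or after the global AVM maximum (argmax, first maximal sample on ties)
are falls; earlier events were triggered by activity preceding the fall and
are labeled ADL.  This carries the activity-before-fall case through the
pipeline as genuine negative examples.

**Calibration.**  The per-dataset threshold is the largest value on the
0–5 g grid (0.005 g steps) for which every fall record yields at least one
fall-labeled event; larger is better because it minimizes ADL false alarms.
The implementation evaluates, per record, the feasible interval
`(quiet_max(i), AVM[i])` of every candidate at/after the peak and intersects
grid membership across records; this is algebraically identical to running
the detector at every grid value and is verified against exactly that brute
force in the tests.  An infeasible grid raises `NoFeasibleThreshold`.

**Event-centered records.**  ±4 s around each labeled event (2·margin·fs + 1
samples, event at the midpoint).  Events with less than the margin on either
side are dropped; retention tables report per-class counts as the margin
varies (0/4/5 s by default).

**Windowing.**  W2 = [t0−t1, t0−t3), W1 = [t0−t3, t0+t4),
W3 = [t0+t4, t0+t2), half-open so adjacent windows never share a sample and
their union is the contiguous span [t0−max(t1,t3), t0+max(t2,t4)).  The t0
sample lands in W1 when t4 > 0, otherwise in W3 when W3 exists.  The
enumeration grid (t1, t2 ∈ {0, 0.5, …, 4}; t3 ∈ {0, 0.25, …, t1};
t4 ∈ {0, 0.25, …, t2}) yields 6561 tuples; the all-zero tuple admits no
features (every window empty) and is the single exclusion, leaving 6560.
The published criteria table distinguishes five classes (W1, W1+W2, W1+W3,
W2+W3, W1+W2+W3) but does not cover 16 grid tuples in which only W2 or only
W3 is non-empty (t2 = t3 = t4 = 0 with t1 > 0, and symmetrically); these are
classified `"W2"` / `"W3"` rather than rejected so the enumeration is total.

**Features and classifier.**  Eight features per window (see README), with
two deliberate conventions: the population divisor N for the standard
deviation, and AAMV as the mean of the N−1 valid consecutive differences
(the defining sum would otherwise index past the end; divisor switchable via
`aamv_divisor`).  The last feature is the square root of the summed squared
axis values (`rms_take_root=False` gives the plain sum).  SMA and the
root-sum feature are unnormalized and therefore scale with fs and window
length; standardization downstream absorbs this.  The classifier is an
RBF-kernel SVM, C = 1, gamma = 1/(n_features · Var(training features)) after
standardization (scikit-learn's `"scale"`; the effective value is logged per
fold).  Folds are a seeded random partition of the event-centered records —
fold membership depends only on the seed and the record identifiers, never
on features or labels; standardization parameters are fit per training fold
only; confusion counts are summed over the five test folds (for the Fscore
this weights folds by size, which is the natural pooling of summed counts).
Stratified folding is available behind a flag.  Undefined rates
(zero denominators) are reported as `None`, never as 0.

## Synthetic data generator

The generator emulates the features of waist-sensor fall/ADL corpora that
the pipeline relies on, not biomechanics.  Waveforms are built on the AVM
profile and re-projected onto three axes along a random per-record unit
gravity direction, plus per-axis Gaussian noise (sd 0.03 g by default, small
against the 1 g rest level).  With zero noise, rest samples have AVM exactly
1 g for any orientation.

Phase vocabulary: `rest` (1 g), `pre_impact_descent` (linear dip from 1 g to
0.3–0.5 g), `impact_peak` / `posture_change` (half-sine pulse from the 1 g
baseline to the drawn peak, 0.15–0.3 s wide), `periodic_motion` (two
phase-locked harmonics, `1 + a·sin + 0.3a·sin(2·)`, whose per-cycle maximum
is a fixed ≈1.135·a above rest — so walking with a ∈ [0.6, 0.8] crosses any
threshold near 1.5 g every step cycle and can never present a 2.5 s quiet
window).  Built-in templates: plain falls, broken falls (secondary pulse
0.4–1.2 s after the primary at 50–85 % of its height, with a tail long
enough that the detected event still honors the 4 s margin), falls preceded
by a sit-down bump (1.8–2.6 g, producing a genuine false event before the
fall), hard sit-downs (1.5–3 g bump between stretches of light motion),
walking, and low-peak activities capped below 1.2 g.

Key amplitude conventions, chosen once:

* ADL impact amplitudes are uniform on [1.5, 3] g.
* Fall impact amplitudes are uniform on [max(template floor, 4 − 2·d), 8] g,
  where d is the dataset `difficulty`.  At d = 0, every fall impact
  (including broken-fall secondary peaks, which the floor also applies to —
  the detected event can land on them) clears the ADL range and the classes
  are linearly separable on the impact maximum alone.  At the default d = 1
  the ranges overlap on [2, 3] g (about one fall in six), and the class
  signal must come from context: descent-then-rest around falls versus
  motion-before-and-after around ADL impacts.  This mirrors the regime real
  datasets are in, where a single impact window performs clearly worse than
  three windows.
* Error injection: spikes (31.5–40 g over three samples) on a deterministic
  leading share of fall and/or ADL records; low-peak falls rescaled to a
  1.05 g maximum.  The manifest's `qc_error` column is the ground truth the
  QC stage is tested against.

What the generator does **not** emulate: realistic fall biomechanics or
inter-subject variability, gyroscope/barometer channels, soft (low-g) real
falls, sensor drift, or dataset-specific activity inventories.  Passing
tests therefore demonstrate pipeline correctness and the *direction* of the
segmentation effect on data with the assumed structure — not performance
numbers transferable to real datasets, whose reproduction requires the
original recordings.

## Scales and numerical choices

Evaluation-scale runs (tests, acceptance script, examples) use 50 Hz, 100
falls + 100 ADL, and a reduced t_max = 2 s grid (624 configurations) —
sizes chosen so a sweep completes in seconds while exercising every window
class; the full 6560-configuration grid and the 25–238 Hz range are
supported and tested at the enumeration/extraction level.  These runs fix
the detection threshold at 1.4 g (inside the 1.3–2.4 g band typical of
calibrated waist-sensor datasets) rather than calibrating: max-threshold
calibration on data whose fall peaks are all comfortably supra-threshold
lands just below the smallest fall peak and would leave almost no ADL events
to classify.  Calibration is exercised and brute-force-verified on its own.

Strictness conventions: event crossing and quiet comparisons are strict;
QC bounds are strict; window classes are decided by exact comparisons on
grid values (multiples of 0.25 s, exactly representable).  Degenerate
inputs raise: empty record sets, < 2-sample segments (AAMV undefined),
single-class CV input, zero-length windows at low sampling rates, windows
exceeding the extraction margin.

## Known limitations

* The quiet-period detector's event count is not monotone in the threshold
  (see above); calibration is well-defined regardless because it quantifies
  over fall records, not event counts.
* Fscore from summed confusion counts differs slightly from averaging
  per-fold Fscores when folds are unbalanced; summed counts were chosen.
* Sampling rates below ~8 Hz make 0.25 s windows round to zero samples;
  extraction raises rather than silently emitting empty windows.
* Overlapping or gap-separated windows and multi-sensor fusion are out of
  scope.
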