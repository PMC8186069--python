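# Methods

## The problem

Collar-mounted tags recording tri-axial acceleration (surge *x*, sway *y*,
heave *z*, in g) and tri-axial magnetometry at 40 Hz can classify caprid
behaviour when paired with direct observations. The workflow this package
implements — windowed feature derivation, random-forest classification,
feature refinement, frequency/magnetometry ablations, random- vs
individual-level validation splits, cross-species transfer and slope-of-
terrain classification — is the standard surrogate-calibration recipe for
species that cannot be observed in the wild. Because the original zoo
observations are not publicly deposited, the package ships a synthetic
cohort generator that reproduces the *structure* of such data; every
pipeline stage is exercised against it.

## Signal model of the simulator

Orientation uses intrinsic heading-about-vertical, pitch-about-sway,
roll-about-surge rotations. Gravity in the device frame is

    a_static = (sin p, cos p · sin r, cos p · cos r)

for pitch *p* and roll *r*, which the feature module's estimators
(pitch = asin of the static surge share, roll = asin of the static sway
share) invert — exactly for pitch, and up to the closed form
asin(sin r · cos p) for roll, which differs from *r* by < 0.1° for the
modest angle combinations the repertoire uses.

Each behaviour contributes:

* a posture (mean pitch/roll of the collar) — e.g. grazing tips the collar
  nose-down (−35° pitch), browsing on hind legs tips it up (+30°), resting
  animals lie with the collar rolled;
* a gait oscillation: per-axis sinusoid at the stride frequency plus one 2×
  harmonic, heave leading surge by 90°; static behaviours (stride 0 Hz)
  emit none;
* a bounded heading random walk (AR(1) with coefficient 0.98 toward the
  bout's starting heading) whose step sd is behaviour-specific, so
  magnetometry carries information accelerometry lacks;
* i.i.d. Gaussian sensor noise (defaults: 0.02 g accelerometer,
  0.01 field-units magnetometer against a local field of magnitude ≈ 0.64).

Locomotion bouts draw a slope category and a signed angle (flat within
±2.5°, otherwise |angle| ∈ [4°, 12°]); the angle adds to pitch (uphill
positive) and scales gait amplitude by an effort factor (1.1 uphill, 0.9
downhill). A config switch (`slope_pitch_effect`) removes the postural
slope signature while keeping the labels, for ablation tests.

Species differ by a stride-frequency multiplier (goat-like 1.45 — short
legs cycle faster), an amplitude multiplier (0.8 — smaller body), and their
repertoire (climbing only in the ibex-like species, browsing only in the
goat-like one). Individuals draw log-normal stride/amplitude scales
(sd = `individual_sd`, default 0.15) and Gaussian posture offsets
(30°·sd pitch, 20°·sd roll). Male ibex add a fixed dimorphism shift
(stride ×0.85, amplitude ×1.3, +6° pitch) so sex-specific transfer is
testable; the default cohort is 2 male + 4 female ibex-like and 9 female
goat-like individuals, 30 min each — matching the deployments behind the
reference ethogram.

Bout behaviours are drawn with probabilities proportional to the reference
ethogram's per-species time shares (eating/standing dominant, shaking
rare), after one shuffled pass through the full repertoire per individual.
That guard guarantees every class appears for every individual at any seed
— without it a 0.15 %-share behaviour can vanish from a 30 min stream and
break stratified splitting — at the cost of inflating the rarest classes'
shares by well under the 5-point realism-check threshold. Bout durations
are log-normal (median 15 s, σ = 0.7, minimum 4 s so bouts hold whole
windows); `ethogram_realism_check` compares realised shares against any
target ethogram.

## Feature derivation

Features are computed over non-overlapping 2 s windows; a window is kept
only when it lies entirely inside one labelled interval (windows straddling
behaviour boundaries are dropped). Per-window rows, rather than per-sample
rows, make splitting well defined and match the 2 s span of the oscillation
features.

The static component is a centred running mean whose width is forced to an
odd sample count ≥ 3 (81 samples at 40 Hz, 3 at 1 Hz); dynamic = raw −
static, so the reconstruction is exact to machine rounding (bitwise
whenever static and raw agree to within a factor of two, per the Sterbenz
condition; ≤ 1 ulp otherwise). Near behaviour transitions the running mean
bleeds the neighbouring posture in — an inherent property of the
decomposition, so posture-recovery checks use windows at least one
smoothing window away from interval edges.

The 39-variable candidate registry comprises, per acceleration axis: static
mean and sd, dynamic mean/sd/min/max/range/mean-absolute, and the dominant
periodogram amplitude (psd1_*); whole-body: pitch, roll, VeDBA mean/sd/max,
smoothed VeDBA, ODBA; and five magnetometry variables (per-axis sd, sd of
the field-vector norm, mean angular change per sample of the normalised
field vector). It is deliberately redundant (range = max − min; ODBA ≈
VeDBA) so that correlation pruning has real work to do. Oscillation
amplitudes are scaled as sinusoid-equivalent amplitudes (2|X_k|/n, Nyquist
|X|/n), so a pure tone at a bin frequency is recovered exactly.

Subsampling is decimation (keep every k-th sample), applied *before* any
feature derivation — the two orders genuinely differ and the pipeline fixes
decimate-first. At 1 Hz a 2 s window holds two samples: only the Nyquist
component of the gait is resolvable and the smoothing window widens to 3 s.
That degradation is the mechanism behind the frequency-sweep results, so
the minimum window is 2 samples rather than 4.

## Dataset assembly

Class balancing down-samples whole windows uniformly at random from every
class whose labelled duration exceeds the threshold; the threshold is the
median of the pooled per-(species, behaviour) total durations, 560.4 s for
the reference ethogram (20 class totals, locomotion undivided). Behaviour
reduction removes aggression, grooming and shaking by default and refuses
unknown names.

Random splits are stratified by behaviour (unstratified 60/40 splitting can
lose a 57.8 s class from one side entirely). Individual-level splits
enumerate every subset of individuals whose row share lies within ±10
points of the 60 % training target; each admissible subset is one fold, a
cap subsamples folds reproducibly, and an empty band widens in 5-point
steps with a warning. Consecutive windows are autocorrelated; this inflates
random-split accuracy and is deliberately left uncorrected — the
random-vs-individual gap is the quantity of interest.

## Classification and refinement

The forest is scikit-learn's `RandomForestClassifier` (500 trees, Gini,
bootstrap, √p features per node, out-of-bag scoring); importances are mean
decrease in Gini impurity. The OOB error trace is reconstructed per tree
count from each tree's out-of-bag rows. Vote ties resolve to the first
class in sorted order.

Correlation pruning processes pairs by descending |r| and removes the
lower-importance member (importance ties: the lexicographically later name)
until the retained set is pairwise |r| < 0.70 — which also makes it
idempotent. Constant features (undefined r) are treated as r = 0 with a
warning.

RFE drops the lowest-importance features chunk-wise down a candidate-size
grid (default {2, 4, 8, 12, 16, 20, 25, 30, 39} capped at the feature
count), recomputing importances at each size step, and scores each subset
by stratified k-fold CV accuracy (k = 3, 100-tree forests by default for
affordability). The selected size is the *smallest* within 0.01 of the best
score: strict argmax is unstable under CV jitter — forests score a fraction
of a point higher with redundant features on easy problems — and the
tolerance rule is what reliably discards planted pure-noise features. For
cross-species use the refinement is run consistently: pruning uses the
elementwise-max |r| across species and mean importances, RFE scores are
averaged across species, and one shared feature set results.

On the synthetic cohort the refinement is aggressive (a handful of features
reach within-tolerance accuracy) because the simulated classes are far more
separable than real field data; the counts it reports describe the
synthetic conditions, not an expectation for real deployments.

## Evaluation

Overall accuracy is the confusion-matrix trace over the total, reported as
a percentage. (An alternative per-class formulation that divides each
class's true positives by the full one-vs-rest total is available as
`accuracy_form="printed"` for audits; its aggregate equals accuracy divided
by the class count and is not used for reporting.) Zero-denominator
precision/recall are reported as 0 and flagged; classes absent from the
validation side are excluded from the mean F1. Accuracy equals the
prevalence-weighted mean of per-class recalls — asserted as an algebraic
identity in the tests. Fold aggregation is an unweighted mean ± sd.

The frequency sweep runs the full pipeline per (species × frequency ×
magnetometry) cell. Transfer trains wholly on one species and evaluates on
the other restricted to shared behaviours (climbing and browsing are
excluded by construction); a sex filter restricts the test individuals. The
random-label null redraws labels i.i.d. with empirical class proportions
and reruns the random-split pipeline; with the reference imbalance its
accuracy sits near the sum of squared class shares, well above 1/k but far
below any informative model.

Statistical significance testing of sweep cells (GLM/ANOVA-style) is
deliberately replaced by descriptive tables and seeded ordering properties:
hypothesis tests on simulated cells would test the simulator, not the
method.

## Problem sizes and seeds

The test-suite and `scripts/acceptance.py` use the default cohort
(15 individuals × 30 min ≈ 12,000 windows) for headline accuracies, a
6-individual × 15 min cohort for the individual-variation sweep
(`individual_sd` ∈ {0.2, 0.4, 0.6}, chosen to span weak to strong
individuality), individual-split folds capped at 5, and 200-tree forests
for multi-fold sweeps (forest accuracy saturates well below 200 trees on
these data; 500 trees are kept for single headline fits). Refinement in the
acceptance script runs on 3,000 rows per species with 60-tree CV forests —
the selected-feature *counts* are insensitive to these sizes. One master
seed drives everything through deterministic child seeds (per individual,
stage and fold), so cohorts, splits and fits are bit-reproducible.

## What passing tests do and do not show

The simulator produces idealised signals: stationary sinusoidal gaits, a
noise-free orientation model, clean behaviour transitions, a homogeneous
magnetic field, no collar slip, drift, calibration error or unlabelled
time. Random-split accuracies near 100 % and transfer accuracies far above
field-realistic values reflect that idealisation. What the synthetic
results *do* establish is ordinal and structural: individual-split
validation scores below random-split validation and degrades with
individual variation; 1 Hz sampling loses gait information while 10 Hz does
not; a morphologically shifted surrogate species transfers imperfectly and
matched-sex transfer does not hurt; magnetometry separates behaviours that
accelerometry cannot; slope classes are recoverable exactly when the
postural slope signature exists. Real-data magnitudes must come from real
calibrations.

## Known limitations

* Gait dynamics are a fundamental-plus-harmonic caricature; no
  biomechanical stride model, no speed/step-length covariation.
* No GPS/dead-reckoning, pressure or temperature channels.
* The proprietary binary format of the original tags is out of scope; the
  CSV interfaces are the ingestion path.
* Per-class observation *durations* are the only quantity the reference
  ethogram pins down; per-behaviour signal parameters are stipulated, not
  fitted.
* Prediction-confidence thresholding for deployment on unlabelled data is
  a possible extension, not implemented.
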