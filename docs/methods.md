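# Methods

This note documents the models, numerical choices and limitations of
`ctgdecel`. It is the package's own account of what it computes and why.

## Signal model and preprocessing

A CTG record is a pair of uniformly sampled series: FHR in bpm and UCP in
arbitrary pressure units with basal value 0, default 4 Hz. FHR samples that
are zero, non-finite, or outside [30, 250] bpm are flagged as gaps. Gaps of
at most 15 s are bridged by linear interpolation; longer gaps split the
record into independent analysis windows. The 15 s cut matches the minimum
event duration, so no deceleration can be fabricated across a dropout long
enough to have hidden one.

Before segmentation the FHR is passed through a 7-sample (1.75 s at 4 Hz)
median filter. On a monotone stretch the median of a window is its centre
sample, so baseline-crossing instants are preserved exactly on clean
signals, while single-sample artifacts and beat-to-beat jitter are
suppressed. The filter flattens the trough of a smooth deceleration into a
tie of two or three samples; the nadir *instant* is therefore refined on
the unfiltered signal within the filter half-width (earliest sample if
tied), while the nadir *value* is taken from the filtered signal, which is
the more robust depth estimate under noise.

## Baseline estimation

The baseline is the stable FHR level with accelerations and decelerations
excluded — but finding those events requires a baseline. The estimator
treats this as a fixed point:

1. seed with the mode of the FHR histogram at 1 bpm bins (bin edges
   anchored at the sample minimum, making the seed equivariant under a
   constant shift of the signal);
2. exclude contiguous runs deviating from the current estimate by more
   than 10 bpm for at least 15 s;
3. re-estimate as the inner-80% trimmed mean of the retained samples;
4. iterate until the estimate moves < 0.5 bpm (cap 20 iterations; the cap
   returns the last iterate with `converged=False`).

Requires ≥ 10 minutes of valid signal (configurable). One baseline is
produced per analysis window — default the whole record — because each
deceleration row carries a single "Baseline" feature. The 10 bpm / 15 s /
80% / 0.5 bpm constants are this module's own choices of standard values;
they are deliberately conservative: an event shallower than 10 bpm biases
the baseline by well under the 12 bpm depth threshold that would change
any downstream decision.

## Fuzzy identification

Each maximal below-baseline excursion (entering at a sample ≤ BL, interior
strictly below, leaving at the first sample ≥ BL; excursions still open at
a record or window edge are dropped) is summarised by duration
T = tₙ − t₁ and depth N = BL − min(segment). Comparisons against BL use a
10⁻⁶ bpm tolerance so float round-off in the baseline estimate cannot flip
a sample's side.

Duration categories: T < 13.5, 13.5 ≤ T < 15, 15 ≤ T ≤ 120, 120 < T ≤ 360,
360 < T < 600, T ≥ 600 (seconds). Depth categories: N < 12, 12 ≤ N < 15,
N ≥ 15 (bpm). Membership functions are trapezoids: plateau 1 on the
category interior, linear shoulders of total width 2ε straddling each
internal boundary, so the two adjacent grades sum to 1 throughout a
shoulder zone. Shoulder half-widths: ε = 1 s at the 13.5 and 15 s
boundaries, 10 s at 120/360/600 s, 0.5 bpm at 12 and 15 bpm — roughly
proportional to the scale of each boundary so borderline excursions degrade
gracefully. Because the 13.5–15 s category is narrower than two shoulder
widths, its peak grade is 0.875 rather than 1; that category maps to ND for
every depth, so the winner is unaffected.

The 16-rule rulebase maps category pairs to {ND, D, PD, BC}. Two rows are
single-antecedent wildcards (T < 13.5 alone, N < 12 alone — either alone
rejects the excursion). Inference is Mamdani-style: rule activation = min
of its antecedent grades, per-consequent activation = max over that
consequent's rules, winner = argmax with ties broken by severity
BC > PD > D > ND (boundary cases escalate rather than vanish). The binary
"identifiable deceleration" flag is 1 iff the winner is D or PD.

The cell (120 < T ≤ 360, N ≥ 15) has no rulebase row although it satisfies
the deceleration bounds (15 ≤ T < 600, N ≥ 15); it is covered by an
explicit extrapolated internal rule with consequent D, on by default and
toggleable (`include_extrapolated`). The deterministic argmax is the
default decision rule; a learned MLP defuzzifier (5-fold CV, seeded) is
provided for training against external labels and reproduces the argmax
surface with held-out accuracy ≥ 0.99 when trained on its own labels.

## Event points and pairing

Deceleration landmarks: start = the baseline crossing entering the
segment, end = first sample at/above baseline after the nadir, nadir as
above. A monotone segment may have its nadir at an edge; this is permitted
and flagged `degenerate_nadir`.

Contractions are excursions of UCP above θ_on = 15 units, with start/end
at the surrounding crossings of θ_off = 5 units (hysteresis prevents
chatter) and a 30 s minimum duration between the off-crossings. The
operational start/end of a contraction is therefore threshold-based; the
synthetic generator reports its ground truth at the closed-form θ_off
crossings of the planted bump for exactly this reason.

Pairing: each deceleration is matched to the contraction maximising the
temporal overlap of its span with the contraction span widened by 30 s
before its start and 60 s after its end (late decelerations reach the
nadir after the contraction has ended). Assignment is greedy by descending
overlap, one deceleration per contraction. A deceleration with no
overlapping contraction falls back to the unclaimed contraction whose peak
is nearest to — and at most 120 s before — the nadir; failing that it is
emitted unpaired and classified Variable. The window constants are design
choices balancing admission of late decelerations against pairing across
unrelated contractions; all are config-exposed.

## Crisp classification

The rule cascade, applied in order to (descent time, nadir lag):

1. descent < 30 s → Variable (abrupt);
2. |nadir − peak| ≤ 15 s → Early;
3. nadir − peak > 30 s → Late;
4. otherwise → Variable.

The 15 s coincidence tolerance is one minimum-event duration; setting it
to 0 reproduces the strict reading under which true Early decelerations
are vanishingly rare. A flag (`late_on_start`) switches the Late criterion
to the alternative onset-after-peak reading. The 30 s abrupt/gradual cut
and the 15 s screening threshold of the segmentation stage are independent
configuration keys: screening keeps every candidate ≥ 15 s (shorter
segments are rejected by the rulebase, not the scanner), while descent
shape is judged against the 30 s onset-to-nadir rule.

## Feature sets, adequacy, classifiers

A deceleration–contraction pair plus the baseline yields 13 features in
fixed column order (U_st_time … D_e_point, Baseline). Tags S1/S2/S3
distinguish annotation provenance (pipeline event points + external
labels; external event points + labels; pipeline event points + crisp
labels). Rows lacking a contraction are rejected with a logged warning.

Adequacy: KMO = Σr²ᵢⱼ/(Σr²ᵢⱼ + Σq²ᵢⱼ) over off-diagonal pairs, with q the
anti-image partial correlations from the inverse correlation matrix
(pseudo-inverse with a warning when singular); Bartlett's
χ² = −(n−1−(2p+5)/6)·ln det R with df = p(p−1)/2; PCA on the correlation
matrix, components defaulting to eigenvalue > 1, optional varimax rotation
(the rotation used for component plots "in rotated space").

Classifier harness (stratified 5-fold CV, seed 1 by default, pooled
out-of-fold predictions → one confusion matrix per run):

* random forest — 100 trees;
* MLP — two hidden layers of (features + classes)/2 units, SGD with
  learning rate 0.4 and momentum 0.2 on standardised inputs;
* Gaussian naive Bayes;
* simple logistic — multiclass LogitBoost with one-attribute weighted
  least-squares base learners, capped at 400 boosting iterations, early
  stop when an internal validation deviance has not improved for 50
  iterations (then refit on all data at the selected iteration count).

Hidden-layer widths are not dictated by the hyperparameter conventions the
names come from; (features + classes)/2 is that toolkit's own default
heuristic. Batch size 100 is recorded for fidelity and treated as an
upper bound. Classes with fewer members than folds reduce the fold count
with a warning. RMSE of a classifier is the root mean square of (one-hot
truth − predicted probability) over all instances and classes.

The six-feature baseline harness uses only the six time features, one
single-output network per class (four hidden layers of 8 units,
one-vs-rest, argmax over per-class outputs) on a stratified 70/30 split,
reporting per-class percent-correct for both splits.

## Metrics

Class order is fixed (Early, Variable, Late). Per-class statistics come
from the one-vs-rest 2×2 reduction; accuracy is percent of the trace;
kappa from the standard p₀/pₑ formula; MCC per class by the binary
formula, macro MCC as their unweighted mean; averages are support-weighted.
A statistic with an empty denominator is reported as 0 and flagged rather
than dropped, so a class a classifier never predicts still yields a
complete, comparable report. AUC is the Mann–Whitney estimate (ties half).

## Agreement statistics

ICC uses the two-way mixed model with consistency definitions — ICC(3,1)
single measure, ICC(3,k) average measure — with F-distribution confidence
bounds; a flag could switch to absolute agreement but consistency is the
conventional reading of "two-way mixed" with fixed raters. Deming
regression uses the closed-form errors-in-variables slope with error
variance ratio λ = 1 by default (orthogonal regression; no basis for any
other ratio) and jackknife confidence intervals. Bland–Altman limits are
d̄ ± 1.96·SD (sample SD, n−1). The paired t-test handles zero-variance
differences explicitly (t = 0/p = 1 when identical, p = 0 flagged when a
constant nonzero shift). Applying these to nominal class codes
(Early = 1, Variable = 2, Late = 3) reproduces a common practice in the
method-comparison literature; the mechanics are provided without endorsing
that inference, and the coding is explicit.

## Synthetic data

The generator emulates what the pipeline consumes: FHR = baseline +
Gaussian noise − sum of deceleration pulses; UCP = sum of raised-cosine
bumps. A pulse is zero at onset and end and strictly below baseline in
between; descent is a cosine-tapered ramp when onset-to-nadir ≥ 30 s
(gradual) and linear when shorter (abrupt), recovery cosine-tapered. All
planted landmarks are snapped to the sample grid, so with zero noise the
operational event points equal the planted ones to within one sample.
Ground-truth labels derive from the planted geometry with the same
thresholds the crisp classifier uses.

The default benchmark suite (fully determined by its seed) plants one
single-event record per rulebase cell — durations and depths drawn inside
each category's plateau — plus mixed records totalling 21 events per NICHD
class, each with its paired contraction, events spaced 450 s apart.
Prolonged-deceleration durations are drawn from [420, 585] s and
baseline-change durations from [700, 900] s: partial baseline-exclusion of
shallow flanks shortens the *detected* duration of very long events by up
to ~10%, and these ranges keep the detected value inside the intended
category plateau. Records are sized at ≥ 4× the longest event so the
baseline histogram mode is dominated by true baseline.

What the generator does **not** model: realistic FHR variability spectra,
accelerations, signal-loss patterns, maternal heart rate contamination, or
UCP noise. Passing tests therefore demonstrate correctness of the
*mechanics* (segmentation, event points, rules, statistics) under the
stated signal model, not clinical performance on real labour traces.

## Problem sizes

The test suite and the acceptance script run the full benchmark suite
(26 records, 80 planted events, ~3.5 hours of synthetic signal), 100-
instance oracle-equivalence batteries per statistic, 1000-replicate
type-I-error simulation, and 4 × 5-fold CV on n = 300 — a few seconds in
total. These sizes give binomial/Monte-Carlo margins comfortably inside
every stated tolerance.

## Known limitations

* The baseline is global per analysis window; slow baseline drift within a
  window biases T and N for events far from the window mean. Windowed
  estimation is available via the `window` argument but not automatic.
* Hysteresis start/end of contractions are threshold-relative; absolute
  pressure calibration (mmHg) is out of scope.
* The learned defuzzifier trains on whatever labels it is given; with
  rulebase-generated labels it merely reproduces the argmax and is of no
  additional value — it exists for external annotation sources.
* Deming/Bland–Altman on nominal codes inherit all caveats of treating
  categories as numbers.
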