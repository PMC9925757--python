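# ctgdecel

Detection and classification of fetal heart rate (FHR) decelerations in
cardiotocography (CTG) records.

## The problem

During labour, a CTG monitor records the fetal heart rate together with the
mother's uterine contraction pressure (UCP), conventionally at 4 Hz.
*Decelerations* — transient drops of the FHR at least 15 bpm below the
baseline lasting at least 15 s — are the single most informative and most
disputed pattern in the trace. Obstetric guidelines (NICHD and others)
classify them by the timing of the deceleration nadir relative to the peak
of the paired uterine contraction:

| Class    | Timing rule                                     | Clinical reading |
|----------|--------------------------------------------------|------------------|
| Early    | gradual descent, nadir coincides with the peak   | benign           |
| Late     | gradual descent, nadir > 30 s after the peak     | pathological     |
| Variable | abrupt descent (onset → nadir < 30 s), any lag   | suspicious       |

Crisp thresholds handle borderline excursions poorly: a dip of 14.9 bpm for
14.9 s is physiologically indistinguishable from one of 15.1 bpm for 15.1 s.
This package implements the full pipeline around that observation:

1. **Baseline estimation** — recursive fixed-point estimate of the stable
   FHR level, excluding accelerations/decelerations.
2. **Fuzzy identification** — every below-baseline excursion is summarised
   by its duration *T* (s) and depth *N* (bpm); a 2-input Mamdani-style
   model with trapezoidal membership functions and a 16-rule rulebase
   decides between *not a deceleration* (ND), *identifiable deceleration*
   (D), *prolonged deceleration* (PD) and *baseline change* (BC).
3. **Event points** — each identified deceleration and its paired
   contraction yield twelve (time, value) landmarks: start/nadir/end of the
   FHR dip and start/peak/end of the pressure bump.
4. **Crisp classification** — the NICHD-style rule cascade above maps each
   deceleration–contraction pair to Early/Late/Variable.
5. **Feature sets & ML harness** — the 12 event points plus the baseline
   form a 13-feature vector; four classifiers (random forest, MLP, Gaussian
   naive Bayes, boosted simple logistic) are compared under seeded
   stratified 5-fold cross-validation, plus a six-feature neural-network
   baseline. Feature adequacy is checked with KMO, Bartlett's sphericity
   test and PCA.
6. **Method-comparison statistics** — ICC (two-way mixed, consistency),
   Deming errors-in-variables regression, Bland–Altman limits of agreement,
   paired t-test.

A synthetic-data module generates 4 Hz CTG records with planted
decelerations and raised-cosine contractions of known geometry, emitting
ground-truth event points and class labels, so every stage is testable
without access to clinical data.

## Worked example

Simulate the seeded benchmark, then run the pipeline on one record:

```sh
$ ctgdecel --seed 1 simulate --out-dir sim
wrote 26 records to sim

$ ctgdecel detect sim/nichd_mix_0.csv
# → baseline 125.1 bpm, 7 candidate segments, all 7 identifiable

$ ctgdecel classify-crisp sim/nichd_mix_0.csv
# → ["Early", "Variable", "Early", "Early", "Late", "Late", "Variable"]
```

The record `nichd_mix_0` plants seven decelerations with paired
contractions; `detect` recovers the baseline (125.1 bpm against a planted
125.07), flags all seven dips as identifiable decelerations, and
`classify-crisp` recovers exactly the planted Early/Late/Variable labels.

From Python, the same chain is three calls:

```python
from ctgdecel import read_record, estimate_baseline, classify_record_crisp

record = read_record("sim/nichd_mix_0.csv", dialect="csv")
bl = estimate_baseline(record)            # BaselineEstimate(bl=125.07...)
rows = classify_record_crisp(record, bl=bl)
for decel, contraction, cls in rows:
    print(f"{decel.D_st_time:7.1f}s  {cls.label:8s} "
          f"descent {cls.descent_time:5.1f}s  lag {cls.nadir_lag:+6.1f}s")
```

Metrics work directly on confusion matrices (class order Early, Variable,
Late):

```python
import numpy as np
from ctgdecel import ConfusionMatrix, report_from_confusion

cm = ConfusionMatrix(np.array([[38, 1, 0], [1, 36, 0], [0, 0, 21]]))
rep = report_from_confusion(cm)
print(rep.accuracy_pct)   # 97.94
print(rep.kappa)          # 0.968
```

## Scope notes

Real clinical traces (e.g. the CTU-UHB intrapartum database) are supported
through the `wfdb` dialect of `read_record` (PhysioNet-style header/signal
pairs, 16-bit format). Clinician annotations for such data are not public,
so the package validates against synthetic ground truth; it does not claim
to reproduce any particular study's real-data accuracies.
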