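"""Fuzzy identification of true FHR decelerations.

A below-baseline excursion of the FHR is summarised by two features:

* **T** — duration of time the FHR stays below the baseline, seconds;
* **N** — depth, the distance of the nadir from the baseline, bpm.

A two-input Mamdani-style model with trapezoidal membership functions and a
16-rule rulebase maps (T, N) to one of four consequents:

* ``ND`` — not a deceleration (too brief or too shallow);
* ``D``  — identifiable deceleration (15 s ≤ T ≤ 120 s and N ≥ 15 bpm);
* ``PD`` — prolonged deceleration (roughly 6–10 min below baseline);
* ``BC`` — baseline change (≥ 10 min below the old level is a shift of
  baseline, not an event).

Inference is min for rule AND, max for per-consequent aggregation, and an
argmax winner; ties escalate by severity (BC > PD > D > ND).  The binary
"identifiable deceleration" flag is 1 iff the winner is D or PD.

The crisp category edges (13.5, 15, 120, 360, 600 s; 12, 15 bpm) carry
linear shoulders so borderline excursions degrade gracefully instead of
flipping: a shoulder of total width 2ε straddles each internal boundary and
the two adjacent grades sum to 1 everywhere inside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .baseline import BaselineEstimate
from .io import TraceRecord, _bool_runs

__all__ = [
    "T_CATEGORIES",
    "N_CATEGORIES",
    "CONSEQUENTS",
    "CandidateSegment",
    "FuzzyRule",
    "MembershipGrades",
    "FuzzyDecision",
    "DEFAULT_RULEBASE",
    "EXTRAPOLATED_RULE",
    "find_candidate_segments",
    "membership_grades",
    "apply_rulebase",
    "defuzzify_learned",
    "rulebase_table",
    "save_rulebase",
    "load_rulebase",
]

T_CATEGORIES = (
    "T<13.5",
    "13.5<=T<15",
    "15<=T<=120",
    "120<T<=360",
    "360<T<600",
    "T>=600",
)
N_CATEGORIES = ("N<12", "12<=N<15", "N>=15")
CONSEQUENTS = ("ND", "D", "PD", "BC")
#: tie-break order: higher severity wins
_SEVERITY = {"BC": 3, "PD": 2, "D": 1, "ND": 0}

#: internal T-category boundaries (s) with shoulder half-widths ε (s)
T_BOUNDS: tuple[tuple[float, float], ...] = (
    (13.5, 1.0),
    (15.0, 1.0),
    (120.0, 10.0),
    (360.0, 10.0),
    (600.0, 10.0),
)
#: internal N-category boundaries (bpm) with shoulder half-widths ε (bpm)
N_BOUNDS: tuple[tuple[float, float], ...] = ((12.0, 0.5), (15.0, 0.5))


@dataclass(frozen=True)
class CandidateSegment:
    """One maximal below-baseline excursion of the FHR.

    ``i_start``/``i_end`` are inclusive sample indices of the boundary
    samples (p1 at/below BL entering, pn at/above BL leaving); times are
    seconds from record start.
    """

    i_start: int
    i_end: int
    t1: float
    tn: float
    p1: float
    pn: float
    p_min: float
    t_min: float
    bl: float

    @property
    def T(self) -> float:
        """Duration below baseline, s."""
        return self.tn - self.t1

    @property
    def N(self) -> float:
        """Depth of the nadir below baseline, bpm."""
        return self.bl - self.p_min


@dataclass(frozen=True)
class MembershipGrades:
    """Trapezoidal membership grades of one (T, N) pair, all in [0, 1]."""

    t_grades: dict[str, float]
    n_grades: dict[str, float]

    def vector(self) -> np.ndarray:
        """Concatenated grade vector (6 T-categories then 3 N-categories)."""
        return np.array(
            [self.t_grades[c] for c in T_CATEGORIES]
            + [self.n_grades[c] for c in N_CATEGORIES]
        )


@dataclass(frozen=True)
class FuzzyRule:
    """One rulebase row: antecedent categories (or ``ANY``) → consequent."""

    t_category: str
    n_category: str
    consequent: str
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if self.t_category != "ANY" and self.t_category not in T_CATEGORIES:
            raise ValueError(f"unknown T category {self.t_category!r}")
        if self.n_category != "ANY" and self.n_category not in N_CATEGORIES:
            raise ValueError(f"unknown N category {self.n_category!r}")
        if self.consequent not in CONSEQUENTS:
            raise ValueError(f"unknown consequent {self.consequent!r}")


@dataclass(frozen=True)
class FuzzyDecision:
    """Aggregated rule activations and the crisp decision they imply."""

    activations: dict[str, float]
    winner: str
    identifiable: bool


# The shipped 16-rule rulebase.  Rows 1-2 are single-antecedent (wildcard)
# rules: a duration under 13.5 s, or a depth under 12 bpm, rejects the
# excursion regardless of the other feature.
DEFAULT_RULEBASE: tuple[FuzzyRule, ...] = (
    FuzzyRule("T<13.5", "ANY", "ND"),
    FuzzyRule("ANY", "N<12", "ND"),
    FuzzyRule("13.5<=T<15", "N<12", "ND"),
    FuzzyRule("13.5<=T<15", "12<=N<15", "ND"),
    FuzzyRule("13.5<=T<15", "N>=15", "ND"),
    FuzzyRule("15<=T<=120", "N<12", "ND"),
    FuzzyRule("15<=T<=120", "12<=N<15", "ND"),
    FuzzyRule("15<=T<=120", "N>=15", "D"),
    FuzzyRule("120<T<=360", "N<12", "ND"),
    FuzzyRule("120<T<=360", "12<=N<15", "ND"),
    FuzzyRule("360<T<600", "N<12", "ND"),
    FuzzyRule("360<T<600", "12<=N<15", "PD"),
    FuzzyRule("360<T<600", "N>=15", "PD"),
    FuzzyRule("T>=600", "N<12", "ND"),
    FuzzyRule("T>=600", "12<=N<15", "BC"),
    FuzzyRule("T>=600", "N>=15", "BC"),
)

# The cell (120 < T ≤ 360, N ≥ 15) has no rulebase row although it satisfies
# the deceleration bounds 15 ≤ T < 600 s and N ≥ 15 bpm; it is covered by an
# explicit extrapolated rule, toggleable via apply_rulebase.
EXTRAPOLATED_RULE = FuzzyRule("120<T<=360", "N>=15", "D", extrapolated=True)


# ---------------------------------------------------------------------------
# segmentation

#: width of the median filter applied before segmentation, samples.
#: A 1.75 s window (at 4 Hz) suppresses single-sample artifacts and beat
#: jitter without displacing baseline crossings: the median of a window on a
#: monotone stretch is its centre sample, so crossing instants are preserved
#: exactly on clean signals.
MEDIAN_FILTER_WIDTH = 7


def preprocessed_fhr(
    record: TraceRecord, median_width: int = MEDIAN_FILTER_WIDTH
) -> np.ndarray:
    """Gap-interpolated, median-filtered FHR used by the detection stages."""
    from scipy import ndimage

    fhr = record.interpolated_fhr()
    if median_width and median_width > 1:
        finite = np.isfinite(fhr)
        arr = np.where(finite, fhr, np.inf)
        filt = ndimage.median_filter(arr, size=median_width, mode="nearest")
        filt[~finite] = np.nan
        filt[np.isinf(filt)] = np.nan
        fhr = filt
    return fhr


def find_candidate_segments(
    record: TraceRecord,
    bl: BaselineEstimate | float,
    median_width: int = MEDIAN_FILTER_WIDTH,
) -> list[CandidateSegment]:
    """Find maximal below-baseline excursions of the FHR.

    A segment enters at a sample p1 ≤ BL, stays strictly below BL in its
    interior, and leaves at the first sample pn ≥ BL.  Excursions still open
    at a record (or long-gap window) edge are dropped — their duration is
    unknowable.  Very short segments are kept; rejecting them is the
    rulebase's job.  Nadir ties break to the earliest sample.
    """
    bl_value = bl.bl if isinstance(bl, BaselineEstimate) else float(bl)
    fhr = preprocessed_fhr(record, median_width)
    fs = record.sample_rate
    t0 = record.start_time
    # tolerance far below physiological resolution: a sample this close to
    # the baseline counts as "at" it, guarding against float round-off in
    # the baseline estimate itself
    eps = 1e-6
    out: list[CandidateSegment] = []
    for w_lo, w_hi in _bool_runs(np.isfinite(fhr)):
        below = np.zeros(len(fhr), dtype=bool)
        below[w_lo:w_hi] = fhr[w_lo:w_hi] < bl_value - eps
        for lo, hi in _bool_runs(below):
            if lo <= w_lo or hi >= w_hi:
                continue  # open excursion at a window edge
            # entering sample: step back if the previous sample sits exactly
            # on the baseline, so t1 marks the true crossing instant
            a = lo - 1 if fhr[lo - 1] <= bl_value + eps else lo
            b = hi  # first sample at/above BL after the run
            seg = fhr[a : b + 1]
            k = int(np.argmin(seg))
            out.append(
                CandidateSegment(
                    i_start=a,
                    i_end=b,
                    t1=t0 + a / fs,
                    tn=t0 + b / fs,
                    p1=float(fhr[a]),
                    pn=float(fhr[b]),
                    p_min=float(seg[k]),
                    t_min=t0 + (a + k) / fs,
                    bl=bl_value,
                )
            )
    return out


# ---------------------------------------------------------------------------
# membership functions


def _trapezoid(x: float, lo: tuple[float, float] | None, hi: tuple[float, float] | None) -> float:
    """Grade of a trapezoid with linear shoulders of half-width ε per edge.

    ``lo``/``hi`` are (boundary, ε) pairs, or None for an unbounded side.
    The rising shoulder spans [b-ε, b+ε] so that the grades of the two
    categories adjacent to any internal boundary sum to one throughout the
    shoulder zone.
    """
    g = 1.0
    if lo is not None:
        b, eps = lo
        g = min(g, (x - (b - eps)) / (2.0 * eps))
    if hi is not None:
        b, eps = hi
        g = min(g, ((b + eps) - x) / (2.0 * eps))
    return float(np.clip(g, 0.0, 1.0))


def membership_grades(T: float, N: float) -> MembershipGrades:
    """Trapezoidal membership grades of duration T (s) and depth N (bpm).

    Negative or zero depth is legal (an excursion shallower than noise);
    only the ``N<12`` category then fires.  Non-positive duration is a
    caller error — a segment cannot have zero length.
    """
    if T <= 0:
        raise ValueError(f"duration must be positive, got {T}")
    t_edges: list[tuple[float, float] | None] = [None, *T_BOUNDS, None]
    t_grades = {
        cat: _trapezoid(T, t_edges[i], t_edges[i + 1])
        for i, cat in enumerate(T_CATEGORIES)
    }
    n_edges: list[tuple[float, float] | None] = [None, *N_BOUNDS, None]
    n_grades = {
        cat: _trapezoid(N, n_edges[i], n_edges[i + 1])
        for i, cat in enumerate(N_CATEGORIES)
    }
    return MembershipGrades(t_grades=t_grades, n_grades=n_grades)


# ---------------------------------------------------------------------------
# inference


def apply_rulebase(
    grades: MembershipGrades,
    rules: tuple[FuzzyRule, ...] = DEFAULT_RULEBASE,
    include_extrapolated: bool = True,
) -> FuzzyDecision:
    """Mamdani-style inference: min-AND, max-aggregation, argmax winner.

    ``include_extrapolated`` adds the internal rule covering the
    (120 < T ≤ 360, N ≥ 15) cell absent from the shipped rulebase.
    """
    if not rules:
        raise ValueError("rulebase must be non-empty")
    active = list(rules)
    if include_extrapolated:
        active.append(EXTRAPOLATED_RULE)
    activations = {c: 0.0 for c in CONSEQUENTS}
    for rule in active:
        strength = 1.0
        if rule.t_category != "ANY":
            strength = min(strength, grades.t_grades[rule.t_category])
        if rule.n_category != "ANY":
            strength = min(strength, grades.n_grades[rule.n_category])
        activations[rule.consequent] = max(activations[rule.consequent], strength)
    winner = max(CONSEQUENTS, key=lambda c: (activations[c], _SEVERITY[c]))
    return FuzzyDecision(
        activations=activations,
        winner=winner,
        identifiable=winner in ("D", "PD"),
    )


# ---------------------------------------------------------------------------
# learned defuzzifier (optional alternative to the deterministic argmax)


@dataclass
class TrainedDefuzzifier:
    """A small MLP mapping membership-grade vectors to the binary flag."""

    model: object
    cv_accuracy: float
    fold_splits: list[tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=list)

    def predict(self, grades: MembershipGrades) -> int:
        return int(self.model.predict(grades.vector().reshape(1, -1))[0])


def defuzzify_learned(
    decisions: list[tuple[MembershipGrades, int]], seed: int = 1
) -> TrainedDefuzzifier:
    """Train an MLP defuzzifier on labeled membership-grade vectors.

    Mirrors a neural-network defuzzification step with 5-fold
    cross-validation; the deterministic argmax of :func:`apply_rulebase`
    remains the default decision rule, this learned variant exists for
    training against external (e.g. clinician) labels.

    Requires at least 50 examples spanning both classes.
    """
    from sklearn.model_selection import StratifiedKFold
    from sklearn.neural_network import MLPClassifier

    if len(decisions) < 50:
        raise ValueError(f"need ≥ 50 labeled examples, got {len(decisions)}")
    X = np.vstack([g.vector() for g, _ in decisions])
    y = np.array([int(lbl) for _, lbl in decisions])
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    splits = [(tr.copy(), te.copy()) for tr, te in cv.split(X, y)]
    accs = []
    for tr, te in splits:
        clf = MLPClassifier(
            hidden_layer_sizes=(16, 16), max_iter=3000, random_state=seed
        )
        clf.fit(X[tr], y[tr])
        accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
    final = MLPClassifier(hidden_layer_sizes=(16, 16), max_iter=3000, random_state=seed)
    final.fit(X, y)
    return TrainedDefuzzifier(
        model=final, cv_accuracy=float(np.mean(accs)), fold_splits=splits
    )


# ---------------------------------------------------------------------------
# rulebase serialization


def rulebase_table(rules: tuple[FuzzyRule, ...] = DEFAULT_RULEBASE):
    """Rulebase as a DataFrame (t_category, n_category, consequent)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "t_category": r.t_category,
                "n_category": r.n_category,
                "consequent": r.consequent,
            }
            for r in rules
        ]
    )


def save_rulebase(path: str | Path, rules: tuple[FuzzyRule, ...] = DEFAULT_RULEBASE) -> None:
    rulebase_table(rules).to_csv(path, index=False)


def load_rulebase(path: str | Path) -> tuple[FuzzyRule, ...]:
    import pandas as pd

    df = pd.read_csv(path)
    return tuple(
        FuzzyRule(r["t_category"], r["n_category"], r["consequent"])
        for _, r in df.iterrows()
    )
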