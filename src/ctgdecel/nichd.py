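"""Crisp NICHD-style classification of decelerations.

The NICHD guideline separates deceleration classes by descent shape and by
the timing of the nadir relative to the paired contraction peak:

1. onset-to-nadir under 30 s → the descent is *abrupt* → **Variable**;
2. gradual descent with the nadir coinciding with the contraction peak
   (within a configurable tolerance) → **Early**;
3. gradual descent with the nadir more than 30 s after the peak → **Late**;
4. anything else (gradual but non-conforming timing) → **Variable**.

A strict reading of "coincide" (tolerance 0) makes true Early decelerations
vanishingly rare; the default tolerance of 15 s — one minimum-event
duration — matches how the classes are applied in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

from .baseline import BaselineEstimate, estimate_baseline
from .events import (
    ContractionEventPoints,
    DecelEventPoints,
    DecelContractionPair,
    extract_contraction_event_points,
    extract_decel_event_points,
    pair_decel_to_contraction,
)
from .fuzzy import apply_rulebase, find_candidate_segments, membership_grades
from .io import TraceRecord

__all__ = [
    "DecelClass",
    "classify_crisp",
    "classify_record_crisp",
    "DEFAULT_TOL_COINCIDE_S",
    "ABRUPT_DESCENT_MAX_S",
    "LATE_NADIR_LAG_MIN_S",
]

#: |nadir − contraction peak| within this means "coincides" → Early, s
DEFAULT_TOL_COINCIDE_S = 15.0
#: onset-to-nadir shorter than this is an abrupt descent → Variable, s
ABRUPT_DESCENT_MAX_S = 30.0
#: nadir more than this after the contraction peak → Late, s
LATE_NADIR_LAG_MIN_S = 30.0


@dataclass(frozen=True)
class DecelClass:
    """Crisp class of one deceleration with the rule that fired."""

    label: str  #: Early, Late or Variable
    rule: str
    descent_time: float  #: onset-to-nadir, s
    nadir_lag: float | None  #: nadir − contraction peak, s (None if unpaired)


def classify_crisp(
    pair: DecelContractionPair,
    tol_coincide: float = DEFAULT_TOL_COINCIDE_S,
    late_on_start: bool = False,
) -> DecelClass:
    """Classify one deceleration–contraction pair as Early/Late/Variable.

    ``late_on_start`` switches the Late criterion from nadir-lag (> 30 s
    after the peak) to the alternative reading where the *onset* after the
    peak marks a late deceleration.
    """
    d = pair.decel
    descent = d.descent_time
    if pair.contraction is None:
        return DecelClass("Variable", "no-contraction", descent, None)
    lag = d.D_n_time - pair.contraction.U_p_time
    if descent < ABRUPT_DESCENT_MAX_S:
        return DecelClass("Variable", "abrupt-descent", descent, lag)
    if abs(lag) <= tol_coincide:
        return DecelClass("Early", "nadir-at-peak", descent, lag)
    late_marker = (
        d.D_st_time - pair.contraction.U_p_time > 0.0 if late_on_start else lag > LATE_NADIR_LAG_MIN_S
    )
    if late_marker:
        return DecelClass("Late", "nadir-after-peak", descent, lag)
    return DecelClass("Variable", "non-conforming-timing", descent, lag)


def classify_record_crisp(
    record: TraceRecord,
    bl: BaselineEstimate | float | None = None,
    tol_coincide: float = DEFAULT_TOL_COINCIDE_S,
) -> list[tuple[DecelEventPoints, ContractionEventPoints | None, DecelClass]]:
    """Run the full chain on a record and return crisp-labeled events.

    baseline → candidate segmentation → fuzzy identification → event
    points → contraction pairing → crisp label; rows are in time order.
    """
    if len(record) == 0:
        return []
    if bl is None:
        bl = estimate_baseline(record)
    segments = find_candidate_segments(record, bl)
    decels: list[DecelEventPoints] = []
    for seg in segments:
        decision = apply_rulebase(membership_grades(seg.T, seg.N))
        if decision.identifiable:
            decels.append(extract_decel_event_points(seg, record, bl))
    contractions = extract_contraction_event_points(record)
    pairs = pair_decel_to_contraction(decels, contractions)
    out = []
    for pair in pairs:
        cls = classify_crisp(pair, tol_coincide=tol_coincide)
        out.append((pair.decel, pair.contraction, cls))
    out.sort(key=lambda row: row[0].D_st_time)
    return out
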