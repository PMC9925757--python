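"""Event-point extraction and deceleration–contraction pairing.

Each identified deceleration and its corresponding uterine contraction are
summarised by twelve event points — three (time, value) landmarks per
signal:

* deceleration: start (FHR crossing the baseline downward), nadir (lowest
  sample, earliest if tied), end (first sample back at/above baseline);
* contraction: start, peak (highest pressure, earliest if tied), end of the
  pressure excursion above the basal value zero.

Contractions are detected with an on/off hysteresis (rise above θ_on, ends
at the surrounding crossings of θ_off) so small ripples on the pressure
channel do not fragment a contraction.  A deceleration is paired with the
contraction whose (slightly widened) span it overlaps the most; late
decelerations reach their nadir after the contraction has ended, so the
contraction window is extended 60 s rightward (and 30 s leftward) before
computing overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .baseline import BaselineEstimate
from .fuzzy import CandidateSegment, preprocessed_fhr
from .io import TraceRecord, _bool_runs

__all__ = [
    "DecelEventPoints",
    "ContractionEventPoints",
    "DecelContractionPair",
    "extract_decel_event_points",
    "extract_contraction_event_points",
    "pair_decel_to_contraction",
    "UCP_ON_THRESHOLD",
    "UCP_OFF_THRESHOLD",
    "UCP_MIN_DURATION_S",
]

#: pressure must exceed this to open a contraction (units of the record)
UCP_ON_THRESHOLD = 15.0
#: contraction start/end at the surrounding crossings of this level
UCP_OFF_THRESHOLD = 5.0
#: contractions shorter than this between off-crossings are discarded, s
UCP_MIN_DURATION_S = 30.0

#: pairing window extensions around the contraction span, s
PAIR_WINDOW_BEFORE_S = 30.0
PAIR_WINDOW_AFTER_S = 60.0
#: fallback: nearest contraction peak at most this far before the nadir, s
PAIR_PEAK_LAG_MAX_S = 120.0


@dataclass(frozen=True)
class DecelEventPoints:
    """The deceleration half of the twelve event points."""

    D_st_time: float
    D_n_time: float
    D_e_time: float
    D_st_point: float
    D_n_point: float
    D_e_point: float
    degenerate_nadir: bool = False  #: nadir at a segment edge (monotone dip)

    @property
    def descent_time(self) -> float:
        """Onset-to-nadir time, the NICHD abrupt/gradual discriminator, s."""
        return self.D_n_time - self.D_st_time


@dataclass(frozen=True)
class ContractionEventPoints:
    """The contraction half of the twelve event points."""

    U_st_time: float
    U_p_time: float
    U_e_time: float
    U_start: float
    U_peak: float
    U_end: float


@dataclass(frozen=True)
class DecelContractionPair:
    """A deceleration with its corresponding contraction (if any)."""

    decel: DecelEventPoints
    contraction: ContractionEventPoints | None
    overlap: float  #: temporal overlap fraction of the decel span, in [0, 1]

    @property
    def unpaired(self) -> bool:
        return self.contraction is None


def extract_decel_event_points(
    segment: CandidateSegment,
    record: TraceRecord,
    bl: BaselineEstimate | float,
    identifiable: bool = True,
) -> DecelEventPoints:
    """Event points of one identified deceleration segment.

    The segment must already be flagged identifiable (D or PD) by the fuzzy
    stage; passing an unflagged segment is a contract violation.
    """
    if not identifiable:
        raise ValueError("segment was not flagged as an identifiable deceleration")
    from .fuzzy import MEDIAN_FILTER_WIDTH

    fhr = preprocessed_fhr(record)
    fs = record.sample_rate
    t0 = record.start_time
    a, b = segment.i_start, segment.i_end
    seg = fhr[a : b + 1]
    k = int(np.argmin(seg))  # earliest minimum on the filtered signal
    # the filtered nadir value is the robust depth estimate, but the filter
    # flattens the trough into ties, displacing its time by a sample or two;
    # refine the nadir *instant* on the unfiltered signal within the filter
    # half-width (earliest if tied)
    nadir_value = float(seg[k])
    raw = record.interpolated_fhr()
    half = MEDIAN_FILTER_WIDTH // 2
    lo = max(0, k - half)
    hi = min(b - a, k + half)
    window = raw[a + lo : a + hi + 1]
    if np.all(np.isfinite(window)):
        k = lo + int(np.argmin(window))
    degenerate = k == 0 or k == (b - a)
    return DecelEventPoints(
        D_st_time=t0 + a / fs,
        D_n_time=t0 + (a + k) / fs,
        D_e_time=t0 + b / fs,
        D_st_point=float(fhr[a]),
        D_n_point=nadir_value,
        D_e_point=float(fhr[b]),
        degenerate_nadir=degenerate,
    )


def extract_contraction_event_points(
    record: TraceRecord,
    search_window: tuple[float, float] | None = None,
    on_threshold: float = UCP_ON_THRESHOLD,
    off_threshold: float = UCP_OFF_THRESHOLD,
    min_duration_s: float = UCP_MIN_DURATION_S,
) -> list[ContractionEventPoints]:
    """Detect uterine contractions on the pressure channel.

    A contraction is an excursion rising above ``on_threshold``; its start
    and end are the surrounding crossings of ``off_threshold`` (hysteresis),
    its peak the maximum sample (earliest if tied).  Excursions shorter than
    ``min_duration_s`` between the off-crossings are discarded.
    """
    ucp = np.asarray(record.ucp, dtype=float)
    fs = record.sample_rate
    t0 = record.start_time
    n = len(ucp)
    lo_t, hi_t = (-np.inf, np.inf) if search_window is None else search_window

    above_off = ucp > off_threshold
    out: list[ContractionEventPoints] = []
    for lo, hi in _bool_runs(above_off):
        # hi is exclusive: run of samples above the off threshold
        if ucp[lo:hi].max() < on_threshold:
            continue
        # start/end at the samples where the signal sits at/below θ_off
        a = max(lo - 1, 0)
        b = min(hi, n - 1)
        if (b - a) / fs < min_duration_s:
            continue
        k = int(np.argmax(ucp[a : b + 1]))
        t_start = t0 + a / fs
        t_end = t0 + b / fs
        if t_end < lo_t or t_start > hi_t:
            continue
        out.append(
            ContractionEventPoints(
                U_st_time=t_start,
                U_p_time=t0 + (a + k) / fs,
                U_e_time=t_end,
                U_start=float(ucp[a]),
                U_peak=float(ucp[a + k]),
                U_end=float(ucp[b]),
            )
        )
    return out


def _overlap_fraction(decel: DecelEventPoints, c: ContractionEventPoints) -> float:
    """Fraction of the decel span inside the widened contraction window."""
    lo = c.U_st_time - PAIR_WINDOW_BEFORE_S
    hi = c.U_e_time + PAIR_WINDOW_AFTER_S
    span = decel.D_e_time - decel.D_st_time
    if span <= 0:
        return 0.0
    inter = min(decel.D_e_time, hi) - max(decel.D_st_time, lo)
    return float(np.clip(inter / span, 0.0, 1.0))


def pair_decel_to_contraction(
    decels: list[DecelEventPoints],
    contractions: list[ContractionEventPoints],
) -> list[DecelContractionPair]:
    """Pair each deceleration with its corresponding contraction.

    Pairs are assigned greedily by descending overlap fraction, each
    contraction being claimed by at most one deceleration.  A deceleration
    without any overlapping contraction falls back to the unclaimed
    contraction whose peak is nearest to — and not more than 120 s before —
    the deceleration nadir; failing that it is emitted unpaired.

    Input lists must be sorted by time.
    """
    candidates: list[tuple[float, int, int]] = []
    for i, d in enumerate(decels):
        for j, c in enumerate(contractions):
            f = _overlap_fraction(d, c)
            if f > 0:
                candidates.append((f, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    decel_to_contr: dict[int, int] = {}
    used: set[int] = set()
    overlaps: dict[int, float] = {}
    for f, i, j in candidates:
        if i in decel_to_contr or j in used:
            continue
        decel_to_contr[i] = j
        used.add(j)
        overlaps[i] = f
    # fallback on peak lag for decels left unmatched
    for i, d in enumerate(decels):
        if i in decel_to_contr:
            continue
        best_j, best_lag = None, np.inf
        for j, c in enumerate(contractions):
            if j in used:
                continue
            lag = d.D_n_time - c.U_p_time
            if 0.0 <= lag <= PAIR_PEAK_LAG_MAX_S and lag < best_lag:
                best_j, best_lag = j, lag
        if best_j is not None:
            decel_to_contr[i] = best_j
            used.add(best_j)
            overlaps[i] = 0.0
    return [
        DecelContractionPair(
            decel=d,
            contraction=contractions[decel_to_contr[i]] if i in decel_to_contr else None,
            overlap=overlaps.get(i, 0.0),
        )
        for i, d in enumerate(decels)
    ]
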