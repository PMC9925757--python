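"""Synthetic CTG traces with planted decelerations and contractions.

The generator emulates the data model of intrapartum CTG at 4 Hz: an FHR
series fluctuating around a stable baseline with planted below-baseline
deceleration pulses of controlled duration, depth and descent shape, and a
UCP series of raised-cosine contraction bumps over a basal value of zero.
Every planted event is emitted together with its ground-truth event points
and — when paired with a contraction — its Early/Late/Variable class derived
from the planted geometry, so every downstream stage can be tested without
external data.

Deceleration pulse shapes follow the clinical distinction the classifier
relies on: a *gradual* descent (onset-to-nadir ≥ 30 s) is a cosine-tapered
ramp, an *abrupt* descent is a linear drop; recovery is cosine-tapered.  The
pulse is zero at onset and end and strictly below baseline in between, so
the planted landmarks are exactly the operational event points.

Contraction ground truth is reported operationally: start/end are the
closed-form crossings of the detector's off-threshold on the raised-cosine
bump (the pressure channel never returns exactly to zero in practice, so the
working definition of a contraction's extent is threshold-based).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .events import (
    ContractionEventPoints,
    DecelEventPoints,
    UCP_OFF_THRESHOLD,
    UCP_ON_THRESHOLD,
)
from .io import TraceRecord

__all__ = [
    "PlantedDecel",
    "PlantedContraction",
    "SimulationSpec",
    "GroundTruthEvent",
    "GroundTruth",
    "SpecError",
    "simulate",
    "default_benchmark_suite",
]

DECEL_TYPES = ("Early", "Late", "Variable", "Prolonged", "BaselineChange", "SubThreshold")
#: descent at least this long is gradual (cosine ramp), shorter is abrupt
GRADUAL_DESCENT_MIN_S = 30.0


class SpecError(ValueError):
    """Invalid simulation specification (e.g. overlapping planted events)."""


@dataclass(frozen=True)
class PlantedDecel:
    """One planted deceleration pulse."""

    type: str                 #: one of DECEL_TYPES
    onset_time: float         #: s from record start
    descent_time: float       #: onset → nadir, s
    duration: float           #: onset → recovery, s
    depth: float              #: nadir depth below baseline, bpm
    recovery_shape: str = "cosine"  #: "cosine" or "linear"

    def __post_init__(self) -> None:
        if self.type not in DECEL_TYPES:
            raise SpecError(f"unknown decel type {self.type!r}")
        if self.duration <= 0 or self.depth <= 0:
            raise SpecError("duration and depth must be positive")
        if not 0 < self.descent_time < self.duration:
            raise SpecError("descent_time must lie strictly inside the duration")

    @property
    def nadir_time(self) -> float:
        return self.onset_time + self.descent_time

    @property
    def end_time(self) -> float:
        return self.onset_time + self.duration


@dataclass(frozen=True)
class PlantedContraction:
    """One planted raised-cosine contraction bump."""

    start_time: float
    peak_time: float
    end_time: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.start_time < self.peak_time < self.end_time:
            raise SpecError("need start < peak < end")
        if self.amplitude <= 0:
            raise SpecError("amplitude must be positive")


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic record."""

    baseline_bpm: float = 140.0
    duration_s: float = 1800.0
    noise_sd: float = 0.0
    decels: tuple[PlantedDecel, ...] = ()
    contractions: tuple[PlantedContraction, ...] = ()
    #: decel index → contraction index (ground-truth pairing); unmapped
    #: decels have no corresponding contraction
    pairing: dict[int, int] = field(default_factory=dict)
    seed: int = 0
    sample_rate: float = 4.0
    record_id: str = "synthetic"

    def validate(self) -> None:
        for events, what in (
            ([(d.onset_time, d.end_time) for d in self.decels], "decelerations"),
            ([(c.start_time, c.end_time) for c in self.contractions], "contractions"),
        ):
            spans = sorted(events)
            for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
                if s1 < e0:
                    raise SpecError(f"overlapping planted {what} at t={s1:.1f}s")
        for d in self.decels:
            if d.end_time > self.duration_s or d.onset_time < 0:
                raise SpecError("deceleration outside the record")
        for c in self.contractions:
            if c.end_time > self.duration_s or c.start_time < 0:
                raise SpecError("contraction outside the record")
        for i, j in self.pairing.items():
            if not (0 <= i < len(self.decels) and 0 <= j < len(self.contractions)):
                raise SpecError("pairing refers to a non-existent event")


@dataclass(frozen=True)
class GroundTruthEvent:
    """Ground truth for one planted deceleration."""

    planted: PlantedDecel
    decel_points: DecelEventPoints
    contraction_points: ContractionEventPoints | None
    label: str | None        #: Early/Late/Variable, None when unpaired
    consequent: str          #: crisp rulebase cell consequent (ND/D/PD/BC)
    identifiable: bool       #: True iff consequent in {D, PD}


@dataclass(frozen=True)
class GroundTruth:
    baseline_bpm: float
    events: tuple[GroundTruthEvent, ...]
    contractions: tuple[ContractionEventPoints, ...]


# ---------------------------------------------------------------------------
# signal synthesis


def _decel_profile(t: np.ndarray, d: PlantedDecel) -> np.ndarray:
    """Unit-depth pulse: 0 at onset and end, 1 at the nadir."""
    r = np.zeros_like(t)
    down = (t > d.onset_time) & (t <= d.nadir_time)
    u = (t[down] - d.onset_time) / d.descent_time
    if d.descent_time >= GRADUAL_DESCENT_MIN_S:
        r[down] = 0.5 * (1.0 - np.cos(np.pi * u))
    else:
        r[down] = u
    up = (t > d.nadir_time) & (t < d.end_time)
    v = (t[up] - d.nadir_time) / (d.duration - d.descent_time)
    if d.recovery_shape == "cosine":
        r[up] = 0.5 * (1.0 + np.cos(np.pi * v))
    else:
        r[up] = 1.0 - v
    return r


def _contraction_profile(t: np.ndarray, c: PlantedContraction) -> np.ndarray:
    """Raised-cosine bump: 0 at start/end, amplitude at the peak."""
    y = np.zeros_like(t)
    rise = (t > c.start_time) & (t <= c.peak_time)
    u = (t[rise] - c.start_time) / (c.peak_time - c.start_time)
    y[rise] = 0.5 * c.amplitude * (1.0 - np.cos(np.pi * u))
    fall = (t > c.peak_time) & (t < c.end_time)
    v = (t[fall] - c.peak_time) / (c.end_time - c.peak_time)
    y[fall] = 0.5 * c.amplitude * (1.0 + np.cos(np.pi * v))
    return y


def _operational_contraction_points(
    c: PlantedContraction, theta: float = UCP_OFF_THRESHOLD
) -> ContractionEventPoints | None:
    """Closed-form event points of a bump under the threshold definition."""
    if c.amplitude <= max(theta, UCP_ON_THRESHOLD):
        return None
    u_on = math.acos(1.0 - 2.0 * theta / c.amplitude) / math.pi
    v_off = math.acos(2.0 * theta / c.amplitude - 1.0) / math.pi
    return ContractionEventPoints(
        U_st_time=c.start_time + u_on * (c.peak_time - c.start_time),
        U_p_time=c.peak_time,
        U_e_time=c.peak_time + v_off * (c.end_time - c.peak_time),
        U_start=theta,
        U_peak=c.amplitude,
        U_end=theta,
    )


def _crisp_consequent(T: float, N: float) -> str:
    """Crisp rulebase-cell lookup for planted (duration, depth)."""
    if T < 13.5 or N < 12.0:
        return "ND"
    if T < 15.0:
        return "ND"
    if T <= 120.0:
        return "D" if N >= 15.0 else "ND"
    if T <= 360.0:
        return "D" if N >= 15.0 else "ND"  # N>=15 cell covered by extrapolation
    if T < 600.0:
        return "PD"
    return "BC" if N >= 12.0 else "ND"


def _ground_truth_label(d: PlantedDecel, c: PlantedContraction | None) -> str | None:
    """Early/Late/Variable from the planted geometry (None when unpaired)."""
    if c is None:
        return None
    if d.descent_time < GRADUAL_DESCENT_MIN_S:
        return "Variable"
    lag = d.nadir_time - c.peak_time
    if abs(lag) <= 15.0:
        return "Early"
    if lag > 30.0:
        return "Late"
    return "Variable"


def simulate(spec: SimulationSpec) -> tuple[TraceRecord, GroundTruth]:
    """Render a spec into a record plus its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    fhr = np.full(n, spec.baseline_bpm, dtype=float)
    for d in spec.decels:
        fhr -= d.depth * _decel_profile(t, d)
    if spec.noise_sd > 0:
        fhr += rng.normal(0.0, spec.noise_sd, size=n)
    ucp = np.zeros(n, dtype=float)
    for c in spec.contractions:
        ucp += _contraction_profile(t, c)
    record = TraceRecord(
        record_id=spec.record_id,
        fhr=fhr,
        ucp=ucp,
        sample_rate=spec.sample_rate,
    )
    all_contr = tuple(
        cp
        for c in spec.contractions
        if (cp := _operational_contraction_points(c)) is not None
    )
    events = []
    for i, d in enumerate(spec.decels):
        c = spec.contractions[spec.pairing[i]] if i in spec.pairing else None
        consequent = _crisp_consequent(d.duration, d.depth)
        events.append(
            GroundTruthEvent(
                planted=d,
                decel_points=DecelEventPoints(
                    D_st_time=d.onset_time,
                    D_n_time=d.nadir_time,
                    D_e_time=d.end_time,
                    D_st_point=spec.baseline_bpm,
                    D_n_point=spec.baseline_bpm - d.depth,
                    D_e_point=spec.baseline_bpm,
                ),
                contraction_points=(
                    _operational_contraction_points(c) if c is not None else None
                ),
                label=_ground_truth_label(d, c),
                consequent=consequent,
                identifiable=consequent in ("D", "PD"),
            )
        )
    return record, GroundTruth(
        baseline_bpm=spec.baseline_bpm,
        events=tuple(events),
        contractions=all_contr,
    )


# ---------------------------------------------------------------------------
# benchmark suite


def _snap(x: float, fs: float = 4.0) -> float:
    """Snap a time to the sample grid so planted landmarks fall on samples."""
    return round(x * fs) / fs


#: plateau-interior sampling ranges per duration category (s)
_T_RANGES = (
    (5.0, 12.0),
    (14.1, 14.4),
    (17.0, 110.0),
    (132.0, 348.0),
    (420.0, 585.0),
    (700.0, 900.0),
)
#: plateau-interior sampling ranges per depth category (bpm)
_N_RANGES = ((4.0, 11.0), (12.7, 14.3), (16.0, 38.0))

#: (t_category index, n_category index) cells planted by the suite; the
#: (120<T≤360, N≥15) cell is absent from the shipped rulebase and skipped
_RULEBASE_CELLS = tuple(
    (ti, ni) for ti in range(6) for ni in range(3) if not (ti == 3 and ni == 2)
)


def default_benchmark_suite(
    seed: int, noise_sd: float = 0.0, events_per_class: int = 21
) -> list[SimulationSpec]:
    """Fixed battery of simulation specs exercising every pipeline stage.

    * one single-event record per fuzzy rulebase cell, with duration and
      depth drawn inside the cell's category plateau;
    * mixed records planting ``events_per_class`` decelerations of each
      NICHD class (Early/Late/Variable), each with its paired contraction.

    The same seed yields the identical suite.
    """
    rng = np.random.default_rng(seed)
    specs: list[SimulationSpec] = []

    # --- rulebase-cell coverage -------------------------------------------
    for ti, ni in _RULEBASE_CELLS:
        t_lo, t_hi = _T_RANGES[ti]
        n_lo, n_hi = _N_RANGES[ni]
        duration = _snap(rng.uniform(t_lo, t_hi))
        depth = float(rng.uniform(n_lo, n_hi))
        descent_frac = 0.4 if duration < 60 else float(rng.uniform(0.25, 0.45))
        descent = _snap(max(duration * descent_frac, 0.5))
        record_len = max(1800.0, duration * 4.0)
        onset = _snap(record_len / 2.0 - duration / 2.0)
        dtype = {0: "SubThreshold", 1: "SubThreshold"}.get(
            ti, "SubThreshold" if ni == 0 else None
        )
        if dtype is None:
            dtype = {2: "Early", 3: "Early", 4: "Prolonged", 5: "BaselineChange"}[ti]
        specs.append(
            SimulationSpec(
                baseline_bpm=140.0,
                duration_s=record_len,
                noise_sd=noise_sd,
                decels=(
                    PlantedDecel(
                        type=dtype,
                        onset_time=onset,
                        descent_time=descent,
                        duration=duration,
                        depth=depth,
                    ),
                ),
                seed=int(rng.integers(2**31)),
                record_id=f"cell_t{ti}_n{ni}",
            )
        )

    # --- NICHD class coverage ---------------------------------------------
    per_record = 7
    classes = ("Early", "Late", "Variable")
    n_records = math.ceil(events_per_class * len(classes) / per_record)
    labels = [classes[k % 3] for k in range(events_per_class * len(classes))]
    rng.shuffle(labels)
    idx = 0
    for r in range(n_records):
        chunk = labels[idx : idx + per_record]
        idx += per_record
        if not chunk:
            break
        baseline = float(rng.uniform(125.0, 150.0))
        decels, contractions, pairing = [], [], {}
        for k, label in enumerate(chunk):
            onset = _snap(300.0 + k * 450.0 + rng.uniform(-20.0, 20.0))
            depth = float(rng.uniform(16.0, 35.0))
            if label == "Variable":
                descent = _snap(rng.uniform(16.0, 28.0))
                duration = _snap(descent + rng.uniform(25.0, 60.0))
                lag = rng.uniform(-25.0, 25.0)
            elif label == "Early":
                descent = _snap(rng.uniform(36.0, 58.0))
                duration = _snap(descent + rng.uniform(30.0, 55.0))
                lag = rng.uniform(-8.0, 8.0)
            else:  # Late
                descent = _snap(rng.uniform(36.0, 58.0))
                duration = _snap(descent + rng.uniform(30.0, 55.0))
                lag = rng.uniform(40.0, 85.0)
            nadir = onset + descent
            peak = _snap(nadir - lag)
            rise = _snap(rng.uniform(26.0, 40.0))
            fall = _snap(rng.uniform(26.0, 40.0))
            decels.append(
                PlantedDecel(
                    type=label,
                    onset_time=onset,
                    descent_time=descent,
                    duration=duration,
                    depth=depth,
                )
            )
            contractions.append(
                PlantedContraction(
                    start_time=peak - rise,
                    peak_time=peak,
                    end_time=peak + fall,
                    amplitude=float(rng.uniform(40.0, 80.0)),
                )
            )
            pairing[k] = k
        specs.append(
            SimulationSpec(
                baseline_bpm=baseline,
                duration_s=300.0 + per_record * 450.0 + 300.0,
                noise_sd=noise_sd,
                decels=tuple(decels),
                contractions=tuple(contractions),
                pairing=pairing,
                seed=int(rng.integers(2**31)),
                record_id=f"nichd_mix_{r}",
            )
        )
    return specs
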