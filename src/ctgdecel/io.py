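"""Reading and writing CTG records and tabular artifacts.

A CTG record is a pair of simultaneously sampled series: fetal heart rate
(FHR, bpm) and uterine contraction pressure (UCP, arbitrary units with basal
value zero), conventionally at 4 Hz.  Two on-disk dialects are supported:

* ``csv`` — three columns ``time,fhr,ucp`` with a header row and a uniform
  time step;
* ``wfdb`` — a PhysioNet-style header/signal pair (``.hea`` + ``.dat``,
  16-bit format), the layout used by the CTU-UHB intrapartum database.
  Channels are selected by signal-name match ("FHR"/"UC", case-insensitive),
  falling back to channel order.

FHR samples equal to zero or outside the physiological range [30, 250] bpm
are flagged as gaps rather than deleted, so downstream stages can decide how
to treat them: gaps shorter than 15 s are linearly interpolated, longer gaps
split the record into independent analysis windows (no deceleration may be
fabricated across a dropout longer than the minimum event duration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TraceRecord",
    "FormatError",
    "FHR_MIN_BPM",
    "FHR_MAX_BPM",
    "GAP_INTERP_MAX_S",
    "FEATURE_COLUMNS",
    "read_record",
    "write_record",
    "write_features",
    "read_features",
]

FHR_MIN_BPM = 30.0
FHR_MAX_BPM = 250.0
#: gaps at most this long are bridged by linear interpolation
GAP_INTERP_MAX_S = 15.0

#: canonical column order of the 13-feature CSV
FEATURE_COLUMNS = (
    "U_st_time", "U_p_time", "U_e_time",
    "U_st_point", "U_p_point", "U_e_point",
    "D_st_time", "D_n_time", "D_e_time",
    "D_st_point", "D_n_point", "D_e_point",
    "Baseline",
)


class FormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


def mark_gaps(fhr: np.ndarray) -> np.ndarray:
    """Boolean mask of invalid FHR samples (zero, non-finite or out of range)."""
    fhr = np.asarray(fhr, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = ~np.isfinite(fhr) | (fhr < FHR_MIN_BPM) | (fhr > FHR_MAX_BPM)
    return bad


@dataclass
class TraceRecord:
    """Paired FHR/UCP series with uniform sampling.

    Attributes
    ----------
    record_id:
        Identifier, typically the source file stem.
    fhr:
        Fetal heart rate in bpm; invalid samples are kept verbatim and
        flagged in ``gaps``.
    ucp:
        Uterine contraction pressure, basal value 0.
    sample_rate:
        Samples per second (default 4).
    start_time:
        Time of the first sample in seconds (default 0).
    gaps:
        Per-sample boolean flag marking missing/invalid FHR samples.
    """

    record_id: str
    fhr: np.ndarray
    ucp: np.ndarray
    sample_rate: float = 4.0
    start_time: float = 0.0
    gaps: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.fhr = np.asarray(self.fhr, dtype=float)
        self.ucp = np.asarray(self.ucp, dtype=float)
        if self.fhr.shape != self.ucp.shape:
            raise ValueError("fhr and ucp must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.gaps is None:
            self.gaps = mark_gaps(self.fhr)
        else:
            self.gaps = np.asarray(self.gaps, dtype=bool)
            if self.gaps.shape != self.fhr.shape:
                raise ValueError("gap mask must match series length")

    def __len__(self) -> int:
        return len(self.fhr)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self.fhr) / self.sample_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds from record start (t = start + i / fs)."""
        return self.start_time + np.arange(len(self.fhr)) / self.sample_rate

    def interpolated_fhr(self) -> np.ndarray:
        """FHR with short gaps (≤ 15 s) bridged by linear interpolation.

        Samples inside longer gaps (and gaps touching the record edges)
        remain NaN; callers must treat NaN stretches as analysis-window
        boundaries.
        """
        fhr = self.fhr.astype(float).copy()
        fhr[self.gaps] = np.nan
        if not self.gaps.any():
            return fhr
        max_len = int(round(GAP_INTERP_MAX_S * self.sample_rate))
        idx = np.arange(len(fhr))
        for lo, hi in _bool_runs(self.gaps):
            if hi - lo <= max_len and lo > 0 and hi < len(fhr):
                fhr[lo:hi] = np.interp(idx[lo:hi], [lo - 1, hi], [fhr[lo - 1], fhr[hi]])
        return fhr

    def analysis_windows(self) -> list[tuple[int, int]]:
        """Half-open sample index ranges separated by long gaps."""
        fhr = self.interpolated_fhr()
        valid = np.isfinite(fhr)
        return _bool_runs(valid)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs in a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


# ---------------------------------------------------------------------------
# record readers / writers


def read_record(path: str | Path, dialect: str = "csv") -> TraceRecord:
    """Read a CTG record from disk.

    Parameters
    ----------
    path:
        CSV file, or for the wfdb dialect the record path with or without
        the ``.hea`` extension.
    dialect:
        ``"csv"`` or ``"wfdb"``.
    """
    path = Path(path)
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "wfdb":
        return _read_wfdb(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_csv(path: Path) -> TraceRecord:
    try:
        # round_trip parsing: the default fast float parser can be 1 ulp off,
        # breaking bit-exact write→read round-trips
        df = pd.read_csv(path, float_precision="round_trip")
    except OSError as exc:  # pragma: no cover - passthrough
        raise IOError(f"cannot read {path}") from exc
    cols = {c.lower(): c for c in df.columns}
    missing = {"time", "fhr", "ucp"} - set(cols)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    t = df[cols["time"]].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least two samples")
    steps = np.diff(t)
    dt = steps[0]
    if dt <= 0 or np.any(np.abs(steps - dt) > 1e-6):
        raise FormatError(f"{path}: non-uniform time step")
    return TraceRecord(
        record_id=path.stem,
        fhr=df[cols["fhr"]].to_numpy(dtype=float),
        ucp=df[cols["ucp"]].to_numpy(dtype=float),
        sample_rate=1.0 / dt,
        start_time=float(t[0]),
    )


def _read_wfdb(path: Path) -> TraceRecord:
    """Minimal reader for PhysioNet header/signal pairs, 16-bit format.

    Parses the ``.hea`` text header (record line + one line per signal) and
    decodes the shared ``.dat`` file as interleaved little-endian int16,
    converting ADC units to physical units via ``(raw - baseline) / gain``.
    Only single-segment, single-``.dat`` records in format 16 are supported,
    which covers the CTU-UHB layout.
    """
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise IOError(f"header file {hea} not found")
    lines = [
        ln.strip() for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    if len(head) < 2:
        raise FormatError(f"{hea}: malformed record line")
    name = head[0].split("/")[0]
    nsig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    if nsig < 2:
        raise FormatError(f"{hea}: need at least two signals, got {nsig}")
    sigs = []
    for ln in lines[1 : 1 + nsig]:
        parts = ln.split()
        fname, fmt = parts[0], parts[1].split("x")[0]
        if fmt != "16":
            raise FormatError(f"{hea}: unsupported signal format {fmt!r}")
        gain_spec = parts[2] if len(parts) > 2 else "200"
        gain_str = gain_spec.split("/")[0]
        if "(" in gain_str:
            gain_s, base_s = gain_str.rstrip(")").split("(")
            gain, baseline = float(gain_s), float(base_s)
        else:
            gain, baseline = float(gain_str), 0.0
        if gain == 0:
            gain = 200.0
        desc = " ".join(parts[8:]) if len(parts) > 8 else ""
        sigs.append({"file": fname, "gain": gain, "baseline": baseline, "desc": desc})
    if len({s["file"] for s in sigs}) != 1:
        raise FormatError(f"{hea}: multi-file records are not supported")
    dat = hea.with_name(sigs[0]["file"])
    if not dat.exists():
        raise IOError(f"signal file {dat} not found")
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    raw = raw[: (len(raw) // nsig) * nsig].reshape(-1, nsig)

    def _physical(ch: int) -> np.ndarray:
        s = sigs[ch]
        return (raw[:, ch].astype(float) - s["baseline"]) / s["gain"]

    fhr_ch = _find_channel(sigs, ("FHR",), default=0)
    uc_ch = _find_channel(sigs, ("UC", "UCP"), default=1)
    if fhr_ch == uc_ch:
        raise FormatError(f"{hea}: cannot distinguish FHR and UC channels")
    return TraceRecord(
        record_id=name,
        fhr=_physical(fhr_ch),
        ucp=_physical(uc_ch),
        sample_rate=fs,
    )


def _find_channel(sigs: list[dict], keys: tuple[str, ...], default: int) -> int:
    for i, s in enumerate(sigs):
        desc = s["desc"].upper()
        if any(k in desc.split() or desc == k for k in keys):
            return i
    for i, s in enumerate(sigs):
        if any(k in s["desc"].upper() for k in keys):
            return i
    return default


def write_record(record: TraceRecord, path: str | Path) -> None:
    """Write a record as a three-column csv (time, fhr, ucp)."""
    df = pd.DataFrame(
        {"time": record.times(), "fhr": record.fhr, "ucp": record.ucp}
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# feature-table writers


def write_features(rows, path: str | Path) -> None:
    """Write labeled feature vectors to a CSV in the canonical column order.

    Every row must carry the same feature-set tag (S1/S2/S3); mixing tags in
    one file would silently conflate annotation provenances.
    """
    rows = list(rows)
    tags = {r.set_tag for r in rows}
    if len(tags) > 1:
        raise ValueError(f"mixed feature-set tags {sorted(tags)} in one file")
    data = {c: [getattr(r, c) for r in rows] for c in FEATURE_COLUMNS}
    data["label"] = [r.label for r in rows]
    data["set"] = [r.set_tag for r in rows]
    data["source_id"] = [r.source_id for r in rows]
    pd.DataFrame(data, columns=[*FEATURE_COLUMNS, "label", "set", "source_id"]).to_csv(
        path, index=False
    )


def read_features(path: str | Path):
    """Read a feature CSV written by :func:`write_features`."""
    from .features import LabeledFeatureVector

    df = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing feature columns {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        rows.append(
            LabeledFeatureVector(
                **{c: float(r[c]) for c in FEATURE_COLUMNS},
                label=str(r["label"]) if "label" in df.columns else "",
                set_tag=str(r["set"]) if "set" in df.columns else "S1",
                source_id=str(r.get("source_id", "")),
            )
        )
    return rows
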