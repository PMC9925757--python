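"""Recursive FHR baseline estimation.

The baseline (BL) is the stable heart-rate level around which accelerations
and decelerations are deviations.  Identifying those events requires the
baseline, but a fair baseline requires excluding them first.  The estimator
resolves this circularity as a fixed-point iteration:

1. seed ``bl0`` with the mode of the FHR histogram at 1 bpm bins (the most
   frequently visited rate is almost always baseline, not an event);
2. exclude every contiguous run of samples deviating from the current
   estimate by more than 10 bpm for at least 15 s (the minimum duration of
   an acceleration or deceleration);
3. re-estimate as the inner-80% trimmed mean of the retained samples;
4. repeat until the estimate moves by less than 0.5 bpm, capped at 20
   iterations.

One baseline is produced per analysis window (default: the whole record),
matching the single "Baseline" feature attached to every deceleration row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import TraceRecord, _bool_runs

__all__ = ["BaselineEstimate", "BaselineError", "estimate_baseline"]

#: deviation from the current baseline that marks an event sample
EXCLUDE_DEVIATION_BPM = 10.0
#: minimum run length of deviating samples to be excluded, seconds
EXCLUDE_MIN_RUN_S = 15.0
#: symmetric trim fraction per tail for the trimmed mean (inner 80%)
TRIM_FRACTION = 0.1
CONVERGENCE_TOL_BPM = 0.5
MAX_ITERATIONS = 20
#: minimum usable signal required for a stable estimate, seconds
DEFAULT_MIN_SPAN_S = 600.0


class BaselineError(RuntimeError):
    """Raised when a window holds too little valid signal to estimate BL."""


@dataclass(frozen=True)
class BaselineEstimate:
    """Result of the recursive baseline fit."""

    bl: float                #: baseline, bpm
    iterations: int          #: fixed-point iterations used (≥ 1)
    excluded_fraction: float  #: fraction of samples excluded in the final pass
    converged: bool = True   #: False if the 20-iteration cap was hit


def estimate_baseline(
    record: TraceRecord,
    window: tuple[float, float] | None = None,
    min_span_s: float = DEFAULT_MIN_SPAN_S,
) -> BaselineEstimate:
    """Estimate the FHR baseline over a time window (default: whole record).

    Parameters
    ----------
    record:
        The CTG record; gaps are ignored.
    window:
        Optional ``(t_start, t_end)`` in seconds from record start.
    min_span_s:
        Minimum cumulative non-gap signal required (default 10 minutes).

    Raises
    ------
    BaselineError
        If less than ``min_span_s`` of valid FHR is available.
    """
    fhr = record.fhr.astype(float).copy()
    valid = ~record.gaps
    if window is not None:
        t = record.times()
        inside = (t >= window[0]) & (t < window[1])
        valid = valid & inside
    x = fhr[valid]
    if len(x) < min_span_s * record.sample_rate:
        raise BaselineError(
            f"need ≥ {min_span_s:.0f} s of valid FHR, "
            f"got {len(x) / record.sample_rate:.0f} s"
        )

    bl = _histogram_mode(x)
    min_run = int(round(EXCLUDE_MIN_RUN_S * record.sample_rate))
    iterations = 0
    keep = np.ones(len(x), dtype=bool)
    for iterations in range(1, MAX_ITERATIONS + 1):
        keep = _retained_mask(x, bl, min_run)
        if not keep.any():
            # pathological window: everything looks like an event; fall back
            # to the seed rather than diverge
            return BaselineEstimate(float(bl), iterations, 1.0, converged=False)
        new_bl = float(stats.trim_mean(x[keep], TRIM_FRACTION))
        if abs(new_bl - bl) < CONVERGENCE_TOL_BPM:
            bl = new_bl
            break
        bl = new_bl
    else:
        return BaselineEstimate(
            float(np.clip(bl, 30.0, 250.0)),
            MAX_ITERATIONS,
            1.0 - keep.mean(),
            converged=False,
        )
    return BaselineEstimate(
        float(np.clip(bl, 30.0, 250.0)), iterations, 1.0 - keep.mean()
    )


def _histogram_mode(x: np.ndarray) -> float:
    """Centre of the fullest 1 bpm histogram bin, with data-relative edges.

    Bin edges are anchored at ``min(x)`` so the seed is equivariant under a
    constant shift of the whole signal.
    """
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-9:
        return lo
    edges = np.arange(lo, hi + 1.0, 1.0)
    counts, edges = np.histogram(x, bins=edges)
    k = int(np.argmax(counts))
    return 0.5 * (edges[k] + edges[k + 1])


def _retained_mask(x: np.ndarray, bl: float, min_run: int) -> np.ndarray:
    """Mask of samples kept after removing sustained deviations from bl."""
    deviating = np.abs(x - bl) > EXCLUDE_DEVIATION_BPM
    keep = np.ones(len(x), dtype=bool)
    for lo, hi in _bool_runs(deviating):
        if hi - lo >= min_run:
            keep[lo:hi] = False
    return keep
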