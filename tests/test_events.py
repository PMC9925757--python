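"""Event-point extraction and deceleration–contraction pairing."""

import math

import numpy as np
import pytest

from ctgdecel.baseline import estimate_baseline
from ctgdecel.events import (
    ContractionEventPoints,
    DecelEventPoints,
    UCP_OFF_THRESHOLD,
    extract_contraction_event_points,
    extract_decel_event_points,
    pair_decel_to_contraction,
)
from ctgdecel.fuzzy import find_candidate_segments
from ctgdecel.io import TraceRecord
from ctgdecel.synthetic import simulate


def _record_from_fhr(fhr, ucp=None, fs=4.0):
    fhr = np.asarray(fhr, dtype=float)
    ucp = np.zeros_like(fhr) if ucp is None else np.asarray(ucp, dtype=float)
    return TraceRecord("t", fhr, ucp, sample_rate=fs)


class TestDecelEventPoints:
    def test_piecewise_linear_dip(self):
        """BL 140, down to 115 at t=130, back at t=160: the three landmarks."""
        fs = 4.0
        n = 15 * 60 * 4
        t = np.arange(n) / fs
        fhr = np.full(n, 140.0)
        down = (t >= 100) & (t <= 130)
        fhr[down] = 140.0 - 25.0 * (t[down] - 100) / 30.0
        up = (t > 130) & (t <= 160)
        fhr[up] = 115.0 + 25.0 * (t[up] - 130) / 30.0
        record = _record_from_fhr(fhr)
        segs = find_candidate_segments(record, 140.0)
        assert len(segs) == 1
        ep = extract_decel_event_points(segs[0], record, 140.0)
        assert ep.D_st_time == pytest.approx(100.0, abs=0.25)
        assert ep.D_n_time == pytest.approx(130.0, abs=0.25)
        assert ep.D_e_time == pytest.approx(160.0, abs=0.25)
        assert ep.D_st_point == pytest.approx(140.0, abs=1.0)
        assert ep.D_n_point == pytest.approx(115.0, abs=1.0)
        assert ep.D_e_point == pytest.approx(140.0, abs=1.0)

    def test_planted_event_matches_ground_truth(self, single_dip):
        record, truth = single_dip
        bl = estimate_baseline(record)
        segs = find_candidate_segments(record, bl)
        ep = extract_decel_event_points(segs[0], record, bl)
        gt = truth.events[0].decel_points
        for attr in ("D_st_time", "D_n_time", "D_e_time"):
            assert getattr(ep, attr) == pytest.approx(getattr(gt, attr), abs=0.25)
        for attr in ("D_st_point", "D_n_point", "D_e_point"):
            assert getattr(ep, attr) == pytest.approx(getattr(gt, attr), abs=1.0)

    def test_tied_minima_take_earliest(self):
        fs = 4.0
        n = 15 * 60 * 4
        fhr = np.full(n, 140.0)
        # two equal 3 s minima plateaus at t = 500 and t = 510 inside one dip
        # (wider than the median filter, so both survive preprocessing)
        fhr[int(480 * fs) : int(540 * fs)] = 120.0
        fhr[int(500 * fs) : int(503 * fs)] = 110.0
        fhr[int(510 * fs) : int(513 * fs)] = 110.0
        record = _record_from_fhr(fhr)
        segs = find_candidate_segments(record, 140.0)
        ep = extract_decel_event_points(segs[0], record, 140.0)
        assert ep.D_n_time == pytest.approx(500.0, abs=0.25)

    def test_unflagged_segment_rejected(self, single_dip):
        record, _ = single_dip
        segs = find_candidate_segments(record, 140.0)
        with pytest.raises(ValueError, match="not flagged"):
            extract_decel_event_points(segs[0], record, 140.0, identifiable=False)

    def test_ordering_invariant(self, class_record):
        record, _ = class_record
        bl = estimate_baseline(record)
        for seg in find_candidate_segments(record, bl):
            ep = extract_decel_event_points(seg, record, bl)
            assert ep.D_st_time <= ep.D_n_time <= ep.D_e_time
            assert ep.D_n_point <= min(ep.D_st_point, ep.D_e_point)


class TestContractionEventPoints:
    def test_flat_ucp_yields_nothing(self, flat_record):
        assert extract_contraction_event_points(flat_record) == []

    def test_raised_cosine_against_closed_form(self):
        """Start/end at the analytic off-threshold crossings of the bump."""
        fs = 4.0
        amplitude, start, peak, end = 60.0, 200.0, 230.0, 260.0
        n = int(600 * fs)
        t = np.arange(n) / fs
        ucp = np.zeros(n)
        rise = (t > start) & (t <= peak)
        ucp[rise] = 0.5 * amplitude * (1 - np.cos(np.pi * (t[rise] - start) / (peak - start)))
        fall = (t > peak) & (t < end)
        ucp[fall] = 0.5 * amplitude * (1 + np.cos(np.pi * (t[fall] - peak) / (end - peak)))
        record = _record_from_fhr(np.full(n, 140.0), ucp)
        found = extract_contraction_event_points(record)
        assert len(found) == 1
        c = found[0]
        theta = UCP_OFF_THRESHOLD
        t_on = start + (peak - start) * math.acos(1 - 2 * theta / amplitude) / math.pi
        t_off = peak + (end - peak) * math.acos(2 * theta / amplitude - 1) / math.pi
        assert c.U_p_time == pytest.approx(peak, abs=0.25)
        assert c.U_peak == pytest.approx(amplitude, abs=1.0)
        assert c.U_st_time == pytest.approx(t_on, abs=0.25)
        assert c.U_e_time == pytest.approx(t_off, abs=0.25)
        assert c.U_start == pytest.approx(theta, abs=1.0)
        assert c.U_end == pytest.approx(theta, abs=1.0)

    def test_two_contractions_in_time_order(self, class_record):
        record, truth = class_record
        found = extract_contraction_event_points(record)
        assert len(found) == len(truth.contractions)
        starts = [c.U_st_time for c in found]
        assert starts == sorted(starts)

    def test_sub_threshold_bump_ignored(self):
        fs = 4.0
        n = int(600 * fs)
        t = np.arange(n) / fs
        ucp = 10.0 * np.exp(-((t - 300) ** 2) / 200.0)  # peak 10 < θ_on
        record = _record_from_fhr(np.full(n, 140.0), ucp)
        assert extract_contraction_event_points(record) == []


def _decel(st, nadir, e):
    return DecelEventPoints(st, nadir, e, 140.0, 120.0, 140.0)


def _contraction(st, p, e):
    return ContractionEventPoints(st, p, e, 5.0, 60.0, 5.0)


class TestPairing:
    def test_decel_inside_contraction(self):
        pairs = pair_decel_to_contraction(
            [_decel(100, 130, 160)], [_contraction(90, 130, 170)]
        )
        assert len(pairs) == 1
        assert pairs[0].overlap == pytest.approx(1.0)
        assert not pairs[0].unpaired

    def test_extended_window_beats_distant_contraction(self):
        """Decel starting 10 s after a contraction ends pairs backwards."""
        decel = _decel(200, 240, 280)
        near = _contraction(130, 160, 190)   # ends 10 s before the decel
        far = _contraction(490, 520, 550)    # 300 s later
        pairs = pair_decel_to_contraction([decel], [near, far])
        assert pairs[0].contraction is near
        # brute-force check: overlap with the widened near window only
        lo, hi = near.U_st_time - 30, near.U_e_time + 60
        expect = max(0.0, min(280, hi) - max(200, lo)) / 80.0
        assert pairs[0].overlap == pytest.approx(expect)

    def test_no_contractions_flags_unpaired(self):
        pairs = pair_decel_to_contraction([_decel(100, 130, 160)], [])
        assert pairs[0].unpaired

    def test_each_contraction_claimed_once(self):
        decels = [_decel(100, 130, 160), _decel(180, 210, 240)]
        contraction = _contraction(90, 130, 170)
        pairs = pair_decel_to_contraction(decels, [contraction])
        claimed = [p for p in pairs if p.contraction is contraction]
        assert len(claimed) == 1

    def test_pairing_stable_under_time_translation(self, class_record):
        record, _ = class_record
        bl = estimate_baseline(record)
        segs = find_candidate_segments(record, bl)
        decels = [extract_decel_event_points(s, record, bl) for s in segs]
        contractions = extract_contraction_event_points(record)
        base = pair_decel_to_contraction(decels, contractions)

        shift = 37.0
        decels_s = [
            DecelEventPoints(
                d.D_st_time + shift, d.D_n_time + shift, d.D_e_time + shift,
                d.D_st_point, d.D_n_point, d.D_e_point,
            )
            for d in decels
        ]
        contractions_s = [
            ContractionEventPoints(
                c.U_st_time + shift, c.U_p_time + shift, c.U_e_time + shift,
                c.U_start, c.U_peak, c.U_end,
            )
            for c in contractions
        ]
        shifted = pair_decel_to_contraction(decels_s, contractions_s)
        for p0, p1 in zip(base, shifted):
            assert p0.overlap == pytest.approx(p1.overlap, abs=1e-9)
            assert (p0.contraction is None) == (p1.contraction is None)


class TestFullTupleAgainstSimulator:
    def test_twelve_points_match_ground_truth(self, early_pair):
        """All twelve event points of a planted pair match the ground truth."""
        record, truth = early_pair
        bl = estimate_baseline(record)
        segs = find_candidate_segments(record, bl)
        decel = extract_decel_event_points(segs[0], record, bl)
        contractions = extract_contraction_event_points(record)
        pairs = pair_decel_to_contraction([decel], contractions)
        ev = truth.events[0]
        gt_d, gt_c = ev.decel_points, ev.contraction_points
        got_c = pairs[0].contraction
        for attr in ("D_st_time", "D_n_time", "D_e_time"):
            assert getattr(decel, attr) == pytest.approx(getattr(gt_d, attr), abs=0.25)
        for attr in ("D_st_point", "D_n_point", "D_e_point"):
            assert getattr(decel, attr) == pytest.approx(getattr(gt_d, attr), abs=1.0)
        for attr in ("U_st_time", "U_p_time", "U_e_time"):
            assert getattr(got_c, attr) == pytest.approx(getattr(gt_c, attr), abs=0.25)
        for attr in ("U_start", "U_peak", "U_end"):
            assert getattr(got_c, attr) == pytest.approx(getattr(gt_c, attr), abs=1.0)
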