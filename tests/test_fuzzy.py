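"""Fuzzy identification: membership functions, rulebase, segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctgdecel.baseline import estimate_baseline
from ctgdecel.fuzzy import (
    CONSEQUENTS,
    DEFAULT_RULEBASE,
    N_CATEGORIES,
    T_CATEGORIES,
    apply_rulebase,
    defuzzify_learned,
    find_candidate_segments,
    load_rulebase,
    membership_grades,
    save_rulebase,
)
from ctgdecel.synthetic import simulate


def crisp_cell_lookup(T: float, N: float) -> str:
    """Literal, rule-by-rule crisp reading of the rulebase table (oracle)."""
    if T < 13.5:
        return "ND"
    if N < 12.0:
        return "ND"
    t_cat = (
        "13.5<=T<15" if T < 15 else
        "15<=T<=120" if T <= 120 else
        "120<T<=360" if T <= 360 else
        "360<T<600" if T < 600 else
        "T>=600"
    )
    n_cat = "12<=N<15" if N < 15 else "N>=15"
    table = {
        ("13.5<=T<15", "12<=N<15"): "ND",
        ("13.5<=T<15", "N>=15"): "ND",
        ("15<=T<=120", "12<=N<15"): "ND",
        ("15<=T<=120", "N>=15"): "D",
        ("120<T<=360", "12<=N<15"): "ND",
        ("360<T<600", "12<=N<15"): "PD",
        ("360<T<600", "N>=15"): "PD",
        ("T>=600", "12<=N<15"): "BC",
        ("T>=600", "N>=15"): "BC",
    }
    return table.get((t_cat, n_cat), "D")  # uncovered cell → extrapolated D


class TestMembership:
    def test_deep_interior_grades_are_one(self):
        g = membership_grades(60.0, 20.0)
        assert g.t_grades["15<=T<=120"] == 1.0
        assert g.n_grades["N>=15"] == 1.0
        assert sum(g.t_grades.values()) == 1.0
        assert sum(g.n_grades.values()) == 1.0

    def test_boundary_grades_sum_to_one(self):
        """At T = 15 the two adjacent duration categories split the grade."""
        g = membership_grades(15.0, 20.0)
        assert g.t_grades["13.5<=T<15"] + g.t_grades["15<=T<=120"] == pytest.approx(1.0)
        assert g.t_grades["13.5<=T<15"] == pytest.approx(0.5)

    def test_shallow_depth_fully_nd_category(self):
        g = membership_grades(60.0, 11.0)
        assert g.n_grades["N<12"] == 1.0
        assert g.n_grades["12<=N<15"] == 0.0

    def test_negative_depth_allowed(self):
        g = membership_grades(60.0, -5.0)
        assert g.n_grades["N<12"] == 1.0
        assert g.n_grades["N>=15"] == 0.0

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError):
            membership_grades(0.0, 20.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        T=st.floats(min_value=0.1, max_value=1200.0),
        N=st.floats(min_value=-10.0, max_value=60.0),
    )
    def test_grades_bounded_and_cover_axis(self, T, N):
        """Grades lie in [0,1] and every point belongs somewhere.

        The trapezoids tile each axis: total grade is at least 1 everywhere
        (exactly 1 except inside the narrow 13.5–15 s category, whose two
        shoulder zones overlap) and never above 1.5.
        """
        g = membership_grades(T, N)
        for v in list(g.t_grades.values()) + list(g.n_grades.values()):
            assert 0.0 <= v <= 1.0
        assert 1.0 - 1e-9 <= sum(g.t_grades.values()) <= 1.5
        assert sum(g.n_grades.values()) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("boundary,left,right", [
        (13.5, "T<13.5", "13.5<=T<15"),
        (15.0, "13.5<=T<15", "15<=T<=120"),
        (120.0, "15<=T<=120", "120<T<=360"),
        (360.0, "120<T<=360", "360<T<600"),
        (600.0, "360<T<600", "T>=600"),
    ])
    def test_adjacent_grades_sum_to_one_at_each_boundary(self, boundary, left, right):
        g = membership_grades(boundary, 20.0)
        assert g.t_grades[left] + g.t_grades[right] == pytest.approx(1.0)


class TestRulebase:
    def test_shipped_rulebase_structure(self):
        """16 rules; one D, two PD, two BC, the rest ND."""
        assert len(DEFAULT_RULEBASE) == 16
        by_consequent = {c: 0 for c in CONSEQUENTS}
        for r in DEFAULT_RULEBASE:
            by_consequent[r.consequent] += 1
        assert by_consequent == {"ND": 11, "D": 1, "PD": 2, "BC": 2}

    @pytest.mark.parametrize(
        "T,N,winner,flag",
        [
            (60.0, 20.0, "D", True),
            (10.0, 30.0, "ND", False),
            (400.0, 13.0, "PD", True),
            (700.0, 20.0, "BC", False),
            (60.0, 11.0, "ND", False),
            (480.0, 25.0, "PD", True),
            (700.0, 13.5, "BC", False),
            (14.25, 25.0, "ND", False),
        ],
    )
    def test_rulebase_examples(self, T, N, winner, flag):
        decision = apply_rulebase(membership_grades(T, N))
        assert decision.winner == winner
        assert decision.identifiable is flag

    def test_exhaustive_interior_truth_table(self):
        """Every category cell's interior point reproduces the table entry."""
        t_interior = [6.0, 14.25, 60.0, 240.0, 480.0, 700.0]
        n_interior = [6.0, 13.5, 25.0]
        for T in t_interior:
            for N in n_interior:
                decision = apply_rulebase(membership_grades(T, N))
                assert decision.winner == crisp_cell_lookup(T, N), (T, N)

    def test_off_shoulder_points_match_crisp_lookup(self):
        """Away from the boundary shoulders the fuzzy winner is the crisp cell."""
        rng = np.random.default_rng(0)
        t_bounds = [(13.5, 1.0), (15.0, 1.0), (120.0, 10.0), (360.0, 10.0), (600.0, 10.0)]
        n_bounds = [(12.0, 0.5), (15.0, 0.5)]
        count = 0
        while count < 500:
            T = float(rng.uniform(1.0, 1200.0))
            N = float(rng.uniform(0.0, 60.0))
            if any(abs(T - b) <= e for b, e in t_bounds):
                continue
            if any(abs(N - b) <= e for b, e in n_bounds):
                continue
            decision = apply_rulebase(membership_grades(T, N))
            assert decision.winner == crisp_cell_lookup(T, N), (T, N)
            count += 1

    def test_uncovered_cell_without_extrapolation_has_no_activation(self):
        g = membership_grades(240.0, 25.0)
        decision = apply_rulebase(g, include_extrapolated=False)
        assert max(decision.activations.values()) == 0.0
        with_extra = apply_rulebase(g, include_extrapolated=True)
        assert with_extra.winner == "D"

    def test_rulebase_round_trips_through_csv(self, tmp_path):
        path = tmp_path / "rules.csv"
        save_rulebase(path)
        back = load_rulebase(path)
        assert len(back) == 16
        assert {(r.t_category, r.n_category, r.consequent) for r in back} == {
            (r.t_category, r.n_category, r.consequent) for r in DEFAULT_RULEBASE
        }


class TestSegmentation:
    def test_flat_signal_yields_no_segments(self, flat_record):
        bl = estimate_baseline(flat_record)
        assert find_candidate_segments(flat_record, bl) == []

    def test_single_planted_dip_recovered(self, single_dip):
        record, truth = single_dip
        bl = estimate_baseline(record)
        segs = find_candidate_segments(record, bl)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.T == pytest.approx(60.0, abs=0.25)
        assert seg.N == pytest.approx(20.0, abs=0.5)
        assert seg.p1 <= bl.bl
        assert seg.pn >= bl.bl

    def test_segment_invariants(self, class_record):
        record, _ = class_record
        bl = estimate_baseline(record)
        for seg in find_candidate_segments(record, bl):
            assert seg.t1 <= seg.t_min <= seg.tn
            assert seg.T > 0
            assert seg.N == pytest.approx(seg.bl - seg.p_min)

    def test_deceleration_bound_on_eligibility(self):
        """Only segments with 15 ≤ T < 600 and N ≥ 15 are identifiable."""
        for T, N, eligible in [
            (14.0, 30.0, False),   # too brief
            (60.0, 30.0, True),
            (650.0, 30.0, False),  # a baseline change, not a deceleration
            (60.0, 13.0, False),   # too shallow
        ]:
            decision = apply_rulebase(membership_grades(T, N))
            assert decision.identifiable is eligible


class TestLearnedDefuzzifier:
    @staticmethod
    def _grade_dataset(n_grid: int = 18):
        rng = np.random.default_rng(2)
        data = []
        for _ in range(n_grid * n_grid):
            T = float(rng.uniform(1.0, 1200.0))
            N = float(rng.uniform(0.0, 60.0))
            g = membership_grades(T, N)
            data.append((g, int(apply_rulebase(g).identifiable)))
        return data

    def test_learner_recovers_rule_surface(self):
        """Trained on the argmax's own labels, held-out accuracy ≥ 0.99."""
        data = self._grade_dataset()
        model = defuzzify_learned(data, seed=1)
        assert model.cv_accuracy >= 0.99

    def test_too_few_examples_rejected(self):
        data = self._grade_dataset()[:10]
        with pytest.raises(ValueError, match="50"):
            defuzzify_learned(data, seed=1)

    def test_single_class_rejected(self):
        g = membership_grades(60.0, 20.0)
        with pytest.raises(ValueError, match="both classes"):
            defuzzify_learned([(g, 1)] * 60, seed=1)

    def test_seeded_folds_reproducible(self):
        data = self._grade_dataset(10)
        m1 = defuzzify_learned(data, seed=7)
        m2 = defuzzify_learned(data, seed=7)
        for (tr1, te1), (tr2, te2) in zip(m1.fold_splits, m2.fold_splits):
            np.testing.assert_array_equal(tr1, tr2)
            np.testing.assert_array_equal(te1, te2)
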