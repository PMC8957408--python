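"""Rule firing, aggregation, defuzzification and end-to-end classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiotriage import (
    AggregatedOutput,
    FuzzifiedRecord,
    PatientRecord,
    UnclassifiableRecord,
    aggregate,
    canonical_output,
    classify,
    defuzzify_center_of_sums,
    defuzzify_centroid,
    firing_strength,
)
from cardiotriage.membership import FuzzySet
from cardiotriage.inference import OutputVariable
from cardiotriage.rulebase import FuzzyRule


def _rule(consequent, **antecedent):
    return FuzzyRule(rule_id=0, antecedent=tuple(antecedent.items()),
                     consequent=consequent)


class TestFiringStrength:
    def test_min_of_antecedent_degrees(self):
        fz = FuzzifiedRecord(degrees={
            "a": {"x": 1.0}, "b": {"y": 0.5}, "c": {"z": 0.8},
        })
        rule = _rule(2, a="x", b="y", c="z")
        assert firing_strength(rule, fz) == 0.5

    def test_zero_degree_annihilates(self):
        fz = FuzzifiedRecord(degrees={"a": {"x": 0.0}, "b": {"y": 0.9}})
        assert firing_strength(_rule(1, a="x", b="y"), fz) == 0.0

    def test_all_ones_gives_one(self):
        fz = FuzzifiedRecord(degrees={"a": {"x": 1.0}, "b": {"y": 1.0}})
        assert firing_strength(_rule(3, a="x", b="y"), fz) == 1.0

    def test_unresolvable_antecedent_errors(self):
        fz = FuzzifiedRecord(degrees={"a": {"x": 1.0}})
        with pytest.raises(KeyError):
            firing_strength(_rule(1, a="missing_set"), fz)


class TestAggregate:
    def test_per_class_max(self):
        out = canonical_output()
        fired = [(_rule(2, a="x"), 0.3), (_rule(2, a="y"), 0.7)]
        agg = aggregate(fired, out)
        assert agg.activations == {1: 0.0, 2: 0.7, 3: 0.0}

    def test_empty_fired_list_all_zero(self):
        agg = aggregate([], canonical_output())
        assert set(agg.activations.values()) == {0.0}

    def test_one_rule_per_class(self):
        fired = [(_rule(1, a="x"), 0.2), (_rule(2, a="y"), 0.5),
                 (_rule(3, a="z"), 0.1)]
        agg = aggregate(fired, canonical_output())
        assert agg.activations == {1: 0.2, 2: 0.5, 3: 0.1}

    @settings(max_examples=100, deadline=None)
    @given(s1=st.floats(0, 1), s2=st.floats(0, 1))
    def test_raising_a_strength_never_lowers_activation(self, s1, s2):
        out = canonical_output()
        lo, hi = sorted([s1, s2])
        a_lo = aggregate([(_rule(2, a="x"), lo)], out).activations[2]
        a_hi = aggregate([(_rule(2, a="x"), hi)], out).activations[2]
        assert a_hi >= a_lo


class TestDefuzzify:
    def test_single_symmetric_triangle_returns_apex(self):
        """The class-2 output triangle is symmetric within the axis, so the
        center of sums must land exactly on its apex."""
        out = canonical_output()
        agg = AggregatedOutput(output=out, activations={1: 0.0, 2: 0.6, 3: 0.0})
        assert defuzzify_center_of_sums(agg) == pytest.approx(2.0, abs=1e-9)

    def test_two_congruent_sets_equal_activation_gives_midpoint(self):
        out = OutputVariable(
            axis=(0.0, 10.0),
            sets={1: FuzzySet("a", "triangle", (1, 2, 3)),
                  2: FuzzySet("b", "triangle", (5, 6, 7)),
                  3: FuzzySet("c", "triangle", (8, 9, 10))},
        )
        agg = AggregatedOutput(output=out, activations={1: 0.5, 2: 0.5, 3: 0.0})
        assert defuzzify_center_of_sums(agg, n_points=2001) == pytest.approx(
            4.0, abs=1e-6
        )

    def test_all_zero_activations_is_unclassifiable(self):
        agg = AggregatedOutput(output=canonical_output(),
                               activations={1: 0.0, 2: 0.0, 3: 0.0})
        with pytest.raises(UnclassifiableRecord):
            defuzzify_center_of_sums(agg)
        with pytest.raises(UnclassifiableRecord):
            defuzzify_centroid(agg)

    @settings(max_examples=50, deadline=None)
    @given(a1=st.floats(0.01, 1), a2=st.floats(0.01, 1), a3=st.floats(0.01, 1))
    def test_grid_agrees_with_10x_resolution_brute_force(self, a1, a2, a3):
        """Default-grid integration of the algebraic sum matches a 10x-finer
        independent trapezoidal integral to 1e-6 relative.

        Activations below ~0.01 are excluded: there the uniform fine-grid
        oracle's own discretization error exceeds the comparison tolerance
        (the implementation integrates the piecewise-linear curves exactly).
        """
        out = canonical_output()
        acts = {1: a1, 2: a2, 3: a3}
        agg = AggregatedOutput(output=out, activations=acts)
        z = np.linspace(out.axis[0], out.axis[1], 10001)
        total = np.zeros_like(z)
        for c, a in acts.items():
            total += np.minimum(out.set_curve(c, z), a)
        brute = np.trapezoid(z * total, z) / np.trapezoid(total, z)
        got = defuzzify_center_of_sums(agg)
        assert got == pytest.approx(brute, rel=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(a=st.floats(0.01, 1), cls=st.sampled_from([1, 2, 3]))
    def test_center_of_sums_equals_centroid_for_single_class(self, a, cls):
        """With exactly one activated class the algebraic sum and the
        pointwise max coincide, so the two defuzzifiers must agree."""
        acts = {1: 0.0, 2: 0.0, 3: 0.0}
        acts[cls] = a
        agg = AggregatedOutput(output=canonical_output(), activations=acts)
        assert defuzzify_center_of_sums(agg) == pytest.approx(
            defuzzify_centroid(agg), abs=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(a1=st.floats(0, 1), a2=st.floats(0, 1), a3=st.floats(0, 1))
    def test_z_star_stays_on_the_output_axis(self, a1, a2, a3):
        if a1 + a2 + a3 == 0:
            return
        out = canonical_output()
        agg = AggregatedOutput(output=out, activations={1: a1, 2: a2, 3: a3})
        z = defuzzify_center_of_sums(agg)
        assert out.axis[0] <= z <= out.axis[1]


class TestClassify:
    @pytest.fixture()
    def sample_record(self):
        # the worked query record: asymptomatic angina, low BP, medium
        # cholesterol, normal sugar, hypertrophy ECG, low max HR, risk-level
        # old peak, normal thallium, female, very old
        return PatientRecord(chest_pain=4, blood_pressure=100, cholesterol=210,
                             blood_sugar=90, max_heart_rate=80, ecg=2,
                             old_peak=3.0, thallium=3, gender=1, age=70,
                             record_id=0)

    def test_worked_record_classifies_within_candidate_bound(
        self, sample_record, canonical_base, canonical_index
    ):
        res = classify(sample_record, canonical_base, canonical_index)
        assert res.search_scope == "indexed"
        assert res.fired_rule_count <= 3456
        assert res.criticality_class in (1, 2, 3)
        assert res.protection_ring == res.criticality_class
        assert 0.5 <= res.z_star <= 3.5

    def test_index_does_not_change_semantics(
        self, sample_record, canonical_base, canonical_index
    ):
        a = classify(sample_record, canonical_base, canonical_index)
        b = classify(sample_record, canonical_base)
        assert (a.z_star, a.criticality_class, a.fired_rule_count) == (
            b.z_star, b.criticality_class, b.fired_rule_count
        )

    def test_single_class_activation_yields_that_class(self, toy_base):
        """A record whose only fired rules share one consequent must get that
        class and the matching ring."""
        # force every rule to class 3
        for i, r in enumerate(toy_base.rules):
            toy_base.rules[i] = FuzzyRule(r.rule_id, r.antecedent, 3)
        rec = PatientRecord(record_id=0)
        rec.color = 0.0
        rec.size = 5.0
        res = classify(rec, toy_base)
        assert res.criticality_class == 3
        assert res.protection_ring == 3

    def test_unknown_defuzzifier_rejected(self, sample_record, canonical_base):
        with pytest.raises(ValueError, match="defuzzifier"):
            classify(sample_record, canonical_base, defuzzifier="mean-of-max")

    def test_centroid_switch_runs(self, sample_record, canonical_base, canonical_index):
        res = classify(sample_record, canonical_base, canonical_index,
                       defuzzifier="centroid")
        assert 0.5 <= res.z_star <= 3.5
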