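"""Per-window aggregation, filters, and tooltip payload assembly."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from chromocanvas.aggregation import (FilterSpec, aggregate,
                                      aggregate_windows, apply_filter,
                                      build_tooltip_payload)
from chromocanvas.io_formats import Annotation, ChromosomeSpec
from chromocanvas.windowing import (assign_segment, build_windows,
                                    plan_windows)


def _windows_with(members_values, n=3):
    """Build n windows over chr1:[1,30]; members_values maps idx->{id:val}."""
    chrom = ChromosomeSpec("chr1", 1, 10 * n)
    windows = build_windows(chrom, plan_windows([chrom], n))
    annots = {}
    for idx, mv in members_values.items():
        for eid, val in mv.items():
            windows[idx].members.append(eid)
            annots[eid] = Annotation(eid, "chr1", 1 + 10 * idx, 1 + 10 * idx,
                                     val)
    return windows, annots


class TestAggregate:
    @pytest.mark.parametrize("values, op, expected", [
        ([1.0, 2.0, 3.0], "mean", 2.0),
        ([-2.0, 5.0], "max", 5.0),
        ([0.5, 0.25, 0.25], "sum", 1.0),
        ([4.0, -1.0], "min", -1.0),
        ([], "count", 0.0),
        ([1.0, 2.0], "count", 2.0)])
    def test_examples(self, values, op, expected):
        assert aggregate(values, op) == expected

    @pytest.mark.parametrize("op", ["sum", "mean", "min", "max"])
    def test_empty_list_fails_for_arithmetic_ops(self, op):
        with pytest.raises(ValueError):
            aggregate([], op)

    def test_unknown_op_rejected(self):
        with pytest.raises(ValueError):
            aggregate([1.0], "median")


class TestAggregateWindows:
    def test_mean_of_members(self):
        windows, annots = _windows_with({0: {"a": 1.0, "b": 3.0}})
        aws = aggregate_windows(windows, annots, "mean")
        assert aws[0].agg_value == 2.0
        assert aws[1].agg_value is None

    def test_empty_window_count_zero(self):
        windows, annots = _windows_with({})
        aws = aggregate_windows(windows, annots, "count")
        assert [aw.agg_value for aw in aws] == [0.0, 0.0, 0.0]

    def test_segment_contributes_full_value_per_window(self):
        chrom = ChromosomeSpec("chr1", 1, 30)
        windows = build_windows(chrom, plan_windows([chrom], 3))
        a = Annotation("seg", "chr1", 5, 25, 2.0)
        assign_segment(a, windows)
        aws = aggregate_windows(windows, {"seg": a}, "sum")
        assert [aw.agg_value for aw in aws] == [2.0, 2.0, 2.0]

    def test_categorical_members_tallied_not_aggregated(self):
        windows, annots = _windows_with(
            {0: {"a": "grpX", "b": "grpX", "c": 4.0, "d": "grpY"}})
        aws = aggregate_windows(windows, annots, "mean")
        assert aws[0].agg_value == 4.0
        assert aws[0].group_counts == {"grpX": 2, "grpY": 1}
        assert aggregate_windows(windows, annots, "count")[0].agg_value == 4.0

    def test_count_equals_membership_cardinality(self):
        windows, annots = _windows_with({0: {"a": 1.0, "b": "g"}, 2: {"c": None}})
        for aw in aggregate_windows(windows, annots, "count"):
            assert aw.agg_value == len(aw.window.members) == aw.count

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=20))
    def test_mean_times_n_equals_sum(self, values):
        mv = {0: {f"e{i}": v for i, v in enumerate(values)}}
        windows, annots = _windows_with(mv)
        mean = aggregate_windows(windows, annots, "mean")[0].agg_value
        total = aggregate_windows(windows, annots, "sum")[0].agg_value
        assert mean * len(values) == pytest.approx(total, rel=1e-9, abs=1e-9)

    @given(st.permutations(list(range(6))))
    def test_permutation_invariant(self, order):
        values = [1.5, -2.0, 0.0, 7.25, 3.5, -1.0]
        mv = {0: {f"e{i}": values[i] for i in order}}
        windows, annots = _windows_with(mv)
        for op in ("sum", "mean", "min", "max", "count"):
            assert aggregate_windows(windows, annots, op)[0].agg_value == \
                aggregate([float(v) for v in values], op)


class TestFilters:
    def test_window_count_threshold(self):
        windows, annots = _windows_with(
            {0: {f"a{i}": 1.0 for i in range(3)},
             1: {f"b{i}": 1.0 for i in range(5)},
             2: {f"c{i}": 1.0 for i in range(7)}})
        aws = aggregate_windows(windows, annots, "count")
        spec = FilterSpec("window", "count", "ge", (5,), "yellow")
        assert apply_filter(spec, aws) == {"chr1:1", "chr1:2"}

    def test_abs_value_threshold_on_features(self):
        feats = [Annotation("f1", "c", 1, 1, -3.0),
                 Annotation("f2", "c", 2, 2, 0.5),
                 Annotation("f3", "c", 3, 3, 2.1)]
        spec = FilterSpec("feature", "value", "abs_ge", (2.0,), "orange")
        assert apply_filter(spec, feats) == {"f1", "f3"}

    def test_between_is_closed(self):
        feats = [Annotation(f"f{i}", "c", i + 1, i + 1, v)
                 for i, v in enumerate([0.0, 0.5, 1.0, 2.0])]
        spec = FilterSpec("feature", "value", "between", (0.0, 1.0), "red")
        assert apply_filter(spec, feats) == {"f0", "f1", "f2"}

    def test_valueless_features_never_marked(self):
        feats = [Annotation("f1", "c", 1, 1), Annotation("f2", "c", 2, 2, "g")]
        spec = FilterSpec("feature", "value", "ge", (0.0,), "red")
        assert apply_filter(spec, feats) == set()

    def test_threshold_arity_enforced(self):
        with pytest.raises(ValueError):
            FilterSpec("feature", "value", "between", (1.0,), "red")
        with pytest.raises(ValueError):
            FilterSpec("feature", "value", "ge", (1.0, 2.0), "red")

    def test_wrong_field_for_scope_fails(self):
        feats = [Annotation("f1", "c", 1, 1, 1.0)]
        with pytest.raises(ValueError):
            apply_filter(FilterSpec("feature", "count", "ge", (1,), "r"), feats)

    @given(st.lists(st.floats(-50, 50), max_size=100),
           st.sampled_from(["lt", "le", "gt", "ge", "eq", "abs_ge"]),
           st.floats(-10, 10))
    def test_matches_brute_force_predicate_and_idempotent(self, values, op, t):
        feats = [Annotation(f"f{i}", "c", i + 1, i + 1, v)
                 for i, v in enumerate(values)]
        spec = FilterSpec("feature", "value", op, (t,), "red")
        import operator
        ops = {"lt": operator.lt, "le": operator.le, "gt": operator.gt,
               "ge": operator.ge, "eq": operator.eq,
               "abs_ge": lambda x, y: abs(x) >= y}
        expected = {f.element_id for f in feats if ops[op](f.value, t)}
        marked = apply_filter(spec, feats)
        assert marked == expected
        assert apply_filter(spec, feats) == marked  # idempotent


class TestTooltips:
    def test_payload_lists_members_and_span(self):
        windows, annots = _windows_with({0: {"geneA": 2.5}})
        aw = aggregate_windows(windows, annots, "mean")[0]
        payload = build_tooltip_payload(aw, annots)
        assert payload["span"] == "1–10"
        assert payload["members"] == [{"id": "geneA", "value": 2.5}]
        assert payload["aggregate"] == 2.5

    def test_empty_window_payload(self):
        windows, annots = _windows_with({})
        aw = aggregate_windows(windows, annots, "count")[1]
        payload = build_tooltip_payload(aw, annots)
        assert payload["n_elements"] == 0 and payload["members"] == []

    def test_hyperlink_carried_verbatim(self):
        chrom = ChromosomeSpec("chr1", 1, 10)
        windows = build_windows(chrom, plan_windows([chrom], 1))
        a = Annotation("g", "chr1", 2, 3, 1.0, "https://x.org/g?q=1&r=2")
        windows[0].members.append("g")
        aw = aggregate_windows(windows, {"g": a}, "count")[0]
        payload = build_tooltip_payload(aw, {"g": a})
        assert payload["members"][0]["hyperlink"] == "https://x.org/g?q=1&r=2"

    def test_active_tags_included(self):
        windows, annots = _windows_with({0: {"a": 1.0}})
        aw = aggregate_windows(windows, annots, "count")[0]
        payload = build_tooltip_payload(aw, annots, active_tags=["dense"])
        assert payload["tags"] == ["dense"]
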