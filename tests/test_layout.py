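"""Canvas geometry: track layout, coordinate map, data tracks, labels."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from chromocanvas.aggregation import aggregate_windows
from chromocanvas.colors import parse_color
from chromocanvas.io_formats import Annotation, ChromosomeSpec
from chromocanvas.layout import (CanvasBox, TrackSet, TrackStyle,
                                 data_track_box, genomic_to_canvas,
                                 heatmap_color, layout_tracks,
                                 place_data_track, place_labels)
from chromocanvas.windowing import (WindowingPlan, assign_point,
                                    build_windows, plan_windows)


def _set(set_id, lengths, target=10, **style):
    chroms = [ChromosomeSpec(f"{set_id}c{i + 1}", 1, l)
              for i, l in enumerate(lengths)]
    return TrackSet(set_id, chroms, plan_windows(chroms, target),
                    TrackStyle(**style))


class TestLayoutTracks:
    def test_width_proportional_to_window_count(self):
        s = _set("s1", [100, 50], target=10)
        boxes = layout_tracks([s], canvas_width=1000.0)
        assert boxes[("s1", "s1c1")].width == pytest.approx(1000.0)
        assert boxes[("s1", "s1c2")].width == pytest.approx(500.0)

    def test_sets_stack_vertically_in_order(self):
        s1, s2 = _set("s1", [100]), _set("s2", [80, 60])
        boxes = layout_tracks([s1, s2], canvas_width=500.0)
        bottom_of_first = boxes[("s1", "s1c1")].y + boxes[("s1", "s1c1")].height
        for key in (("s2", "s2c1"), ("s2", "s2c2")):
            assert boxes[key].y > bottom_of_first

    def test_boxes_vertically_disjoint(self):
        boxes = layout_tracks([_set("s1", [100, 90, 80])], canvas_width=400.0)
        spans = sorted((b.y, b.y + b.height) for b in boxes.values())
        for (_, hi), (lo, _) in zip(spans, spans[1:]):
            assert lo >= hi

    def test_pure_function(self):
        sets = [_set("s1", [100, 50]), _set("s2", [70])]
        assert layout_tracks(sets, 800.0) == layout_tracks(sets, 800.0)

    def test_per_set_independence(self):
        s1 = _set("s1", [100, 50])
        before = layout_tracks([s1, _set("s2", [70])], 800.0)
        after = layout_tracks([s1, _set("s2", [70, 30, 20])], 800.0)
        for key, box in before.items():
            if key[0] == "s1":
                assert after[key] == box

    def test_common_scale_shares_px_per_window(self):
        s1, s2 = _set("s1", [100], target=10), _set("s2", [50], target=5)
        boxes = layout_tracks([s1, s2], 1000.0, common_scale=True)
        # both plans use 10 bp windows; equal px-per-window across sets
        w1 = boxes[("s1", "s1c1")].width / 10
        w2 = boxes[("s2", "s2c1")].width / 5
        assert w1 == pytest.approx(w2)
        # without common scale each set fills the canvas independently
        free = layout_tracks([s1, s2], 1000.0)
        assert free[("s2", "s2c1")].width == pytest.approx(1000.0)

    def test_canvas_too_narrow_fails(self):
        with pytest.raises(ValueError, match="too narrow"):
            layout_tracks([_set("s1", [1000], target=500)], canvas_width=100.0)


class TestGenomicToCanvas:
    @pytest.fixture
    def setup(self):
        return CanvasBox(10.0, 0.0, 200.0, 20.0), ChromosomeSpec("c", 1, 101)

    def test_boundaries_and_midpoint(self, setup):
        box, chrom = setup
        assert genomic_to_canvas(1, box, chrom) == box.x
        assert genomic_to_canvas(101, box, chrom) == box.x + box.width
        assert genomic_to_canvas(51, box, chrom) == pytest.approx(110.0, abs=0.5)

    def test_out_of_range_fails(self, setup):
        box, chrom = setup
        with pytest.raises(ValueError):
            genomic_to_canvas(0, box, chrom)

    @given(st.integers(1, 100))
    def test_strictly_monotone(self, pos):
        box, chrom = CanvasBox(0.0, 0.0, 500.0, 20.0), ChromosomeSpec("c", 1, 101)
        assert genomic_to_canvas(pos, box, chrom) < \
            genomic_to_canvas(pos + 1, box, chrom)


def _scatter_setup(values, categories=None):
    chrom = ChromosomeSpec("c", 1, 100)
    windows = build_windows(chrom, plan_windows([chrom], 10))
    annots = {}
    for i, v in enumerate(values):
        a = Annotation(f"f{i}", "c", 1 + 10 * i, 1 + 10 * i,
                       categories[i] if categories else v)
        assign_point(a, windows)
        annots[a.element_id] = a
    aws = aggregate_windows(windows, annots, "count")
    return chrom, aws, annots


class TestDataTracks:
    def test_scatter_y_rescale(self):
        chrom, aws, annots = _scatter_setup([0.0, 5.0, 10.0])
        style = TrackStyle(plot_type="scatter", track_height=100.0)
        box = CanvasBox(0.0, 0.0, 500.0, 100.0)
        marks, _ = place_data_track(aws, style, box, chrom, annots)
        offsets = {m.element_id: m.y - box.y for m in marks}
        assert offsets == {"f0": 100.0, "f1": 50.0, "f2": 0.0}

    def test_reference_line_between_signs(self):
        chrom, aws, annots = _scatter_setup([-4.0, 3.0])
        style = TrackStyle(plot_type="scatter", y_reference=0.0,
                           track_height=80.0)
        box = CanvasBox(0.0, 0.0, 500.0, 80.0)
        marks, _ = place_data_track(aws, style, box, chrom, annots)
        ref = next(m for m in marks if m.kind == "refline")
        neg = next(m for m in marks if m.element_id == "f0")
        pos = next(m for m in marks if m.element_id == "f1")
        assert pos.y < ref.y < neg.y  # larger values sit higher

    def test_categorical_scatter_colors_and_legend(self):
        chrom, aws, annots = _scatter_setup(
            [None] * 4, categories=["glycolysis", "tca", "glycolysis", "ppp"])
        style = TrackStyle(plot_type="scatter")
        box = CanvasBox(0.0, 0.0, 500.0, 60.0)
        marks, legend = place_data_track(aws, style, box, chrom, annots)
        assert len({m.color for m in marks}) == 3
        assert [c for c, _ in legend] == ["glycolysis", "tca", "ppp"]

    def test_bar_heights_proportional(self):
        chrom, aws, annots = _scatter_setup([1.0, 2.0, 4.0])
        aws = aggregate_windows(
            [aw.window for aw in aws], annots, "sum")
        style = TrackStyle(plot_type="bar", track_height=100.0)
        box = CanvasBox(0.0, 0.0, 500.0, 100.0)
        marks, _ = place_data_track(aws, style, box, chrom, annots)
        bars = {m.element_id: m.height for m in marks if m.kind == "bar"}
        assert bars["c:0"] == pytest.approx(25.0)
        assert bars["c:2"] == pytest.approx(100.0)

    def test_no_numeric_data_fails(self):
        chrom, aws, annots = _scatter_setup([])
        aws = aggregate_windows([aw.window for aw in aws], annots, "sum")
        style = TrackStyle(plot_type="bar")
        with pytest.raises(ValueError):
            place_data_track(aws, style, CanvasBox(0, 0, 10, 10), chrom, annots)
        style = TrackStyle(plot_type="scatter")
        with pytest.raises(ValueError):
            place_data_track(aws, style, CanvasBox(0, 0, 10, 10), chrom, annots)


class TestHeatmapColor:
    def test_anchor_values_exact(self):
        anchors = ("#112233", "#aabbcc", "#ffffff")
        assert heatmap_color(0.0, 0.0, 1.0, anchors) == "#112233"
        assert heatmap_color(0.5, 0.0, 1.0, anchors) == "#aabbcc"
        assert heatmap_color(1.0, 0.0, 1.0, anchors) == "#ffffff"

    def test_black_white_midpoint(self):
        mid = parse_color(heatmap_color(0.5, 0.0, 1.0, ("black", "white")))
        for channel in mid:
            assert abs(channel - 128) <= 1

    def test_out_of_range_clamps(self):
        anchors = ("#000000", "#ffffff")
        assert heatmap_color(-10.0, 0.0, 1.0, anchors) == "#000000"
        assert heatmap_color(99.0, 0.0, 1.0, anchors) == "#ffffff"

    def test_degenerate_range_maps_to_last_anchor(self):
        assert heatmap_color(5.0, 2.0, 2.0, ("#000000", "#ff0000")) == "#ff0000"

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_per_channel(self, t1, t2):
        t1, t2 = sorted((t1, t2))
        anchors = ("#000000", "#4682b4")
        c1 = parse_color(heatmap_color(t1, 0.0, 1.0, anchors))
        c2 = parse_color(heatmap_color(t2, 0.0, 1.0, anchors))
        assert all(a <= b for a, b in zip(c1, c2))


class TestLabels:
    def _chrom_box(self):
        return ChromosomeSpec("c", 1, 1001), CanvasBox(0.0, 0.0, 1000.0, 20.0)

    def test_distant_labels_share_row(self):
        chrom, box = self._chrom_box()
        feats = [Annotation("aaaaaaaa", "c", 1, 1),
                 Annotation("bbbbbbbb", "c", 501, 501)]
        labels = place_labels(feats, box, chrom)
        assert {l.row for l in labels} == {0}

    def test_near_labels_stagger(self):
        chrom, box = self._chrom_box()
        feats = [Annotation("aaaaaaaa", "c", 1, 1),
                 Annotation("bbbbbbbb", "c", 11, 11)]
        labels = place_labels(feats, box, chrom)
        assert sorted(l.row for l in labels) == [0, 1]

    def test_empty_input(self):
        chrom, box = self._chrom_box()
        assert place_labels([], box, chrom) == []

    @given(st.lists(st.integers(1, 1001), max_size=40))
    def test_no_two_labels_in_a_row_intersect(self, starts):
        chrom, box = self._chrom_box()
        feats = [Annotation(f"lbl{i:03d}", "c", s, s)
                 for i, s in enumerate(starts)]
        labels = place_labels(feats, box, chrom)
        by_row = {}
        for l in labels:
            by_row.setdefault(l.row, []).append((l.x, l.x + len(l.text) * 7.0))
        for spans in by_row.values():
            spans.sort()
            for (_, hi), (lo, _) in zip(spans, spans[1:]):
                assert lo >= hi
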