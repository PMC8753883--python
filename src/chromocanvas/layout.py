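"""Canvas geometry: multi-track arrangement and genomic→pixel mapping.

A *track set* is one ordered group of chromosomes laid out together; a
plot may stack several sets (homologous chromosome copies of a phased
polyploid assembly, different species, different conditions), each
windowed and scaled independently so sets of different size and number
coexist on one canvas.

Within a set every chromosome shares one bp-per-px scale: box width is
proportional to window count, the longest chromosome spanning the full
drawable width, so relative lengths are visually truthful.  Sets are
stacked vertically in input order.  Each chromosome row reserves a data
track area above the chromosome band for scatter/bar marks and a label
area below.

All geometry here is pure arithmetic — identical inputs always give
identical pixel output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .aggregation import AggregatedWindow
from .colors import (DEFAULT_CATEGORY_PALETTE, DEFAULT_HEATMAP_ANCHORS,
                     parse_color, piecewise_interpolate, to_hex)
from .io_formats import Annotation, ChromosomeSpec
from .windowing import WindowingPlan

__all__ = [
    "CanvasBox",
    "TrackStyle",
    "TrackSet",
    "Mark",
    "LabelMark",
    "layout_tracks",
    "data_track_box",
    "genomic_to_canvas",
    "place_data_track",
    "heatmap_color",
    "place_labels",
]

#: vertical gap between a data track and its chromosome band, px
_TRACK_GAP = 4.0
#: per-character width estimate for label staggering, px
_CHAR_WIDTH = 7.0
#: label line height, px
_LABEL_HEIGHT = 12.0


@dataclass(frozen=True)
class CanvasBox:
    """An axis-aligned rectangle in canvas units (px; y grows downward)."""

    x: float
    y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width < 0 or self.height < 0:
            raise ValueError("box width and height must be >= 0")


@dataclass(frozen=True)
class TrackStyle:
    """Per-set display options.

    ``plot_type`` selects how feature data is drawn: plain ``annotation``
    (presence/absence window fill), ``heatmap`` (window fill by aggregate
    through the color scale), ``scatter`` or ``bar`` (marks in the data
    track above the chromosome).  ``color_anchors`` drive the heatmap
    scale (>= 2 required) and default window/mark colors otherwise.
    ``y_reference`` draws a dashed horizontal baseline at that data value
    in scatter/bar tracks.
    """

    plot_type: str = "annotation"
    color_anchors: Tuple[str, ...] = DEFAULT_HEATMAP_ANCHORS
    y_reference: "float | None" = None
    label_mode: bool = False
    track_height: float = 60.0
    chrom_height: float = 20.0

    def __post_init__(self) -> None:
        if self.plot_type not in ("annotation", "heatmap", "scatter", "bar"):
            raise ValueError(f"unknown plot type {self.plot_type!r}")
        if not self.color_anchors:
            raise ValueError("need at least one color anchor")
        if self.plot_type == "heatmap" and len(self.color_anchors) < 2:
            raise ValueError("heatmap needs at least 2 color anchors")


@dataclass
class TrackSet:
    """One ordered group of chromosomes rendered as an independent track."""

    set_id: str
    chromosomes: List[ChromosomeSpec]
    plan: WindowingPlan
    display: TrackStyle = field(default_factory=TrackStyle)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError(
                f"track set {self.set_id!r}: chromosome names must be unique")


@dataclass(frozen=True)
class Mark:
    """One drawable data mark (scatter dot, bar, or reference line)."""

    kind: str  # "scatter" | "bar" | "refline"
    x: float
    y: float
    width: float = 0.0
    height: float = 0.0
    color: str = "#444444"
    element_id: "str | None" = None
    category: "str | None" = None
    value: "float | None" = None


@dataclass(frozen=True)
class LabelMark:
    """One positioned text label (left-anchored at its feature's x)."""

    text: str
    x: float
    y: float
    row: int
    element_id: "str | None" = None


def layout_tracks(sets: Sequence[TrackSet], canvas_width: float = 1000.0,
                  spacing: float = 40.0, left_margin: float = 0.0,
                  top_margin: float = 0.0, row_gap: float = 28.0,
                  common_scale: bool = False,
                  ) -> Dict[Tuple[str, str], CanvasBox]:
    """Compute each chromosome's band box.

    Returns ``(set_id, chrom_name) -> CanvasBox``.  Within a set, box
    width is proportional to window count and the widest chromosome spans
    the full drawable width; sets stack vertically in input order with
    ``spacing`` px between them.  Each row additionally reserves
    ``display.track_height`` above the band (see :func:`data_track_box`)
    and ``row_gap`` below it for labels.  Per-set independence: one set's
    contents never influence another set's boxes — unless
    ``common_scale`` forces a single global px-per-window so chromosome
    lengths are comparable across sets too.
    """
    drawable = canvas_width - left_margin
    boxes: Dict[Tuple[str, str], CanvasBox] = {}
    global_max = max(
        (s.plan.per_chromosome_counts[c.name]
         for s in sets for c in s.chromosomes), default=0)
    y = top_margin
    for s in sets:
        counts = [s.plan.per_chromosome_counts[c.name] for c in s.chromosomes]
        max_count = global_max if common_scale else (max(counts) if counts else 0)
        if max_count and drawable / max_count < 1.0:
            raise ValueError(
                f"canvas too narrow: {drawable:g} px for {max_count} windows "
                f"in set {s.set_id!r} (need >= 1 px per window)")
        px_per_window = drawable / max_count if max_count else 0.0
        style = s.display
        for c, n in zip(s.chromosomes, counts):
            band_y = y + style.track_height + _TRACK_GAP
            boxes[(s.set_id, c.name)] = CanvasBox(
                left_margin, band_y, n * px_per_window, style.chrom_height)
            y = band_y + style.chrom_height + row_gap
        y += spacing
    return boxes


def data_track_box(band: CanvasBox, style: TrackStyle) -> CanvasBox:
    """The data-track area reserved directly above a chromosome band."""
    return CanvasBox(band.x, band.y - _TRACK_GAP - style.track_height,
                     band.width, style.track_height)


def genomic_to_canvas(pos: int, box: CanvasBox, chrom: ChromosomeSpec) -> float:
    """Affine genomic→canvas map: start → box.x, end → box.x + width."""
    if not chrom.start <= pos <= chrom.end:
        raise ValueError(
            f"position {pos} outside chromosome {chrom.name} "
            f"[{chrom.start}, {chrom.end}]")
    if chrom.end == chrom.start:
        return box.x
    frac = (pos - chrom.start) / (chrom.end - chrom.start)
    return box.x + frac * box.width


def _value_range(values: Sequence[float],
                 y_range: "Tuple[float, float] | None",
                 y_reference: "float | None") -> Tuple[float, float]:
    if y_range is not None:
        return y_range
    lo, hi = min(values), max(values)
    if y_reference is not None:
        lo, hi = min(lo, y_reference), max(hi, y_reference)
    return lo, hi


def _y_offset(v: float, lo: float, hi: float, height: float) -> float:
    """Offset from track top: larger values sit higher."""
    if hi == lo:
        return height / 2.0
    return (hi - v) / (hi - lo) * height


def place_data_track(aggregated: Sequence[AggregatedWindow],
                     style: TrackStyle, box: CanvasBox,
                     chrom: ChromosomeSpec,
                     annotations: "Dict[str, Annotation] | None" = None,
                     anchor: str = "start",
                     y_range: "Tuple[float, float] | None" = None,
                     category_colors: "Dict[str, str] | None" = None,
                     ) -> Tuple[List[Mark], List[Tuple[str, str]]]:
    """Place scatter dots or bars in the data track above one chromosome.

    *Scatter* draws one dot per valued feature at its anchor's canvas x.
    Numeric values are linearly rescaled to the track height (larger
    values higher); categorically-valued features sit at mid-height,
    color-coded per category with one legend entry each (colors from
    ``category_colors`` or the default palette in first-appearance
    order).  *Bar* draws one bar per window with height proportional to
    the aggregate, rising from the zero baseline.  An optional dashed
    reference line is drawn at ``style.y_reference``.

    Returns ``(marks, legend)``; legend pairs are ``(category, color)``.
    """
    if style.plot_type not in ("scatter", "bar"):
        raise ValueError(
            f"data track needs plot type scatter or bar, got {style.plot_type!r}")
    marks: List[Mark] = []
    legend: List[Tuple[str, str]] = []
    base_color = to_hex(parse_color(style.color_anchors[-1]))

    if style.plot_type == "scatter":
        if annotations is None:
            raise ValueError("scatter track needs the annotation index")
        feats = []
        seen: set = set()  # segment features repeat per window; dedupe
        for aw in aggregated:
            for eid, value in aw.member_values:
                a = annotations[eid]
                if value is not None and a.chrom == chrom.name \
                        and eid not in seen:
                    seen.add(eid)
                    feats.append(a)
        if not feats:
            raise ValueError(
                f"no feature data to scatter on {chrom.name}")
        numeric = [a.numeric_value for a in feats
                   if a.numeric_value is not None]
        lo, hi = (_value_range(numeric, y_range, style.y_reference)
                  if numeric else (0.0, 0.0))
        cat_color: Dict[str, str] = {}
        for a in feats:
            pos = a.start if anchor == "start" else (a.start + a.end) // 2
            color, cat = base_color, a.category
            if cat is not None:
                if cat not in cat_color:
                    if category_colors and cat in category_colors:
                        cat_color[cat] = category_colors[cat]
                    else:
                        palette = DEFAULT_CATEGORY_PALETTE
                        cat_color[cat] = palette[len(cat_color) % len(palette)]
                    legend.append((cat, cat_color[cat]))
                color = cat_color[cat]
            if a.numeric_value is not None:
                y = box.y + _y_offset(a.numeric_value, lo, hi, box.height)
            else:
                y = box.y + box.height / 2.0
            marks.append(Mark(
                "scatter", x=genomic_to_canvas(pos, box, chrom), y=y,
                color=color, element_id=a.element_id, category=cat,
                value=a.numeric_value))
    else:  # bar
        valued = [aw for aw in aggregated if aw.agg_value is not None]
        if not valued:
            raise ValueError(f"no aggregated data to bar-plot on {chrom.name}")
        lo, hi = _value_range([aw.agg_value for aw in valued], y_range,
                              style.y_reference)
        lo = min(lo, 0.0)
        hi = max(hi, 0.0)
        n = len(aggregated)
        bar_w = box.width / n if n else 0.0
        y_zero = box.y + _y_offset(0.0, lo, hi, box.height)
        for aw in valued:
            v = aw.agg_value
            y_v = box.y + _y_offset(v, lo, hi, box.height)
            marks.append(Mark(
                "bar",
                x=box.x + aw.window.index * bar_w,
                y=min(y_v, y_zero),
                width=max(bar_w, 1.0),
                height=abs(y_zero - y_v),
                color=base_color, element_id=aw.key, value=v))

    if style.y_reference is not None:
        all_vals = [m.value for m in marks if m.value is not None]
        lo, hi = _value_range(all_vals, y_range, style.y_reference)
        if style.plot_type == "bar":
            lo, hi = min(lo, 0.0), max(hi, 0.0)
        marks.append(Mark(
            "refline", x=box.x,
            y=box.y + _y_offset(style.y_reference, lo, hi, box.height),
            width=box.width, color="#888888", value=style.y_reference))
    return marks, legend


def heatmap_color(agg_value: float, v_min: float, v_max: float,
                  anchors: Sequence[str] = DEFAULT_HEATMAP_ANCHORS) -> str:
    """Map a value through a piecewise-linear multi-anchor color scale.

    Anchor values reproduce anchor colors exactly; values outside
    ``[v_min, v_max]`` clamp to the end colors; a degenerate range
    (``v_min == v_max``) maps everything to the last anchor.
    """
    rgb_anchors = [parse_color(c) for c in anchors]
    if v_min > v_max:
        raise ValueError(f"v_min {v_min} > v_max {v_max}")
    if v_min == v_max:
        return to_hex(rgb_anchors[-1])
    t = (agg_value - v_min) / (v_max - v_min)
    return to_hex(piecewise_interpolate(rgb_anchors, t))


def place_labels(features: Sequence[Annotation], box: CanvasBox,
                 chrom: ChromosomeSpec,
                 char_width: float = _CHAR_WIDTH) -> List[LabelMark]:
    """Stagger feature labels into non-overlapping rows below a band.

    Labels anchor at their feature's canvas x and are swept left to
    right; a label drops to the next row whenever its estimated bounding
    box (``len(text) * char_width``) would intersect the previous label
    in the current row.  No two labels in one row ever intersect.
    """
    anchored = sorted(
        ((genomic_to_canvas(a.start, box, chrom), a) for a in features),
        key=lambda t: (t[0], t[1].element_id))
    row_ends: List[float] = []
    out: List[LabelMark] = []
    for x, a in anchored:
        w = len(a.element_id) * char_width
        for row, end in enumerate(row_ends):
            if x >= end:
                row_ends[row] = x + w
                break
        else:
            row = len(row_ends)
            row_ends.append(x + w)
        out.append(LabelMark(
            a.element_id, x,
            box.y + box.height + _LABEL_HEIGHT * (row + 1), row,
            element_id=a.element_id))
    return out
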