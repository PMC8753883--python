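"""End-to-end plot assembly: files in, rendered document out.

``run_pipeline`` executes the whole chain — read → validate →
plan/build windows → assign → aggregate → filter → layout → links →
render — from a :class:`PlotConfig`.  Each (chromosome file, annotation
file) pair becomes one independently windowed and scaled track set, so a
plot with several pairs shows homolog sets, species, or conditions as
stacked tracks.

Out-of-bound or unknown-chromosome annotations are removed with a
console warning and the plot proceeds from the rest (exit status 0);
structurally broken files and invalid configurations abort before any
output file is written.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import aggregation, io_formats, layout, links as links_mod, render, windowing
from .aggregation import AggregatedWindow, FilterSpec, build_tooltip_payload, window_key
from .colors import DEFAULT_CATEGORY_PALETTE, DEFAULT_HEATMAP_ANCHORS
from .io_formats import Annotation, ChromosomeSpec, ValidationReport
from .layout import (CanvasBox, Mark, TrackSet, TrackStyle, data_track_box,
                     genomic_to_canvas, heatmap_color, place_data_track,
                     place_labels)
from .links import TrackGeometry, link_colors, link_geometry, resolve_link
from .render import RenderedDocument, Scene, TextMark, WindowRect, render_html, render_png, render_svg

__all__ = ["PlotConfig", "ConfigError", "run_pipeline", "parse_filter", "build_scene"]

PLOT_TYPES = ("annotation", "heatmap", "scatter", "bar")

#: canvas margins, px
_LEFT_MARGIN = 70.0
_RIGHT_MARGIN = 170.0
_TOP_MARGIN = 30.0
_BOTTOM_MARGIN = 20.0

_EMPTY_FILL = "#ededed"


class ConfigError(ValueError):
    """The plot configuration is invalid; nothing has been written."""


@dataclass
class PlotConfig:
    """Everything needed to construct one plot.

    ``chromosome_files`` and ``annotation_files`` are parallel lists, one
    pair per track set (``"-"`` in annotation_files means a bare
    ideogram set).  ``plot_type`` may be a single type applied to every
    set or one per set.
    """

    chromosome_files: List[str] = field(default_factory=list)
    annotation_files: List[str] = field(default_factory=list)
    links_file: Optional[str] = None
    mode: str = "point"  # point | segment
    point_anchor: str = "start"  # start | midpoint
    plot_type: List[str] = field(default_factory=lambda: ["annotation"])
    aggregate_op: str = "count"
    filters: List[FilterSpec] = field(default_factory=list)
    n_windows: Optional[int] = None
    window_size: Optional[int] = None
    canvas_width: float = 1160.0
    track_height: float = 60.0
    chrom_height: float = 20.0
    y_reference: Optional[float] = None
    y_range: Optional[Tuple[float, float]] = None
    labels: bool = False
    colors: Tuple[str, ...] = DEFAULT_HEATMAP_ANCHORS
    common_scale: bool = False
    link_style: str = "edge"
    link_palette: Tuple[str, ...] = DEFAULT_CATEGORY_PALETTE
    link_distinct: bool = False
    zero_based: bool = False
    header: bool = False
    title: Optional[str] = None
    out: Optional[str] = None
    format: Optional[str] = None
    png_dpi: int = 96
    dump_windows: Optional[str] = None
    seed: int = 0
    quiet: bool = False


def parse_filter(text: str) -> FilterSpec:
    """Parse the CLI filter grammar.

    ``SCOPE:FIELD OP THRESHOLD[,THRESHOLD] COLOR[:LABEL]`` — e.g.
    ``"window:count ge 5 yellow:dense"`` or
    ``"feature:value abs_ge 2 orange"``.
    """
    parts = text.split()
    if len(parts) != 4:
        raise ConfigError(
            f"filter {text!r} must have 4 space-separated parts: "
            f"SCOPE:FIELD OP THRESHOLDS COLOR[:LABEL]")
    scope_field, op, thresholds_s, color_label = parts
    if ":" not in scope_field:
        raise ConfigError(f"filter scope/field {scope_field!r} needs SCOPE:FIELD")
    scope, fieldname = scope_field.split(":", 1)
    try:
        thresholds = tuple(float(t) for t in thresholds_s.split(","))
    except ValueError:
        raise ConfigError(
            f"filter thresholds {thresholds_s!r} must be numbers") from None
    if ":" in color_label:
        color, label = color_label.split(":", 1)
    else:
        color, label = color_label, None
    try:
        return FilterSpec(scope, fieldname, op, thresholds, color, label)
    except ValueError as exc:
        raise ConfigError(str(exc)) from None


def _validate_config(cfg: PlotConfig) -> None:
    """Pre-flight checks that need no file contents."""
    if not cfg.chromosome_files:
        raise ConfigError("at least one chromosome file is required")
    if len(cfg.annotation_files) != len(cfg.chromosome_files):
        raise ConfigError(
            f"{len(cfg.chromosome_files)} chromosome file(s) but "
            f"{len(cfg.annotation_files)} annotation file(s); the lists "
            f"must be parallel (use '-' for a bare set)")
    if cfg.mode not in ("point", "segment"):
        raise ConfigError(f"unknown annotation mode {cfg.mode!r}")
    if cfg.point_anchor not in ("start", "midpoint"):
        raise ConfigError(f"unknown point anchor {cfg.point_anchor!r}")
    n_sets = len(cfg.chromosome_files)
    if len(cfg.plot_type) not in (1, n_sets):
        raise ConfigError(
            f"plot_type needs 1 or {n_sets} entries, got {len(cfg.plot_type)}")
    for pt in cfg.plot_type:
        if pt not in PLOT_TYPES:
            raise ConfigError(f"unknown plot type {pt!r}; use one of {PLOT_TYPES}")
    if cfg.aggregate_op not in aggregation.AGG_OPS:
        raise ConfigError(
            f"unknown aggregate op {cfg.aggregate_op!r}; use one of "
            f"{aggregation.AGG_OPS}")
    if cfg.n_windows is not None and cfg.window_size is not None:
        raise ConfigError("--n-windows and --window-size are mutually exclusive")
    if cfg.window_size is not None and cfg.window_size < 1:
        raise ConfigError(f"window size must be >= 1, got {cfg.window_size}")
    if cfg.n_windows is not None and cfg.n_windows < 1:
        raise ConfigError(f"n_windows must be >= 1, got {cfg.n_windows}")
    if cfg.link_style not in ("edge", "ribbon"):
        raise ConfigError(f"unknown link style {cfg.link_style!r}")
    if cfg.format is not None and cfg.format not in ("html", "svg", "png"):
        raise ConfigError(f"unknown output format {cfg.format!r}")
    if any(pt == "heatmap" for pt in cfg.plot_type) and len(cfg.colors) < 2:
        raise ConfigError("heatmap plots need at least 2 colors")


@dataclass
class _SetState:
    """Internal per-track-set working state."""

    set_id: str
    chromosomes: List[ChromosomeSpec]
    style: TrackStyle
    kept: List[Annotation]
    windows_by_chrom: Dict[str, List[windowing.Window]]
    aggregated_by_chrom: Dict[str, List[AggregatedWindow]]
    plan: windowing.WindowingPlan


def _plot_type_for(cfg: PlotConfig, i: int) -> str:
    return cfg.plot_type[i] if len(cfg.plot_type) > 1 else cfg.plot_type[0]


def _prepare_sets(cfg: PlotConfig) -> Tuple[List[_SetState], ValidationReport]:
    report = ValidationReport()
    all_chroms: List[ChromosomeSpec] = []
    parsed = []
    for i, (cfile, afile) in enumerate(
            zip(cfg.chromosome_files, cfg.annotation_files)):
        chroms = io_formats.read_chromosome_file(
            cfile, header=cfg.header, zero_based=cfg.zero_based)
        if not chroms:
            raise ConfigError(f"chromosome file {cfile} is empty")
        annots = []
        if afile and afile != "-":
            annots = io_formats.read_annotation_file(
                afile, header=cfg.header, zero_based=cfg.zero_based)
        parsed.append((chroms, annots))
        all_chroms.extend(chroms)

    sets: List[_SetState] = []
    for i, (chroms, annots) in enumerate(parsed):
        plot_type = _plot_type_for(cfg, i)
        set_report = io_formats.validate_annotations(annots, chroms)
        report.kept.extend(set_report.kept)
        report.dropped.extend(set_report.dropped)
        report.messages.extend(set_report.messages)
        if plot_type in ("heatmap", "scatter", "bar") and not any(
                a.value is not None for a in set_report.kept):
            raise ConfigError(
                f"plot type {plot_type!r} requires a data value column, but "
                f"set {i + 1} ({cfg.annotation_files[i]}) has no valued "
                f"annotations")
        plan_source = all_chroms if cfg.common_scale else chroms
        plan = windowing.plan_windows(
            plan_source,
            target_windows=cfg.n_windows or windowing.DEFAULT_TARGET_WINDOWS,
            explicit_window_size=cfg.window_size)
        plan = windowing.WindowingPlan(
            plan.window_size,
            {c.name: math.ceil(c.length / plan.window_size) for c in chroms})
        windows_by_chrom = {
            c.name: windowing.build_windows(c, plan) for c in chroms}
        windowing.assign_annotations(
            set_report.kept, windows_by_chrom, mode=cfg.mode,
            anchor=cfg.point_anchor)
        index = {a.element_id: a for a in set_report.kept}
        aggregated = {
            name: aggregation.aggregate_windows(ws, index, cfg.aggregate_op)
            for name, ws in windows_by_chrom.items()}
        style = TrackStyle(
            plot_type=plot_type, color_anchors=tuple(cfg.colors),
            y_reference=cfg.y_reference, label_mode=cfg.labels,
            track_height=cfg.track_height if plot_type in ("scatter", "bar")
            else 12.0,
            chrom_height=cfg.chrom_height)
        sets.append(_SetState(
            set_id=f"set{i + 1}", chromosomes=chroms, style=style,
            kept=set_report.kept, windows_by_chrom=windows_by_chrom,
            aggregated_by_chrom=aggregated, plan=plan))
    return sets, report


def _window_fill(cfg: PlotConfig, state: _SetState, aw: AggregatedWindow,
                 v_range: Tuple[float, float],
                 category_color: Dict[str, str]) -> str:
    if not aw.member_values:
        return _EMPTY_FILL
    if state.style.plot_type == "heatmap" and aw.agg_value is not None:
        return heatmap_color(aw.agg_value, v_range[0], v_range[1],
                             state.style.color_anchors)
    if aw.group_counts:
        # group-annotation: color by the window's dominant category
        top = max(sorted(aw.group_counts), key=lambda c: aw.group_counts[c])
        return category_color[top]
    return state.style.color_anchors[-1]


def build_scene(cfg: PlotConfig,
                ) -> Tuple[Scene, ValidationReport]:
    """Assemble the drawable scene (pure given the input files)."""
    _validate_config(cfg)
    sets, report = _prepare_sets(cfg)

    track_sets = [TrackSet(s.set_id, s.chromosomes, s.plan, s.style)
                  for s in sets]
    drawable_width = cfg.canvas_width - _LEFT_MARGIN - _RIGHT_MARGIN
    boxes = layout.layout_tracks(
        track_sets, canvas_width=_LEFT_MARGIN + drawable_width,
        spacing=36.0, left_margin=_LEFT_MARGIN, top_margin=_TOP_MARGIN,
        common_scale=cfg.common_scale)

    total_height = max((b.y + b.height for b in boxes.values()),
                       default=_TOP_MARGIN) + 30.0 + _BOTTOM_MARGIN
    scene = Scene(width=cfg.canvas_width, height=total_height,
                  title=cfg.title)

    # stable category colors across the whole plot, first-appearance order
    category_color: Dict[str, str] = {}
    for s in sets:
        for a in s.kept:
            cat = a.category
            if cat is not None and cat not in category_color:
                palette = DEFAULT_CATEGORY_PALETTE
                category_color[cat] = palette[len(category_color) % len(palette)]

    window_filters = [f for f in cfg.filters if f.scope == "window"]
    feature_filters = [f for f in cfg.filters if f.scope == "feature"]
    feature_marked: Dict[str, str] = {}  # element_id -> highlight color
    for spec in feature_filters:
        for s in sets:
            for eid in aggregation.apply_filter(spec, s.kept):
                feature_marked[eid] = spec.highlight

    legend_seen: set = set()
    geometry = TrackGeometry(boxes={}, chromosomes={}, elements={})

    for s in sets:
        annot_index = {a.element_id: a for a in s.kept}
        for chrom in s.chromosomes:
            band = boxes[(s.set_id, chrom.name)]
            geometry.boxes[(s.set_id, chrom.name)] = band
            geometry.chromosomes[(s.set_id, chrom.name)] = chrom
            for a in s.kept:
                if a.chrom == chrom.name:
                    geometry.elements.setdefault(a.element_id, (s.set_id, a))
            aggregated = s.aggregated_by_chrom[chrom.name]

            # window-scope filters for this chromosome
            marked: Dict[str, Tuple[str, List[str]]] = {}
            for spec in window_filters:
                for key in aggregation.apply_filter(spec, aggregated):
                    color, tags = marked.get(key, (spec.highlight, []))
                    tags = tags + [spec.tag_label or
                                   f"{spec.field} {spec.op} "
                                   + ",".join(f"{t:g}" for t in spec.thresholds)]
                    marked[key] = (spec.highlight, tags)

            agg_vals = [aw.agg_value for aw in aggregated
                        if aw.agg_value is not None]
            v_range = ((min(agg_vals), max(agg_vals)) if agg_vals
                       else (0.0, 0.0))
            n = len(aggregated)
            win_w = band.width / n if n else 0.0
            for aw in aggregated:
                fill = _window_fill(cfg, s, aw, v_range, category_color)
                tags: List[str] = []
                if aw.key in marked:
                    fill, tags = marked[aw.key]
                scene.window_rects.append(WindowRect(
                    s.set_id, chrom.name, aw.window.index,
                    x=band.x + aw.window.index * win_w, y=band.y,
                    width=win_w, height=band.height, fill=fill))
                payload = build_tooltip_payload(aw, annot_index,
                                                active_tags=tags or None)
                scene.tooltips[f"{s.set_id}/{aw.key}"] = payload

            # chromosome name
            scene.texts.append(TextMark(
                chrom.name, x=band.x - 8.0, y=band.y + band.height / 2 + 4,
                size=11.0, anchor="end"))
            # centromere notch
            if chrom.centromere is not None:
                scene.marks.append(Mark(
                    "notch", x=genomic_to_canvas(chrom.centromere, band, chrom),
                    y=band.y + band.height / 2, height=band.height / 3,
                    color="#555555"))

            chrom_feats = [a for a in s.kept if a.chrom == chrom.name]

            if s.style.plot_type in ("scatter", "bar"):
                tbox = data_track_box(band, s.style)
                marks, legend = place_data_track(
                    aggregated, s.style, tbox, chrom,
                    annotations=annot_index, anchor=cfg.point_anchor,
                    y_range=cfg.y_range, category_colors=category_color)
                for m in marks:
                    if m.element_id in feature_marked and m.kind == "scatter":
                        m = replace(m, color=feature_marked[m.element_id])
                    scene.marks.append(m)
                for entry in legend:
                    if entry not in legend_seen:
                        legend_seen.add(entry)
                        scene.legends.append(entry)

            if s.style.plot_type == "annotation" and category_color:
                for cat in sorted(
                        {a.category for a in chrom_feats
                         if a.category is not None},
                        key=lambda c: list(category_color).index(c)):
                    entry = (cat, category_color[cat])
                    if entry not in legend_seen:
                        legend_seen.add(entry)
                        scene.legends.append(entry)

            if s.style.label_mode:
                scene.labels.extend(place_labels(chrom_feats, band, chrom))

            # hyperlink anchors: scatter marks carry their own; everything
            # else gets a tick glyph on the band so each hyperlinked
            # feature has exactly one clickable mark
            scatter_marked = {m.element_id for m in scene.marks
                             if m.kind == "scatter"}
            for a in chrom_feats:
                if a.hyperlink:
                    scene.hyperlinks[a.element_id] = a.hyperlink
                    if a.element_id not in scatter_marked:
                        x = genomic_to_canvas(a.start, band, chrom)
                        scene.marks.append(Mark(
                            "tick", x=x - 1.0, y=band.y, width=2.0,
                            height=band.height, color="#222222",
                            element_id=a.element_id))

    # links resolve (and fail) before anything is rendered
    if cfg.links_file:
        link_list = io_formats.read_link_file(cfg.links_file, header=cfg.header)
        resolved = [resolve_link(l, geometry) for l in link_list]
        colors, legend = link_colors(link_list, cfg.link_palette,
                                     distinct=cfg.link_distinct)
        for i, (l, (src, tgt, widths)) in enumerate(zip(link_list, resolved)):
            path = link_geometry(l, (src, tgt), style=cfg.link_style,
                                 end_widths=widths)
            scene.link_paths.append((path, colors[i]))
        for entry in legend:
            if entry not in legend_seen:
                legend_seen.add(entry)
                scene.legends.append(entry)

    # filter legend entries
    for spec in cfg.filters:
        label = spec.tag_label or (
            f"{spec.scope} {spec.field} {spec.op} "
            + ",".join(f"{t:g}" for t in spec.thresholds))
        entry = (label, spec.highlight)
        if entry not in legend_seen:
            legend_seen.add(entry)
            scene.legends.append(entry)

    return scene, report


def run_pipeline(cfg: PlotConfig) -> Tuple[RenderedDocument, ValidationReport]:
    """Execute the full pipeline and (optionally) write the output file.

    Dropped annotations are a warning, not a failure; structural errors
    in files or configuration raise before any output is written.
    """
    scene, report = build_scene(cfg)

    fmt = cfg.format
    if fmt is None and cfg.out:
        suffix = Path(cfg.out).suffix.lower().lstrip(".")
        fmt = suffix if suffix in ("html", "svg", "png") else "html"
    if fmt is None:
        fmt = "html"

    if fmt == "svg":
        doc = render_svg(scene)
    elif fmt == "png":
        doc = render_png(render_svg(scene), dpi=cfg.png_dpi)
    else:
        doc = render_html(scene)

    if cfg.out:
        Path(cfg.out).write_bytes(doc.payload)
    if cfg.dump_windows:
        _dump_windows_bed(cfg, Path(cfg.dump_windows))
    if not cfg.quiet:
        render.emit_console_diagnostics(report)
    return doc, report


def _dump_windows_bed(cfg: PlotConfig, path: Path) -> None:
    """Write every computed window as BED (0-based, half-open)."""
    sets, _ = _prepare_sets(cfg)
    lines = []
    for s in sets:
        for chrom in s.chromosomes:
            for w in s.windows_by_chrom[chrom.name]:
                lines.append(f"{w.chrom}\t{w.span_start - 1}\t{w.span_end}"
                             f"\t{s.set_id}/{w.chrom}:{w.index}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
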