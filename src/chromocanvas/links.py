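"""Inter-locus links: anchor resolution, edge/ribbon geometry, colors.

A link connects two annotated features (by element id) or two explicit
``chrom:pos`` loci, within or across track sets — homolog pairs,
co-expressed genes, orthologs.  Links draw either as thin cubic *edges*
(optionally directed, with an arrowhead at the target) or as thick
chord-like *ribbons* whose end widths follow the connected features'
drawn widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .colors import DEFAULT_CATEGORY_PALETTE, distinct_colors
from .io_formats import Annotation, ChromosomeSpec, Link
from .layout import CanvasBox, genomic_to_canvas, heatmap_color

__all__ = [
    "TrackGeometry",
    "LinkPath",
    "LinkResolutionError",
    "resolve_link_anchor",
    "resolve_link",
    "link_geometry",
    "link_colors",
]

#: minimum ribbon end width, px
_MIN_RIBBON_WIDTH = 2.0


class LinkResolutionError(ValueError):
    """A link endpoint names no drawn element or in-bound locus."""


@dataclass
class TrackGeometry:
    """The laid-out geometry links resolve against.

    ``boxes`` and ``chromosomes`` are keyed by ``(set_id, chrom_name)``;
    ``elements`` maps each drawn element id to the set it is drawn in and
    its annotation record.
    """

    boxes: Dict[Tuple[str, str], CanvasBox]
    chromosomes: Dict[Tuple[str, str], ChromosomeSpec]
    elements: Dict[str, Tuple[str, Annotation]] = field(default_factory=dict)

    def locate(self, endpoint) -> Tuple[Tuple[str, str], int, float]:
        """Resolve an endpoint to (box key, genomic pos, feature width bp)."""
        if isinstance(endpoint, tuple):
            chrom, pos = endpoint
            for key in self.boxes:
                if key[1] == chrom:
                    spec = self.chromosomes[key]
                    if spec.start <= pos <= spec.end:
                        return key, pos, 1
            raise LinkResolutionError(
                f"link endpoint {chrom}:{pos} matches no drawn chromosome "
                f"or is out of bounds")
        entry = self.elements.get(endpoint)
        if entry is None:
            raise LinkResolutionError(
                f"link endpoint {endpoint!r} names no drawn element")
        set_id, a = entry
        return (set_id, a.chrom), a.start, a.end - a.start + 1


def resolve_link_anchor(endpoint, geometry: TrackGeometry,
                        partner_y: "float | None" = None,
                        ) -> Tuple[float, float]:
    """Resolve one endpoint to a canvas point on its chromosome's edge.

    Element endpoints anchor at the element's start base (the
    point-annotation convention); loci map through the affine coordinate
    map.  The anchor sits on the chromosome edge facing the partner:
    bottom edge when the partner lies below, top edge when above (bottom
    by default when the partner's y is unknown).
    """
    key, pos, _ = geometry.locate(endpoint)
    box = geometry.boxes[key]
    x = genomic_to_canvas(pos, box, geometry.chromosomes[key])
    mid = box.y + box.height / 2.0
    if partner_y is not None and partner_y < mid:
        y = box.y
    else:
        y = box.y + box.height
    return x, y


def resolve_link(l: Link, geometry: TrackGeometry,
                 ) -> Tuple[Tuple[float, float], Tuple[float, float],
                            Tuple[float, float]]:
    """Resolve both endpoints with edges facing each other.

    Returns ``(source_anchor, target_anchor, (source_width, target_width))``
    where widths are the connected features' drawn widths in px (1 px
    minimum, loci count as single-base features).  Fails before any
    rendering if either endpoint is unresolvable.
    """
    s_key, s_pos, s_bp = geometry.locate(l.source)
    t_key, t_pos, t_bp = geometry.locate(l.target)
    s_mid = geometry.boxes[s_key].y + geometry.boxes[s_key].height / 2.0
    t_mid = geometry.boxes[t_key].y + geometry.boxes[t_key].height / 2.0
    src = resolve_link_anchor(l.source, geometry, partner_y=t_mid)
    tgt = resolve_link_anchor(l.target, geometry, partner_y=s_mid)

    def px_width(key, bp):
        box = geometry.boxes[key]
        spec = geometry.chromosomes[key]
        return max(bp / spec.length * box.width, 1.0)

    return src, tgt, (px_width(s_key, s_bp), px_width(t_key, t_bp))


@dataclass(frozen=True)
class LinkPath:
    """A drawable link: an SVG path plus arrowhead/style metadata."""

    d: str
    style: str  # "edge" | "ribbon"
    arrowhead_at: "Tuple[float, float] | None" = None
    source: Tuple[float, float] = (0.0, 0.0)
    target: Tuple[float, float] = (0.0, 0.0)


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def link_geometry(l: Link, anchors: Tuple[Tuple[float, float],
                                          Tuple[float, float]],
                  style: str = "edge",
                  end_widths: Tuple[float, float] = (2.0, 2.0)) -> LinkPath:
    """Compute the drawable path between two resolved anchors.

    *Edge* style emits a cubic curve whose control points are offset
    vertically by half the inter-anchor gap; a directed link gets exactly
    one arrowhead, at the target.  *Ribbon* style emits a closed
    chord-like band whose end widths equal the source/target feature
    widths (2 px minimum).  Path endpoints coincide with the anchors.
    """
    (x1, y1), (x2, y2) = anchors
    dy = (y2 - y1) / 2.0
    if style == "edge":
        d = (f"M {_fmt(x1)} {_fmt(y1)} "
             f"C {_fmt(x1)} {_fmt(y1 + dy)}, {_fmt(x2)} {_fmt(y2 - dy)}, "
             f"{_fmt(x2)} {_fmt(y2)}")
        return LinkPath(d, "edge",
                        arrowhead_at=(x2, y2) if l.directed else None,
                        source=(x1, y1), target=(x2, y2))
    if style != "ribbon":
        raise ValueError(f"unknown link style {style!r}")
    w1 = max(end_widths[0], _MIN_RIBBON_WIDTH)
    w2 = max(end_widths[1], _MIN_RIBBON_WIDTH)
    l1, r1 = x1 - w1 / 2.0, x1 + w1 / 2.0
    l2, r2 = x2 - w2 / 2.0, x2 + w2 / 2.0
    d = (f"M {_fmt(l1)} {_fmt(y1)} "
         f"C {_fmt(l1)} {_fmt(y1 + dy)}, {_fmt(l2)} {_fmt(y2 - dy)}, "
         f"{_fmt(l2)} {_fmt(y2)} "
         f"L {_fmt(r2)} {_fmt(y2)} "
         f"C {_fmt(r2)} {_fmt(y2 - dy)}, {_fmt(r1)} {_fmt(y1 + dy)}, "
         f"{_fmt(r1)} {_fmt(y1)} Z")
    return LinkPath(d, "ribbon", arrowhead_at=None,
                    source=(x1, y1), target=(x2, y2))


def _endpoint_label(e) -> str:
    if isinstance(e, tuple):
        return f"{e[0]}:{e[1]}"
    return e


def link_colors(links: Sequence[Link],
                palette: Sequence[str] = DEFAULT_CATEGORY_PALETTE,
                distinct: bool = False,
                ) -> Tuple[Dict[int, str], List[Tuple[str, str]]]:
    """Assign each link a color and build the legend.

    Returns ``(colors, legend)`` with colors keyed by link list index.
    Categorical values map category→color stably in first-appearance
    order, cycling the palette, with one legend entry per category.
    Numeric values map through the two ends of the palette as a linear
    color scale (one legend entry describing the scale).  Valueless links
    all take the first palette color — unless ``distinct=True``, which
    gives every link its own color and legend entry (ortholog-pair
    style).
    """
    colors: Dict[int, str] = {}
    legend: List[Tuple[str, str]] = []
    if distinct:
        cs = distinct_colors(len(links), palette)
        for i, l in enumerate(links):
            colors[i] = cs[i]
            legend.append((
                f"{_endpoint_label(l.source)}–{_endpoint_label(l.target)}",
                cs[i]))
        return colors, legend

    numeric = [(i, l.value) for i, l in enumerate(links)
               if isinstance(l.value, float)]
    categories: Dict[str, str] = {}
    if numeric:
        vals = [v for _, v in numeric]
        v_min, v_max = min(vals), max(vals)
        scale = (palette[0], palette[-1]) if len(palette) >= 2 else palette
        for i, v in numeric:
            colors[i] = heatmap_color(v, v_min, v_max, scale)
        legend.append((f"value scale [{v_min:g}, {v_max:g}]", scale[-1]))
    for i, l in enumerate(links):
        if i in colors:
            continue
        if isinstance(l.value, str):
            if l.value not in categories:
                categories[l.value] = palette[len(categories) % len(palette)]
                legend.append((l.value, categories[l.value]))
            colors[i] = categories[l.value]
        else:
            colors[i] = palette[0]
    return colors, legend
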