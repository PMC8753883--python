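"""Document emission: standalone interactive HTML, static SVG, and PNG.

The renderer consumes a fully laid-out :class:`Scene` — window
rectangles, data marks, labels, link paths, legends — and serializes it.
SVG is the native format; HTML embeds the same SVG together with a small
inline script providing hover tooltips (per-window data records embedded
as a JSON block, no runtime fetching), click-through hyperlinks, and
wheel/drag zoom-pan of the vector canvas.  The HTML references no
external scripts, styles, or fonts, so the file works offline as a
publication supplement.

PNG export rasterizes the SVG payload with a purpose-built rasterizer
for the subset of SVG this package emits (rects, circles, lines, cubic
paths, text), scaled by the requested dpi against the 96 dpi base.

Rendering is deterministic: identical scenes serialize to byte-identical
payloads.
"""

from __future__ import annotations

import io
import json
import re
import sys
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .io_formats import ValidationReport
from .layout import LabelMark, Mark
from .links import LinkPath

__all__ = [
    "Scene",
    "WindowRect",
    "TextMark",
    "RenderedDocument",
    "render_svg",
    "render_html",
    "render_png",
    "emit_console_diagnostics",
]

SVG_NS = "http://www.w3.org/2000/svg"
XLINK_NS = "http://www.w3.org/1999/xlink"


@dataclass(frozen=True)
class WindowRect:
    """One drawn window rectangle with its stable identity."""

    set_id: str
    chrom: str
    index: int
    x: float
    y: float
    width: float
    height: float
    fill: str
    stroke: str = "#2f4f4f"

    @property
    def key(self) -> str:
        return f"{self.set_id}/{self.chrom}:{self.index}"


@dataclass(frozen=True)
class TextMark:
    text: str
    x: float
    y: float
    size: float = 12.0
    anchor: str = "start"
    color: str = "#222222"


@dataclass
class Scene:
    """Everything the renderer draws, in final canvas coordinates."""

    width: float
    height: float
    title: "str | None" = None
    window_rects: List[WindowRect] = field(default_factory=list)
    marks: List[Mark] = field(default_factory=list)
    labels: List[LabelMark] = field(default_factory=list)
    texts: List[TextMark] = field(default_factory=list)
    link_paths: List[Tuple[LinkPath, str]] = field(default_factory=list)
    legends: List[Tuple[str, str]] = field(default_factory=list)
    tooltips: Dict[str, dict] = field(default_factory=dict)
    #: element_id -> URL; exactly the features to wrap in anchors
    hyperlinks: Dict[str, str] = field(default_factory=dict)


@dataclass
class RenderedDocument:
    """An emitted artifact plus a manifest of drawn primitive counts."""

    format: str  # "html" | "svg" | "png"
    payload: bytes
    manifest: Dict[str, int]


def _fmt(v: float) -> str:
    s = f"{v:.2f}"
    return s.rstrip("0").rstrip(".") if "." in s else s


_DATA_MARK_KINDS = ("scatter", "bar", "tick")


def _build_svg_tree(scene: Scene) -> Tuple[ET.Element, Dict[str, int]]:
    ET.register_namespace("", SVG_NS)
    svg = ET.Element(
        f"{{{SVG_NS}}}svg",
        {"width": _fmt(scene.width), "height": _fmt(scene.height),
         "viewBox": f"0 0 {_fmt(scene.width)} {_fmt(scene.height)}"})
    needs_arrow = any(p.arrowhead_at for p, _ in scene.link_paths)
    if needs_arrow:
        defs = ET.SubElement(svg, f"{{{SVG_NS}}}defs")
        marker = ET.SubElement(defs, f"{{{SVG_NS}}}marker", {
            "id": "arrowhead", "markerWidth": "8", "markerHeight": "8",
            "refX": "6", "refY": "3", "orient": "auto",
            "markerUnits": "strokeWidth"})
        ET.SubElement(marker, f"{{{SVG_NS}}}path",
                      {"d": "M 0 0 L 6 3 L 0 6 Z", "fill": "#333333"})
    root = ET.SubElement(svg, f"{{{SVG_NS}}}g", {"id": "plot-root"})

    if scene.title:
        t = ET.SubElement(root, f"{{{SVG_NS}}}text", {
            "x": _fmt(scene.width / 2), "y": "18", "text-anchor": "middle",
            "font-size": "15", "font-family": "sans-serif",
            "class": "title"})
        t.text = scene.title

    n_windows = 0
    for r in scene.window_rects:
        ET.SubElement(root, f"{{{SVG_NS}}}rect", {
            "id": f"win-{r.set_id}-{r.chrom}-{r.index}",
            "class": "window", "data-key": r.key,
            "x": _fmt(r.x), "y": _fmt(r.y),
            "width": _fmt(max(r.width, 0.1)), "height": _fmt(r.height),
            "fill": r.fill, "stroke": r.stroke, "stroke-width": "0.5"})
        n_windows += 1

    n_marks = 0
    n_anchors = 0
    for m in scene.marks:
        url = scene.hyperlinks.get(m.element_id) if m.element_id else None
        parent = root
        if url and m.kind in _DATA_MARK_KINDS:
            parent = ET.SubElement(root, f"{{{SVG_NS}}}a", {
                "href": url, "target": "_blank", "class": "feature-link"})
            n_anchors += 1
        if m.kind == "scatter":
            attrs = {"class": "mark", "cx": _fmt(m.x), "cy": _fmt(m.y),
                     "r": "3", "fill": m.color}
            if m.element_id:
                attrs["data-element"] = m.element_id
            ET.SubElement(parent, f"{{{SVG_NS}}}circle", attrs)
            n_marks += 1
        elif m.kind == "bar":
            ET.SubElement(parent, f"{{{SVG_NS}}}rect", {
                "class": "mark", "x": _fmt(m.x), "y": _fmt(m.y),
                "width": _fmt(max(m.width, 0.5)),
                "height": _fmt(max(m.height, 0.5)), "fill": m.color})
            n_marks += 1
        elif m.kind == "tick":
            attrs = {"class": "mark", "x": _fmt(m.x), "y": _fmt(m.y),
                     "width": _fmt(max(m.width, 1.0)),
                     "height": _fmt(m.height), "fill": m.color}
            if m.element_id:
                attrs["data-element"] = m.element_id
            ET.SubElement(parent, f"{{{SVG_NS}}}rect", attrs)
            n_marks += 1
        elif m.kind == "refline":
            ET.SubElement(parent, f"{{{SVG_NS}}}line", {
                "class": "decor", "x1": _fmt(m.x), "y1": _fmt(m.y),
                "x2": _fmt(m.x + m.width), "y2": _fmt(m.y),
                "stroke": m.color, "stroke-dasharray": "4 3"})
        elif m.kind == "notch":
            ET.SubElement(parent, f"{{{SVG_NS}}}circle", {
                "class": "decor", "cx": _fmt(m.x), "cy": _fmt(m.y),
                "r": _fmt(max(m.height, 2.0)), "fill": m.color})
        else:
            raise ValueError(f"unknown mark kind {m.kind!r}")

    n_links = 0
    for path, color in scene.link_paths:
        attrs = {"class": "link", "d": path.d}
        if path.style == "edge":
            attrs.update({"fill": "none", "stroke": color,
                          "stroke-width": "1.5"})
        else:
            attrs.update({"fill": color, "fill-opacity": "0.55",
                          "stroke": color, "stroke-width": "0.5"})
        if path.arrowhead_at is not None:
            attrs["marker-end"] = "url(#arrowhead)"
        ET.SubElement(root, f"{{{SVG_NS}}}path", attrs)
        n_links += 1

    n_labels = 0
    for lab in scene.labels:
        t = ET.SubElement(root, f"{{{SVG_NS}}}text", {
            "class": "label", "x": _fmt(lab.x), "y": _fmt(lab.y),
            "font-size": "10", "font-family": "sans-serif"})
        t.text = lab.text
        n_labels += 1

    for tm in scene.texts:
        t = ET.SubElement(root, f"{{{SVG_NS}}}text", {
            "class": "text", "x": _fmt(tm.x), "y": _fmt(tm.y),
            "font-size": _fmt(tm.size), "font-family": "sans-serif",
            "text-anchor": tm.anchor, "fill": tm.color})
        t.text = tm.text

    n_legends = 0
    for i, (label, color) in enumerate(scene.legends):
        y = 16.0 + 16.0 * i
        x = scene.width - 150.0
        ET.SubElement(root, f"{{{SVG_NS}}}rect", {
            "class": "legend-swatch", "x": _fmt(x), "y": _fmt(y - 9),
            "width": "10", "height": "10", "fill": color})
        t = ET.SubElement(root, f"{{{SVG_NS}}}text", {
            "class": "legend-label", "x": _fmt(x + 14), "y": _fmt(y),
            "font-size": "10", "font-family": "sans-serif"})
        t.text = label
        n_legends += 1

    manifest = {"windows": n_windows, "marks": n_marks, "links": n_links,
                "labels": n_labels, "legends": n_legends,
                "anchors": n_anchors}
    return svg, manifest


def render_svg(scene: Scene) -> RenderedDocument:
    """Serialize a scene as a standalone SVG document.

    Every window rectangle carries a stable id (``win-<set>-<chrom>-<k>``)
    and class so primitive counts can be recovered from the markup; the
    manifest records them.  Byte-identical output for identical scenes.
    """
    svg, manifest = _build_svg_tree(scene)
    payload = (b'<?xml version="1.0" encoding="UTF-8"?>\n'
               + ET.tostring(svg, encoding="unicode").encode("utf-8"))
    return RenderedDocument("svg", payload, manifest)


# Interactivity: hover tooltips from the embedded JSON records, wheel
# zoom and drag pan on the vector canvas.  Authored once, inlined
# verbatim into every HTML document; no external references.
_HTML_SCRIPT = """
(function () {
  var data = JSON.parse(document.getElementById('tooltip-data').textContent);
  var tip = document.getElementById('tooltip');
  var svg = document.querySelector('svg');
  var root = document.getElementById('plot-root');
  var scale = 1, tx = 0, ty = 0;
  function apply() {
    root.setAttribute('transform',
      'translate(' + tx + ',' + ty + ') scale(' + scale + ')');
  }
  document.querySelectorAll('.window').forEach(function (el) {
    el.addEventListener('mousemove', function (ev) {
      var rec = data[el.getAttribute('data-key')];
      if (!rec) return;
      var html = '<b>' + rec.chrom + '</b> ' + rec.span +
        '<br>' + rec.n_elements + ' element(s)';
      if ('aggregate' in rec) html += '<br>aggregate: ' + rec.aggregate;
      rec.members.forEach(function (m) {
        html += '<br>' + (m.hyperlink
          ? '<a href="' + m.hyperlink + '" target="_blank">' + m.id + '</a>'
          : m.id);
        if ('value' in m) html += ': ' + m.value;
      });
      if (rec.group_counts) {
        Object.keys(rec.group_counts).sort().forEach(function (k) {
          html += '<br>' + k + ': ' + rec.group_counts[k];
        });
      }
      tip.innerHTML = html;
      tip.style.display = 'block';
      tip.style.left = (ev.pageX + 12) + 'px';
      tip.style.top = (ev.pageY + 12) + 'px';
    });
    el.addEventListener('mouseleave', function () {
      tip.style.display = 'none';
    });
  });
  svg.addEventListener('wheel', function (ev) {
    ev.preventDefault();
    var f = ev.deltaY < 0 ? 1.15 : 1 / 1.15;
    scale = Math.max(0.2, Math.min(40, scale * f));
    apply();
  });
  var drag = null;
  svg.addEventListener('mousedown', function (ev) {
    drag = [ev.clientX - tx, ev.clientY - ty];
  });
  window.addEventListener('mousemove', function (ev) {
    if (drag) { tx = ev.clientX - drag[0]; ty = ev.clientY - drag[1]; apply(); }
  });
  window.addEventListener('mouseup', function () { drag = null; });
})();
"""

_HTML_STYLE = """
body { font-family: sans-serif; margin: 12px; }
#tooltip { display: none; position: absolute; background: #fffef0;
  border: 1px solid #999; border-radius: 4px; padding: 6px 9px;
  font-size: 12px; max-width: 340px; pointer-events: auto;
  box-shadow: 1px 1px 4px rgba(0,0,0,0.3); z-index: 10; }
svg { cursor: grab; }
"""


def render_html(scene: Scene) -> RenderedDocument:
    """Serialize a scene as a self-contained interactive HTML document.

    The SVG is embedded inline; per-window tooltip records ride along in
    an ``application/json`` block keyed ``set/chrom:index`` — one record
    per drawn window; the interactivity script and style are inlined, so
    the file needs no network access at all.
    """
    svg_doc = render_svg(scene)
    svg_markup = svg_doc.payload.decode("utf-8").split("\n", 1)[1]
    tooltip_json = json.dumps(scene.tooltips, sort_keys=True,
                              ensure_ascii=True, separators=(",", ":"))
    title = scene.title or "chromocanvas plot"
    html = (
        "<!DOCTYPE html>\n<html lang=\"en\">\n<head>\n"
        "<meta charset=\"utf-8\">\n"
        f"<title>{title}</title>\n"
        f"<style>{_HTML_STYLE}</style>\n"
        "</head>\n<body>\n"
        f"{svg_markup}\n"
        "<div id=\"tooltip\"></div>\n"
        "<script type=\"application/json\" id=\"tooltip-data\">"
        f"{tooltip_json}</script>\n"
        f"<script>{_HTML_SCRIPT}</script>\n"
        "</body>\n</html>\n")
    manifest = dict(svg_doc.manifest)
    manifest["tooltips"] = len(scene.tooltips)
    return RenderedDocument("html", html.encode("utf-8"), manifest)


# ---------------------------------------------------------------------------
# PNG rasterization (subset rasterizer for this package's own SVG output)

def _cubic_points(p0, p1, p2, p3, n=24):
    pts = []
    for i in range(n + 1):
        t = i / n
        u = 1 - t
        x = (u ** 3 * p0[0] + 3 * u * u * t * p1[0]
             + 3 * u * t * t * p2[0] + t ** 3 * p3[0])
        y = (u ** 3 * p0[1] + 3 * u * u * t * p1[1]
             + 3 * u * t * t * p2[1] + t ** 3 * p3[1])
        pts.append((x, y))
    return pts


_PATH_TOKEN = re.compile(r"([MCLZz])|(-?\d+(?:\.\d+)?)")


def _flatten_path(d: str):
    """Flatten an M/C/L/Z path into (points, closed)."""
    tokens = _PATH_TOKEN.findall(d)
    pts: List[Tuple[float, float]] = []
    closed = False
    nums: List[float] = []
    cmd = None

    def flush():
        nonlocal nums
        if cmd == "M" or cmd == "L":
            for i in range(0, len(nums) - 1, 2):
                pts.append((nums[i], nums[i + 1]))
        elif cmd == "C":
            for i in range(0, len(nums) - 5, 6):
                p0 = pts[-1]
                pts.extend(_cubic_points(
                    p0, (nums[i], nums[i + 1]), (nums[i + 2], nums[i + 3]),
                    (nums[i + 4], nums[i + 5]))[1:])
        nums = []

    for letter, num in tokens:
        if letter:
            flush()
            if letter in "Zz":
                closed = True
                cmd = None
            else:
                cmd = letter
        else:
            nums.append(float(num))
    flush()
    return pts, closed


def _rgba(color: str, opacity: float = 1.0):
    from .colors import parse_color
    r, g, b = parse_color(color)
    return (r, g, b, round(255 * opacity))


def render_png(svg_doc: RenderedDocument, dpi: int = 96) -> RenderedDocument:
    """Rasterize an SVG document to PNG at the requested dpi.

    The canvas is scaled by ``dpi / 96``: a 1000x400 SVG becomes a
    1000x400 image at 96 dpi and 2000x800 at 192.  Raises on a payload
    that does not parse as SVG.
    """
    from PIL import Image, ImageDraw

    if svg_doc.format != "svg":
        raise ValueError(f"render_png needs an svg document, got {svg_doc.format!r}")
    try:
        tree = ET.fromstring(svg_doc.payload)
    except ET.ParseError as exc:
        raise ValueError(f"invalid SVG payload: {exc}") from exc
    if tree.tag != f"{{{SVG_NS}}}svg":
        raise ValueError("payload is XML but not an SVG document")
    width = float(tree.get("width", "0"))
    height = float(tree.get("height", "0"))
    s = dpi / 96.0
    img = Image.new("RGB", (round(width * s), round(height * s)),
                    (255, 255, 255))
    draw = ImageDraw.Draw(img, "RGBA")

    def walk(el):
        tag = el.tag.rsplit("}", 1)[-1]
        if tag == "defs":
            return
        if tag == "rect":
            x, y = float(el.get("x")) * s, float(el.get("y")) * s
            w, h = float(el.get("width")) * s, float(el.get("height")) * s
            fill = el.get("fill")
            stroke = el.get("stroke")
            draw.rectangle(
                [x, y, x + max(w, 1), y + max(h, 1)],
                fill=_rgba(fill) if fill and fill != "none" else None,
                outline=_rgba(stroke) if stroke and stroke != "none" else None)
        elif tag == "circle":
            cx, cy = float(el.get("cx")) * s, float(el.get("cy")) * s
            r = float(el.get("r")) * s
            fill = el.get("fill")
            draw.ellipse([cx - r, cy - r, cx + r, cy + r],
                         fill=_rgba(fill) if fill and fill != "none" else None)
        elif tag == "line":
            draw.line([float(el.get("x1")) * s, float(el.get("y1")) * s,
                       float(el.get("x2")) * s, float(el.get("y2")) * s],
                      fill=_rgba(el.get("stroke", "#000000")))
        elif tag == "path":
            pts, closed = _flatten_path(el.get("d", ""))
            if len(pts) >= 2:
                scaled = [(px * s, py * s) for px, py in pts]
                fill = el.get("fill")
                if closed and fill and fill != "none":
                    opacity = float(el.get("fill-opacity", "1"))
                    draw.polygon(scaled, fill=_rgba(fill, opacity))
                else:
                    stroke = el.get("stroke", "#000000")
                    if stroke != "none":
                        draw.line(scaled, fill=_rgba(stroke),
                                  width=max(round(1.5 * s), 1))
        elif tag == "text":
            x, y = float(el.get("x")) * s, float(el.get("y")) * s
            size = float(el.get("font-size", "10"))
            anchor = el.get("text-anchor", "start")
            text = el.text or ""
            est_w = len(text) * size * 0.6 * s
            if anchor == "middle":
                x -= est_w / 2
            elif anchor == "end":
                x -= est_w
            draw.text((x, y - size * s),
                      text, fill=_rgba(el.get("fill", "#222222")))
        for child in el:
            walk(child)

    for child in tree:
        walk(child)

    buf = io.BytesIO()
    img.save(buf, format="PNG")
    manifest = dict(svg_doc.manifest)
    manifest["width_px"] = img.width
    manifest["height_px"] = img.height
    return RenderedDocument("png", buf.getvalue(), manifest)


def emit_console_diagnostics(report: ValidationReport, stream=None) -> None:
    """Print one summary line per drop reason; silent on clean input."""
    if stream is None:
        stream = sys.stderr
    for msg in report.messages:
        print(msg, file=stream)
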