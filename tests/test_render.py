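"""Document emission: SVG/HTML well-formedness, counts, PNG, diagnostics."""

import io
import re

import pytest
from lxml import etree
from lxml import html as lhtml

from chromocanvas.io_formats import ValidationReport, Annotation
from chromocanvas.layout import LabelMark, Mark
from chromocanvas.links import LinkPath, link_geometry
from chromocanvas.io_formats import Link
from chromocanvas.render import (RenderedDocument, Scene, WindowRect,
                                 emit_console_diagnostics, render_html,
                                 render_png, render_svg)

SVGNS = {"s": "http://www.w3.org/2000/svg"}


def small_scene(n_windows=6, with_links=True, hyperlinks=None):
    scene = Scene(width=400.0, height=300.0, title="demo")
    for k in range(n_windows):
        scene.window_rects.append(WindowRect(
            "set1", "chr1", k, x=10.0 + 20 * k, y=100.0, width=20.0,
            height=18.0, fill="#ccddee"))
        scene.tooltips[f"set1/chr1:{k}"] = {
            "chrom": "chr1", "window": k, "span": f"{k * 10 + 1}–{k * 10 + 10}",
            "n_elements": 0, "members": []}
    scene.marks.append(Mark("scatter", x=30.0, y=50.0, color="#ff0000",
                            element_id="geneA", value=1.0))
    scene.marks.append(Mark("bar", x=50.0, y=60.0, width=18.0, height=30.0,
                            color="#00aa00"))
    scene.labels.append(LabelMark("geneA", 30.0, 140.0, 0))
    if with_links:
        directed = link_geometry(Link("a", "b", directed=True),
                                 ((30.0, 118.0), (200.0, 118.0)))
        plain = link_geometry(Link("c", "d"), ((60.0, 118.0), (240.0, 118.0)))
        scene.link_paths = [(directed, "#336699"), (plain, "#993366")]
    scene.legends = [("grpA", "#1f77b4"), ("grpB", "#ff7f0e")]
    if hyperlinks:
        scene.hyperlinks.update(hyperlinks)
    return scene


class TestSvg:
    def test_well_formed_and_manifest_matches_recount(self):
        doc = render_svg(small_scene())
        root = etree.fromstring(doc.payload)
        assert doc.manifest["windows"] == len(
            root.findall(".//s:rect[@class='window']", SVGNS)) == 6
        marks = (root.findall(".//s:circle[@class='mark']", SVGNS)
                 + root.findall(".//s:rect[@class='mark']", SVGNS))
        assert doc.manifest["marks"] == len(marks) == 2
        assert doc.manifest["links"] == len(
            root.findall(".//s:path[@class='link']", SVGNS)) == 2
        assert doc.manifest["labels"] == len(
            root.findall(".//s:text[@class='label']", SVGNS)) == 1
        assert doc.manifest["legends"] == len(
            root.findall(".//s:text[@class='legend-label']", SVGNS)) == 2

    def test_stable_window_ids(self):
        doc = render_svg(small_scene(n_windows=2))
        root = etree.fromstring(doc.payload)
        ids = [r.get("id") for r in
               root.findall(".//s:rect[@class='window']", SVGNS)]
        assert ids == ["win-set1-chr1-0", "win-set1-chr1-1"]

    def test_one_arrowhead_per_directed_link(self):
        doc = render_svg(small_scene())
        root = etree.fromstring(doc.payload)
        with_marker = [p for p in root.findall(".//s:path[@class='link']", SVGNS)
                       if p.get("marker-end")]
        assert len(with_marker) == 1

    def test_byte_identical_rerun(self):
        assert render_svg(small_scene()).payload == \
            render_svg(small_scene()).payload

    def test_empty_scene_still_valid(self):
        doc = render_svg(Scene(width=100.0, height=50.0))
        root = etree.fromstring(doc.payload)
        assert root.tag.endswith("svg")
        assert doc.manifest["windows"] == 0

    def test_hyperlinked_mark_wrapped_in_anchor(self):
        scene = small_scene(hyperlinks={"geneA": "https://x.org/geneA"})
        doc = render_svg(scene)
        root = etree.fromstring(doc.payload)
        anchors = root.findall(".//s:a", SVGNS)
        assert len(anchors) == doc.manifest["anchors"] == 1
        assert anchors[0].get("href") == "https://x.org/geneA"
        assert anchors[0].find("s:circle", SVGNS) is not None


class TestHtml:
    def test_one_tooltip_record_per_window(self):
        doc = render_html(small_scene(n_windows=6))
        tree = lhtml.document_fromstring(doc.payload)
        import json
        data = json.loads(
            tree.get_element_by_id("tooltip-data").text_content())
        assert len(data) == 6 == doc.manifest["tooltips"]
        assert set(data) == {f"set1/chr1:{k}" for k in range(6)}

    def test_self_contained_no_external_references(self):
        scene = small_scene(hyperlinks={"geneA": "https://x.org/geneA"})
        doc = render_html(scene)
        tree = lhtml.document_fromstring(doc.payload)
        assert tree.findall(".//script[@src]") == []
        assert tree.findall(".//link") == []
        # the only http URLs are user-supplied hyperlinks
        text = doc.payload.decode("utf-8")
        urls = set(re.findall(r"https?://[^\s\"'<)]+", text))
        assert urls == {"https://x.org/geneA", "http://www.w3.org/2000/svg"}

    def test_embeds_svg_and_interactivity(self):
        doc = render_html(small_scene())
        text = doc.payload.decode("utf-8")
        assert "<svg" in text and "tooltip-data" in text
        assert "addEventListener" in text

    def test_byte_identical_rerun(self):
        assert render_html(small_scene()).payload == \
            render_html(small_scene()).payload


class TestPng:
    def test_dimensions_at_base_and_doubled_dpi(self):
        svg = render_svg(Scene(width=1000.0, height=400.0))
        png = render_png(svg, dpi=96)
        assert (png.manifest["width_px"], png.manifest["height_px"]) == \
            (1000, 400)
        png2 = render_png(svg, dpi=192)
        assert (png2.manifest["width_px"], png2.manifest["height_px"]) == \
            (2000, 800)

    def test_payload_is_png(self):
        png = render_png(render_svg(small_scene()))
        assert png.payload.startswith(b"\x89PNG\r\n")
        from PIL import Image
        img = Image.open(io.BytesIO(png.payload))
        # windows and marks leave non-white pixels
        assert img.convert("L").getextrema()[0] < 255

    def test_invalid_svg_bytes_error(self):
        bad = RenderedDocument("svg", b"this is not xml <", {})
        with pytest.raises(ValueError, match="invalid SVG"):
            render_png(bad)
        not_svg = RenderedDocument("svg", b"<root/>", {})
        with pytest.raises(ValueError, match="not an SVG"):
            render_png(not_svg)


class TestDiagnostics:
    def test_messages_printed_with_counts(self, capsys):
        report = ValidationReport(messages=[
            "warning: 2 out-of-bound annotation(s) removed",
            "warning: 1 annotation(s) removed: unknown chromosome(s) chrQ"])
        emit_console_diagnostics(report)
        err = capsys.readouterr().err
        assert "2 out-of-bound" in err and "chrQ" in err

    def test_silent_on_clean_input(self, capsys):
        emit_console_diagnostics(ValidationReport())
        assert capsys.readouterr().err == ""
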