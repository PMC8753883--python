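"""Inter-genome links: ortholog pairs drawn as distinctly colored curves.

Two track sets stand in for two species; links connect feature pairs
across them.  With distinct coloring each pair gets its own color and
legend entry; with a categorical value column, links are colored per
category instead.
"""

import tempfile
from pathlib import Path

from chromocanvas import FixtureSpec, PlotConfig, generate_fixture, run_pipeline

tmp = Path(tempfile.mkdtemp())
fx = generate_fixture(
    FixtureSpec(n_sets=2, chroms_per_set=2, n_features=25,
                oob_fraction=0.0, link_count=10, seed=13), tmp)

cfg = PlotConfig(
    chromosome_files=fx["chromosome_files"],
    annotation_files=fx["annotation_files"],
    links_file=fx["links_file"], link_distinct=True,
    title="ortholog pairs across two genomes",
    out=str(tmp / "links.html"), quiet=True)
doc, report = run_pipeline(cfg)

print("links drawn:", doc.manifest["links"],
      "| legend entries:", doc.manifest["legends"])
print("wrote", tmp / "links.html")
# Each of the 10 ortholog pairs gets one color and one legend line;
# swap link_distinct for a link file with a category column to group
# links by relationship type instead.
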