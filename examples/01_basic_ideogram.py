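"""Minimal ideogram: two chromosomes, a handful of annotated genes.

Builds the two tab-delimited inputs in a temporary directory, renders a
standalone interactive HTML plot, and prints the validation outcome and
the counts of drawn primitives.
"""

import tempfile
from pathlib import Path

from chromocanvas import PlotConfig, run_pipeline

tmp = Path(tempfile.mkdtemp())

(tmp / "chromosomes.tsv").write_text(
    "chr1\t1\t2000000\t900000\n"     # name, start, end, centromere
    "chr2\t1\t1200000\n")

(tmp / "genes.tsv").write_text(
    "geneA\tchr1\t120000\t125000\n"
    "geneB\tchr1\t800000\t815000\n"
    "geneC\tchr2\t400000\t404000\n"
    "geneD\tchr2\t990000\t995000\n"
    "stray\tchr2\t1500000\t1600000\n")  # beyond chr2 -> dropped with warning

cfg = PlotConfig(
    chromosome_files=[str(tmp / "chromosomes.tsv")],
    annotation_files=[str(tmp / "genes.tsv")],
    n_windows=100, labels=True,
    title="basic ideogram",
    out=str(tmp / "plot.html"))
doc, report = run_pipeline(cfg)

print(f"kept {len(report.kept)} of {report.n_total} annotations "
      f"({len(report.dropped)} dropped as out of bound)")
print("drawn primitives:", doc.manifest)
print("wrote", tmp / "plot.html")
# Each chromosome is split into 100-windows-max bins sharing one window
# size; hovering a window in the HTML lists the genes inside it.
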