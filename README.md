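# chromocanvas

Interactive chromosome ideogram plots for genome and multi-omics data.

Annotated genome assemblies come with feature tables — genes, SNPs,
transposable elements, methylation markers — whose regional distribution
along chromosomes is exactly what comparative and functional studies
need to see, yet whole chromosomes are far too long to draw base by base
on a publication-width canvas. `chromocanvas` addresses this for
bioinformaticians and bench scientists alike: it renders each chromosome
as a contiguous composition of fixed-width genomic **windows**, maps any
feature with known coordinates onto those windows, summarizes
feature-associated data per window, and exports either a standalone
interactive HTML file (hover tooltips, click-through hyperlinks,
zoom/pan — usable offline as a publication supplement) or a static
SVG/PNG image.

## The model

Given chromosomes (or regions) with coordinates `[start, end]` (1-based,
closed) and features `(id, chrom, start, end[, value[, url]])`:

- **Windowing.** One window size `w = ⌈L_max / N⌉` is chosen per track
  set, where `L_max` is the longest chromosome in the set and `N` the
  target window count (default 500). Window `k` of a chromosome spans
  `[start + k·w, min(start + (k+1)·w − 1, end)]`: contiguous, disjoint,
  equal width except possibly the last — so windows are comparable
  across chromosomes of one set.
- **Annotation.** *Point*-annotation assigns a feature to the single
  window containing its anchor base (start by default); *segment*-
  annotation assigns it to every window its interval overlaps.
- **Aggregation.** A window holding several numeric values shows one
  aggregate — sum, mean, min, max, or count — drawn as an in-chromosome
  heatmap or as a bar/scatter track above it; individual values stay in
  the tooltip. Categorical values color-code windows and marks by group.
- **Filters.** Condition marks (`count ≥ 5`, `|logFC| ≥ 2`, `between`,
  …) highlight windows or features without touching the data.
- **Multi-track (polyploidy).** Several chromosome sets — homologous
  copies of a phased assembly, species, conditions — stack vertically,
  each windowed and scaled independently.
- **Links.** Feature pairs or explicit `chrom:pos` loci connect across
  tracks as directed/undirected curves or chord-like ribbons, colored by
  category, numeric scale, or per-pair, with legends.

Out-of-bound annotations (coordinates outside their target chromosome)
are detected, removed, and reported on the console; the plot renders
from the remaining features. Structurally broken input files terminate
with a message before any output is written.

## Worked example

`examples/04_multitrack_filters.py` builds a three-track
differential-expression-style figure from seeded synthetic data — a bar
track of genes per window, a logFC scatter with a dashed zero line, and
a mean-logFC heatmap — with two condition filters:

```
windows drawn: 180 | scatter/bar marks: 203
dense windows highlighted: 18
strong-effect genes highlighted: 27
wrote /tmp/.../multitrack.html
```

180 windows cover the three single-chromosome tracks (60 each); 18
windows hold ≥ 5 genes and are painted yellow; 27 genes have
|logFC| ≥ 2 and their scatter dots turn orange. The other scripts in
`examples/` cover basic ideograms, segment (exon/intron) annotation,
window heatmaps, and inter-genome links.

The same plot from the shell:

```sh
chromocanvas fixtures --out fx --seed 7 --n-features 150
chromocanvas plot \
  --chromosomes fx/chromosomes_1.tsv --annotations fx/annotations_1.tsv \
  --plot-type scatter --aggregate mean --y-ref 0 \
  --filter "feature:value abs_ge 2 orange:strong" \
  --out plot.html
```

`chromocanvas validate` runs the readers and the out-of-bound check
alone; `--config plot.yaml` supplies any option from a YAML file, with
explicit flags taking precedence.

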