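# Methods

## Coordinate model

All coordinates are 1-based, fully closed intervals `[start, end]`, for
chromosomes and annotations alike; a chromosome's length is
`end − start + 1`. This reading keeps the file layout self-describing
(both endpoints are data) and avoids half-open off-by-one ambiguity in
user files. True BED (0-based, half-open) input is accepted with
`zero_based=True` / `--zero-based`, which increments starts on read.
Windows are exported as BED (converted back to 0-based half-open) when
dumped.

An annotation is *in bound* iff its chromosome is known and it is fully
contained: `chrom.start ≤ start` and `end ≤ chrom.end`. Partial
overlaps count as out of bound and are dropped. Containment (rather
than overlap) was chosen as the strictest testable reading of
"coordinates outside the boundary"; a partially overhanging feature is
almost always a coordinate error, and dropping it loudly is safer than
silently truncating it.

## Windowing

One window size is shared by every chromosome of a track set:
`w = ⌈L_max / N⌉` with `L_max` the set's longest chromosome length and
`N` the target window count (default 500, sized so the longest
chromosome fills a publication-width canvas at ≥ 2 px per window).
Consequences, all asserted as properties:

- window `k` spans `[start + k·w, min(start + (k+1)·w − 1, end)]`;
- spans exactly cover `[start, end]` — contiguous, disjoint, equal
  width except possibly the truncated last window;
- a chromosome shorter than one window gets a single truncated window,
  never zero;
- windows are comparable across chromosomes of a set (same bp span), so
  per-window counts and aggregates can be read as densities.

The window-size rule is this package's own definition, validated by its
invariants; an explicit `window_size` overrides it.

Point-annotation anchors a feature at its **start** base by default
(deterministic, matches intuition for stranded features); `midpoint` is
available. The window index is computed arithmetically
(`⌊(anchor − start)/w⌋`, clamped to the last index) and is tested for
equality with a linear-scan oracle over enumerated spans.
Segment-annotation adds the feature to the contiguous index range
`[index(start), index(end)]`, which provably equals the set of windows
overlapping the interval.

## Aggregation and filters

Per window: numeric member values feed `sum/mean/min/max`; `count`
counts *all* members regardless of value type; categorical values are
tallied into per-category counts and never enter arithmetic (mixed
columns must not poison the math). A segment feature contributes its
full value to every window it overlaps — no length-proportional
splitting — so tooltip values always equal input values. Windows
without numeric members carry no aggregate (rendered in the neutral
empty fill).

Filters are pure predicates `(scope, field, op, thresholds)` with ops
`lt, le, gt, ge, eq, between, abs_ge`; `between` is closed on both
ends, other ops follow the operator literally on ties; `abs_ge` covers
symmetric fold-change cut-offs in one spec. Multiple filters compose as
independent mark layers applied in order (later layers overwrite
earlier highlights on the same window); there is deliberately no
boolean combination grammar in this version.

## Layout

Within a track set, every chromosome shares one bp-per-px scale: box
width ∝ window count, the longest chromosome spanning the full drawable
width. Across sets each set rescales independently (sets of wildly
different genome sizes remain readable); `common_scale=True` forces one
global px-per-window for honest cross-set length comparison. Sets stack
vertically in input order; each chromosome row reserves a data-track
area (default 60 px) above the band (default 20 px) and a label area
below.

The genomic→canvas map is affine per chromosome
(`start → box.x`, `end → box.x + width`), strictly monotone. Scatter
values rescale linearly from the data range (widened to include the
reference line if set; overridable) to the track height, larger values
higher; bars rise from the zero baseline. Heatmap colors interpolate
piecewise-linearly in RGB across ≥ 2 anchors over the per-set aggregate
range, clamping outside it; a degenerate range maps to the last anchor.
Default scale is white → steel blue; categorical data draws from a
fixed 20-color cycle in first-appearance order so legends are stable
across reruns. Labels use a fixed 7 px-per-character width estimate and
a greedy left-to-right sweep that drops a label to the next row on
overlap — crude but deterministic; no font metrics are consulted.
Centromeres, when given, draw as a decorative notch and never affect
windowing.

## Links

Element endpoints anchor at the element's start base (the
point-annotation convention) on the chromosome edge facing the partner
track; `chrom:pos` loci map through the affine coordinate map. Edge
style is a cubic Bézier whose control points are offset vertically by
half the inter-anchor gap (an aesthetic constant); ribbon style is a
closed band whose end widths equal the connected features' drawn widths
(2 px minimum). Directed links carry exactly one arrowhead, at the
target. Self-links are rejected. All endpoints resolve before any
rendering, so an unresolvable link fails the whole run rather than
leaving a partial drawing.

## Rendering

SVG is built with the standard library XML tree and serialized with
fixed 2-decimal coordinate formatting, making output byte-identical for
identical inputs. Every window rectangle carries a stable id
(`win-<set>-<chrom>-<index>`) and class, so tests recount primitives
from the markup and compare against the manifest. HTML embeds the SVG,
a per-window JSON record block, and one inlined interactivity script
(hover tooltips, click-through hyperlinks, wheel zoom + drag pan of the
vector canvas); it references no external scripts, styles, or fonts.
Zoom is viewport-based — it scales the drawn canvas and does not
re-window at higher resolution. Each hyperlinked feature is wrapped in
exactly one anchor: its scatter dot where one exists, otherwise a small
tick glyph added on the chromosome band.

PNG export rasterizes the SVG payload with a purpose-built rasterizer
for the subset of SVG this package emits (rects, circles, lines, M/C/L/Z
paths flattened by sampling cubics at 24 steps, text), scaled by
`dpi/96`. Text rendering uses Pillow's default font and is approximate;
the PNG is a convenience raster, the SVG is the artifact of record.

## Synthetic data generator

`FixtureSpec`/`generate_fixture` emulate the package's input domain:
uniform feature starts over chromosome length, feature lengths uniform
in a configurable range (default 1–5000 bp, gene-scale against the
default 0.5–2 Mb chromosomes), values from `normal(μ,σ)` (logFC-like,
default `normal(0,1)`), `lognormal` (expression-like), or
`categorical(k)` (pathway-like), a controlled fraction of deliberately
out-of-bound features (constructed to overhang the chromosome end), and
optional links/hyperlinks. A sidecar manifest records ground truth —
out-of-bound ids and each in-bound feature's point window computed by
an independent linear scan — for closed-loop tests.

What the generator does *not* emulate: gene structure (exons/introns),
clustered or telomere-biased feature distributions, correlated values
between tracks, and realistic chromosome-length distributions. Passing
tests therefore demonstrate the correctness of parsing, windowing,
aggregation, geometry, and rendering contracts — not biological
plausibility of any particular figure.

## Numerical and degenerate-input choices

- `mean` is `sum/n`; the `mean·n = sum` identity is asserted to 1e−9
  relative tolerance.
- Color interpolation rounds half-up per channel; anchor positions
  reproduce anchor colors exactly.
- Empty windows, empty annotation files, and bare ideogram sets (no
  annotation file) all render valid documents.
- A value token that lexes entirely as a finite decimal is numeric;
  anything else (including `nan`/`inf` tokens) is a category string.
- Malformed rows inside an otherwise valid file are a hard failure of
  the whole file (mirroring terminate-on-bad-input semantics), with the
  path and line number in the message; out-of-bound *data* never is.

## Problem sizes

The test suite and the acceptance script run randomized checks at 500
chromosomes (windowing), 10⁴/5×10³ features (assignment), 2–3×10³
features (aggregation, filters), and a 2-set, 400-feature, 12-link
pipeline fixture — sizes chosen to exercise every branch while keeping
the whole suite interactive (seconds, one CPU).

## Known limitations

- No GFF/GTF/VCF ingestion, gzip inputs, or remote URLs; TSV only.
- No length-proportional value proration across windows.
- No circular (Circos-style) layout, link bundling, or value-weighted
  ribbon thickness.
- Label collision uses an estimated character width, not font metrics.
- PNG text placement is approximate (see Rendering).
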