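"""Readers and validators for the tab-delimited input dialects.

Three file kinds are understood, all UTF-8 TSV without a header row by
default (``header=True`` skips one line; lines starting with ``#`` and
blank lines are always ignored):

* **chromosome file** — ``name  start  end  [centromere]``: the genomic
  intervals to draw, one per rendered chromosome or region.
* **annotation file** — ``id  chrom  start  end  [value  [hyperlink]]``:
  the features to map.  The value column is parsed as a float when the
  whole token lexes as a decimal number and kept as a category string
  otherwise, so numeric tracks (logFC, methylation scores) and categorical
  tracks (pathway membership) share one column.
* **link file** — ``source  target  [value  [directed]]``: connections
  between annotated features or explicit ``chrom:pos`` loci.

Coordinates are 1-based, fully closed intervals ``[start, end]`` on both
chromosomes and annotations.  ``zero_based=True`` accepts BED-style
0-based half-open input and converts it on read (start+1, end unchanged).

Structural problems in a file (wrong column count, non-integer
coordinates, start > end, duplicate chromosome names) raise
:class:`FileFormatError` naming the offending line — the command-line
front end turns that into a console message and a nonzero exit.
Annotations whose coordinates fall outside their target chromosome are a
*data* problem, not a file problem: :func:`validate_annotations` removes
them with per-reason diagnostics and the plot proceeds with the rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

__all__ = [
    "ChromosomeSpec",
    "Annotation",
    "Link",
    "ValidationReport",
    "FileFormatError",
    "read_chromosome_file",
    "read_annotation_file",
    "read_link_file",
    "validate_annotations",
    "write_chromosome_file",
    "write_annotation_file",
    "write_link_file",
]

#: reason codes attached to dropped annotations
REASON_UNKNOWN_CHROM = "unknown-chromosome"
REASON_OUT_OF_BOUND = "out-of-bound"
REASON_MALFORMED = "malformed-row"


class FileFormatError(ValueError):
    """An input file violates the expected structure.

    Carries the path and 1-based line number of the first offending row so
    callers can print an actionable console message.
    """

    def __init__(self, message: str, path: "Path | str | None" = None,
                 line_no: "int | None" = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line_no is not None:
                loc += f", line {line_no}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = str(path) if path is not None else None
        self.line_no = line_no


@dataclass(frozen=True)
class ChromosomeSpec:
    """A named genomic interval to draw (whole chromosome or region)."""

    name: str
    start: int
    end: int
    centromere: "int | None" = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("chromosome name must be nonempty")
        if self.start > self.end:
            raise ValueError(
                f"chromosome {self.name}: start {self.start} > end {self.end}")
        if self.centromere is not None and not (
                self.start <= self.centromere <= self.end):
            raise ValueError(
                f"chromosome {self.name}: centromere {self.centromere} "
                f"outside [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        """Interval length in bp (closed interval: end − start + 1)."""
        return self.end - self.start + 1


@dataclass(frozen=True)
class Annotation:
    """One genomic feature with optional associated value and hyperlink."""

    element_id: str
    chrom: str
    start: int
    end: int
    value: "float | str | None" = None
    hyperlink: "str | None" = None

    def __post_init__(self) -> None:
        if not self.element_id:
            raise ValueError("annotation element_id must be nonempty")
        if self.start > self.end:
            raise ValueError(
                f"annotation {self.element_id}: start {self.start} > end {self.end}")

    @property
    def numeric_value(self) -> "float | None":
        """The value as a float, or None when absent or categorical."""
        return self.value if isinstance(self.value, float) else None

    @property
    def category(self) -> "str | None":
        """The value as a category string, or None when absent or numeric."""
        return self.value if isinstance(self.value, str) else None


Locus = tuple  # (chrom: str, pos: int)
Endpoint = Union[str, tuple]


@dataclass(frozen=True)
class Link:
    """A connection between two annotated features or explicit loci.

    Endpoints are either an element id string or a ``(chrom, pos)`` tuple
    (written ``chrom:pos`` in the link file).
    """

    source: Endpoint
    target: Endpoint
    value: "float | str | None" = None
    directed: bool = False

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-link not allowed: {self.source!r}")


@dataclass
class ValidationReport:
    """Outcome of the out-of-bound detection step.

    ``kept`` and ``dropped`` partition the parsed annotations; each dropped
    entry carries a reason code; ``messages`` are human-readable summaries
    the front end prints to the console.
    """

    kept: list = field(default_factory=list)
    dropped: list = field(default_factory=list)  # (Annotation, reason)
    messages: list = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.kept) + len(self.dropped)


# ---------------------------------------------------------------------------
# low-level row iteration

def _iter_rows(path) -> Iterable[tuple]:
    """Yield (line_no, fields) for data rows; skip blanks and # comments."""
    text = Path(path).read_text(encoding="utf-8")
    for line_no, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        yield line_no, raw.rstrip("\n").split("\t")


def _parse_int(token: str, what: str, path, line_no: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise FileFormatError(
            f"non-integer {what} {token!r}", path, line_no) from None


def _parse_value(token: str) -> "float | str":
    """Numeric if the whole token lexes as a finite decimal, else category."""
    try:
        v = float(token)
    except ValueError:
        return token
    if math.isfinite(v):
        return v
    return token  # 'nan'/'inf' tokens are treated as category strings


# ---------------------------------------------------------------------------
# readers

def read_chromosome_file(path, *, header: bool = False,
                         zero_based: bool = False) -> list:
    """Parse a chromosome file into :class:`ChromosomeSpec` records.

    Rows have 3 columns (name, start, end) or 4 (…, centromere position).
    Raises :class:`FileFormatError` on a wrong column count, non-integer
    coordinate, start > end, or duplicate name.
    """
    specs: list = []
    seen: set = set()
    for i, (line_no, fields) in enumerate(_iter_rows(path)):
        if header and i == 0:
            continue
        if not 3 <= len(fields) <= 4:
            raise FileFormatError(
                f"chromosome row needs 3 or 4 tab-separated fields, "
                f"got {len(fields)}", path, line_no)
        name = fields[0].strip()
        start = _parse_int(fields[1], "start coordinate", path, line_no)
        end = _parse_int(fields[2], "end coordinate", path, line_no)
        if zero_based:
            start += 1
        centromere = None
        if len(fields) == 4:
            centromere = _parse_int(fields[3], "centromere position",
                                    path, line_no)
            if zero_based:
                centromere += 1
        if not name:
            raise FileFormatError("empty chromosome name", path, line_no)
        if name in seen:
            raise FileFormatError(
                f"duplicate chromosome name {name!r}", path, line_no)
        seen.add(name)
        try:
            specs.append(ChromosomeSpec(name, start, end, centromere))
        except ValueError as exc:
            raise FileFormatError(str(exc), path, line_no) from None
    return specs


def read_annotation_file(path, *, header: bool = False,
                         zero_based: bool = False) -> list:
    """Parse an annotation file into :class:`Annotation` records.

    Rows have 4–6 columns: id, chrom, start, end[, value[, hyperlink]].
    """
    annotations: list = []
    for i, (line_no, fields) in enumerate(_iter_rows(path)):
        if header and i == 0:
            continue
        if not 4 <= len(fields) <= 6:
            raise FileFormatError(
                f"annotation row needs 4 to 6 tab-separated fields, "
                f"got {len(fields)}", path, line_no)
        element_id = fields[0].strip()
        chrom = fields[1].strip()
        start = _parse_int(fields[2], "start coordinate", path, line_no)
        end = _parse_int(fields[3], "end coordinate", path, line_no)
        if zero_based:
            start += 1
        value = _parse_value(fields[4]) if len(fields) >= 5 and fields[4] != "" else None
        hyperlink = fields[5] if len(fields) == 6 and fields[5] != "" else None
        if not element_id:
            raise FileFormatError("empty element id", path, line_no)
        try:
            annotations.append(
                Annotation(element_id, chrom, start, end, value, hyperlink))
        except ValueError as exc:
            raise FileFormatError(str(exc), path, line_no) from None
    return annotations


def _parse_endpoint(token: str, path, line_no: int) -> Endpoint:
    """``chrom:pos`` becomes a (chrom, pos) locus; anything else an id."""
    if ":" in token:
        chrom, _, pos = token.rpartition(":")
        if chrom:
            try:
                return (chrom, int(pos))
            except ValueError:
                pass  # ids may legitimately contain ':'
    if not token:
        raise FileFormatError("empty link endpoint", path, line_no)
    return token


_TRUE_TOKENS = {"1", "true", "yes", "directed"}
_FALSE_TOKENS = {"0", "false", "no", "undirected", ""}


def read_link_file(path, *, header: bool = False) -> list:
    """Parse a link file into :class:`Link` records.

    Rows have 2–4 columns: source, target[, value[, directed flag]].
    """
    links: list = []
    for i, (line_no, fields) in enumerate(_iter_rows(path)):
        if header and i == 0:
            continue
        if not 2 <= len(fields) <= 4:
            raise FileFormatError(
                f"link row needs 2 to 4 tab-separated fields, "
                f"got {len(fields)}", path, line_no)
        source = _parse_endpoint(fields[0].strip(), path, line_no)
        target = _parse_endpoint(fields[1].strip(), path, line_no)
        value = _parse_value(fields[2]) if len(fields) >= 3 and fields[2] != "" else None
        directed = False
        if len(fields) == 4:
            token = fields[3].strip().lower()
            if token in _TRUE_TOKENS:
                directed = True
            elif token in _FALSE_TOKENS:
                directed = False
            else:
                raise FileFormatError(
                    f"unrecognized directed flag {fields[3]!r}", path, line_no)
        try:
            links.append(Link(source, target, value, directed))
        except ValueError as exc:
            raise FileFormatError(str(exc), path, line_no) from None
    return links


# ---------------------------------------------------------------------------
# validation

def validate_annotations(annotations: Sequence, chromosomes: Sequence,
                         ) -> ValidationReport:
    """Partition annotations into kept and dropped.

    An annotation is kept iff its ``chrom`` names a known chromosome and it
    is fully contained: ``chrom.start <= start`` and ``end <= chrom.end``.
    Partial overlaps count as out-of-bound.  Never raises — removal plus a
    console-ready message is the contract, and the plot is rendered from
    the kept set.
    """
    by_name = {c.name: c for c in chromosomes}
    report = ValidationReport()
    unknown_chroms: dict = {}
    n_oob = 0
    for a in annotations:
        spec = by_name.get(a.chrom)
        if spec is None:
            report.dropped.append((a, REASON_UNKNOWN_CHROM))
            unknown_chroms[a.chrom] = unknown_chroms.get(a.chrom, 0) + 1
        elif spec.start <= a.start and a.end <= spec.end:
            report.kept.append(a)
        else:
            report.dropped.append((a, REASON_OUT_OF_BOUND))
            n_oob += 1
    if n_oob:
        report.messages.append(
            f"warning: {n_oob} out-of-bound annotation(s) removed "
            f"(coordinates outside the target chromosome boundary)")
    if unknown_chroms:
        names = ", ".join(sorted(unknown_chroms))
        total = sum(unknown_chroms.values())
        report.messages.append(
            f"warning: {total} annotation(s) removed: unknown chromosome(s) "
            f"{names}")
    return report


# ---------------------------------------------------------------------------
# writers (round-trip support, --dump-windows, fixture output)

def _format_value(value) -> str:
    if isinstance(value, float):
        return repr(value) if not value.is_integer() else str(int(value))
    return str(value)


def write_chromosome_file(specs: Sequence, path) -> None:
    lines = []
    for c in specs:
        row = [c.name, str(c.start), str(c.end)]
        if c.centromere is not None:
            row.append(str(c.centromere))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_annotation_file(annotations: Sequence, path) -> None:
    lines = []
    for a in annotations:
        row = [a.element_id, a.chrom, str(a.start), str(a.end)]
        if a.value is not None or a.hyperlink is not None:
            row.append(_format_value(a.value) if a.value is not None else "")
        if a.hyperlink is not None:
            row.append(a.hyperlink)
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _format_endpoint(e: Endpoint) -> str:
    if isinstance(e, tuple):
        return f"{e[0]}:{e[1]}"
    return e


def write_link_file(links: Sequence, path) -> None:
    lines = []
    for l in links:
        row = [_format_endpoint(l.source), _format_endpoint(l.target)]
        if l.value is not None or l.directed:
            row.append(_format_value(l.value) if l.value is not None else "")
        if l.directed:
            row.append("1")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
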