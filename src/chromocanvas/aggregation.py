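"""Per-window data aggregation, condition filters, and tooltip payloads.

A window holding several features shows one aggregated value (sum, mean,
min, max or count of its members' numeric values); individual values stay
available in the tooltip payload.  Categorical values are tallied into
per-window group counts instead of entering arithmetic.  A segment
feature spanning several windows contributes its full value to every one
of them — no length-proportional splitting — so tooltip values always
equal the input values.

Filters ("epi-tags") mark features or windows whose field satisfies a
comparison against thresholds, e.g. windows with >= 5 member genes, or
features with |logFC| >= 2.  Marking never mutates values; multiple
filters compose as independent layers painted in order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .io_formats import Annotation
from .windowing import Window

__all__ = [
    "AGG_OPS",
    "FILTER_OPS",
    "AggregatedWindow",
    "FilterSpec",
    "aggregate",
    "aggregate_windows",
    "apply_filter",
    "build_tooltip_payload",
    "window_key",
]

AGG_OPS = ("sum", "mean", "min", "max", "count")
FILTER_OPS = ("lt", "le", "gt", "ge", "eq", "between", "abs_ge")


@dataclass
class AggregatedWindow:
    """A window plus its aggregate, raw member values, and category tally."""

    window: Window
    agg_value: "float | None"
    member_values: List[Tuple[str, object]]  # (element_id, value-or-None)
    group_counts: Dict[str, int] = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.member_values)

    @property
    def key(self) -> str:
        return window_key(self.window)


def window_key(w: Window) -> str:
    """Stable identifier for a window: ``chrom:index``."""
    return f"{w.chrom}:{w.index}"


def aggregate(values: Sequence[float], op: str) -> float:
    """Combine numeric values with one of sum / mean / min / max / count.

    ``count`` accepts an empty list (returning 0); the arithmetic ops
    require at least one value.
    """
    if op not in AGG_OPS:
        raise ValueError(f"unknown aggregation op {op!r}; use one of {AGG_OPS}")
    if op == "count":
        return float(len(values))
    if not values:
        raise ValueError(f"aggregation {op!r} needs at least one value")
    if op == "sum":
        return float(sum(values))
    if op == "mean":
        return float(sum(values)) / len(values)
    if op == "min":
        return float(min(values))
    return float(max(values))


def aggregate_windows(windows: Sequence[Window],
                      annotations: Mapping[str, Annotation],
                      op: str = "count") -> List[AggregatedWindow]:
    """Aggregate each window's member values.

    Numeric member values feed the arithmetic ops; categorical values are
    tallied into ``group_counts``.  ``count`` counts *all* members
    regardless of value type.  Windows with no numeric members get
    ``agg_value=None`` under arithmetic ops (and 0.0 under count).
    """
    if op not in AGG_OPS:
        raise ValueError(f"unknown aggregation op {op!r}; use one of {AGG_OPS}")
    out = []
    for w in windows:
        member_values: List[Tuple[str, object]] = []
        numeric: List[float] = []
        group_counts: Dict[str, int] = {}
        for eid in w.members:
            a = annotations[eid]
            member_values.append((eid, a.value))
            if a.numeric_value is not None:
                numeric.append(a.numeric_value)
            elif a.category is not None:
                group_counts[a.category] = group_counts.get(a.category, 0) + 1
        if op == "count":
            agg = float(len(member_values))
        elif numeric:
            agg = aggregate(numeric, op)
        else:
            agg = None
        out.append(AggregatedWindow(w, agg, member_values, group_counts))
    return out


@dataclass(frozen=True)
class FilterSpec:
    """One condition-based mark: field OP threshold(s) -> highlight color.

    ``scope`` picks what is tested (``"feature"`` or ``"window"``);
    ``field`` picks the tested quantity (``value`` for features,
    ``agg_value`` or ``count`` for windows); ``between`` takes two
    thresholds (closed on both ends), every other op exactly one;
    ``abs_ge`` marks ``|x| >= t`` so a single spec covers symmetric
    logFC cut-offs.
    """

    scope: str  # "feature" | "window"
    field: str  # "value" | "agg_value" | "count"
    op: str
    thresholds: Tuple[float, ...]
    highlight: str = "#ffd700"
    tag_label: "str | None" = None

    def __post_init__(self) -> None:
        if self.scope not in ("feature", "window"):
            raise ValueError(f"filter scope must be feature|window, got {self.scope!r}")
        if self.field not in ("value", "agg_value", "count"):
            raise ValueError(f"unknown filter field {self.field!r}")
        if self.op not in FILTER_OPS:
            raise ValueError(f"unknown filter op {self.op!r}; use one of {FILTER_OPS}")
        need = 2 if self.op == "between" else 1
        if len(self.thresholds) != need:
            raise ValueError(
                f"op {self.op!r} needs exactly {need} threshold(s), "
                f"got {len(self.thresholds)}")

    def matches(self, x: float) -> bool:
        t = self.thresholds
        if self.op == "lt":
            return x < t[0]
        if self.op == "le":
            return x <= t[0]
        if self.op == "gt":
            return x > t[0]
        if self.op == "ge":
            return x >= t[0]
        if self.op == "eq":
            return x == t[0]
        if self.op == "between":
            return t[0] <= x <= t[1]
        return abs(x) >= t[0]  # abs_ge


def _filter_field_value(spec: FilterSpec, item) -> "float | None":
    if spec.scope == "feature":
        if spec.field != "value":
            raise ValueError(
                f"feature-scope filters test 'value', not {spec.field!r}")
        return item.numeric_value
    if spec.field == "count":
        return float(item.count)
    if spec.field == "agg_value":
        return item.agg_value
    raise ValueError(
        f"window-scope filters test 'agg_value' or 'count', not {spec.field!r}")


def apply_filter(spec: FilterSpec, items: Iterable) -> set:
    """Return the ids of items whose field satisfies the condition.

    ``items`` are :class:`~chromocanvas.io_formats.Annotation` records for
    feature scope (marked by element_id) or :class:`AggregatedWindow`
    records for window scope (marked by ``chrom:index`` key).  Items whose
    field is absent (no numeric value) are never marked.  Pure: values are
    never mutated, and reapplying the same spec yields the same set.
    """
    marked = set()
    for item in items:
        x = _filter_field_value(spec, item)
        if x is not None and spec.matches(x):
            marked.add(item.element_id if spec.scope == "feature" else item.key)
    return marked


def build_tooltip_payload(aw: AggregatedWindow,
                          annotations: "Mapping[str, Annotation] | None" = None,
                          active_tags: "Sequence[str] | None" = None) -> dict:
    """Assemble the structured record shown when hovering a window.

    Lists the window span, member ids with their individual values, the
    aggregate, category tallies, active filter tags, and each member's
    hyperlink when present.
    """
    members = []
    for eid, value in aw.member_values:
        rec: dict = {"id": eid}
        if value is not None:
            rec["value"] = value
        if annotations is not None:
            link = annotations[eid].hyperlink
            if link:
                rec["hyperlink"] = link
        members.append(rec)
    w = aw.window
    payload = {
        "chrom": w.chrom,
        "window": w.index,
        "span": f"{w.span_start}–{w.span_end}",
        "n_elements": aw.count,
        "members": members,
    }
    if aw.agg_value is not None:
        payload["aggregate"] = aw.agg_value
    if aw.group_counts:
        payload["group_counts"] = dict(aw.group_counts)
    if active_tags:
        payload["tags"] = list(active_tags)
    return payload
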