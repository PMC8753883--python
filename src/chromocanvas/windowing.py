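"""Genomic windows: the atomic drawn unit of a chromosome.

Each rendered chromosome is a contiguous composition of fixed-width
windows.  One window size is shared by every chromosome in a track set so
windows are comparable across chromosomes: by default the size is chosen
so the *longest* chromosome of the set splits into ``target_windows``
windows (``window_size = ceil(L_max / target_windows)``), and every other
chromosome gets ``ceil(length / window_size)`` windows, the last one
truncated when the length is not a multiple of the size.  Chromosomes
shorter than one window get a single truncated window, never zero.

Features land in windows by one of two conventions:

* **point-annotation** ignores the feature's extent and anchors it on a
  single base (the start coordinate by default, optionally the midpoint);
* **segment-annotation** spreads the feature over every window its
  ``[start, end]`` interval overlaps — by construction a contiguous index
  range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

from .io_formats import Annotation, ChromosomeSpec

__all__ = [
    "Window",
    "WindowingPlan",
    "plan_windows",
    "build_windows",
    "assign_point",
    "assign_segment",
    "assign_annotations",
    "DEFAULT_TARGET_WINDOWS",
]

#: default number of windows the longest chromosome of a set is split into
DEFAULT_TARGET_WINDOWS = 500


@dataclass
class Window:
    """One fixed-width genomic bin holding its assigned element ids."""

    chrom: str
    index: int
    span_start: int
    span_end: int
    members: List[str] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.span_end - self.span_start + 1


@dataclass(frozen=True)
class WindowingPlan:
    """A window size plus the window count for each chromosome it covers."""

    window_size: int
    per_chromosome_counts: Dict[str, int]


def plan_windows(chromosomes: Sequence[ChromosomeSpec],
                 target_windows: int = DEFAULT_TARGET_WINDOWS,
                 explicit_window_size: "int | None" = None) -> WindowingPlan:
    """Choose one shared window size for a set of chromosomes.

    With ``explicit_window_size`` the size is used as given; otherwise
    ``window_size = ceil(L_max / target_windows)`` where ``L_max`` is the
    longest chromosome in the set, so that chromosome gets exactly
    ``target_windows`` windows (or fewer, one per base, if it is shorter
    than ``target_windows`` bp).
    """
    if not chromosomes:
        raise ValueError("plan_windows needs at least one chromosome")
    if explicit_window_size is not None:
        if explicit_window_size < 1:
            raise ValueError(
                f"window size must be >= 1, got {explicit_window_size}")
        w = explicit_window_size
    else:
        if target_windows < 1:
            raise ValueError(f"target_windows must be >= 1, got {target_windows}")
        l_max = max(c.length for c in chromosomes)
        w = math.ceil(l_max / target_windows)
        w = max(w, 1)
    counts = {c.name: math.ceil(c.length / w) for c in chromosomes}
    return WindowingPlan(window_size=w, per_chromosome_counts=counts)


def build_windows(chrom: ChromosomeSpec, plan: WindowingPlan) -> List[Window]:
    """Materialize the contiguous windows of one chromosome.

    Window ``k`` spans ``[start + k*w, min(start + (k+1)*w - 1, end)]``;
    the spans exactly cover ``[chrom.start, chrom.end]`` with no gap or
    overlap.  Members start empty.
    """
    if chrom.name not in plan.per_chromosome_counts:
        raise ValueError(f"plan does not cover chromosome {chrom.name!r}")
    w = plan.window_size
    n = plan.per_chromosome_counts[chrom.name]
    windows = []
    for k in range(n):
        span_start = chrom.start + k * w
        span_end = min(chrom.start + (k + 1) * w - 1, chrom.end)
        windows.append(Window(chrom.name, k, span_start, span_end))
    return windows


def _point_index(pos: int, chrom_start: int, window_size: int,
                 n_windows: int) -> int:
    return min((pos - chrom_start) // window_size, n_windows - 1)


def assign_point(a: Annotation, windows: Sequence[Window],
                 anchor: str = "start") -> int:
    """Assign a feature to the single window containing its anchor base.

    ``anchor`` is ``"start"`` (default) or ``"midpoint"``.  The feature's
    id is appended to that window's members and the index returned.  The
    caller must have validated bounds: an out-of-range anchor raises.
    """
    if not windows:
        raise ValueError("no windows to assign into")
    if anchor == "start":
        pos = a.start
    elif anchor == "midpoint":
        pos = (a.start + a.end) // 2
    else:
        raise ValueError(f"unknown point anchor {anchor!r}")
    chrom_start = windows[0].span_start
    chrom_end = windows[-1].span_end
    if not chrom_start <= pos <= chrom_end:
        raise ValueError(
            f"annotation {a.element_id} anchor {pos} outside chromosome "
            f"range [{chrom_start}, {chrom_end}]; validate before assigning")
    w = windows[0].width  # all but possibly the last share this width
    idx = _point_index(pos, chrom_start, w, len(windows))
    windows[idx].members.append(a.element_id)
    return idx


def assign_segment(a: Annotation, windows: Sequence[Window]) -> range:
    """Assign a feature to every window its [start, end] interval overlaps.

    Returns the contiguous index range; the feature's id is appended to
    each window in it.
    """
    if not windows:
        raise ValueError("no windows to assign into")
    chrom_start = windows[0].span_start
    chrom_end = windows[-1].span_end
    if not (chrom_start <= a.start and a.end <= chrom_end):
        raise ValueError(
            f"annotation {a.element_id} [{a.start}, {a.end}] outside "
            f"chromosome range [{chrom_start}, {chrom_end}]")
    w = windows[0].width
    first = _point_index(a.start, chrom_start, w, len(windows))
    last = _point_index(a.end, chrom_start, w, len(windows))
    for k in range(first, last + 1):
        windows[k].members.append(a.element_id)
    return range(first, last + 1)


def assign_annotations(annotations: Sequence[Annotation],
                       windows_by_chrom: Dict[str, List[Window]],
                       mode: str = "point",
                       anchor: str = "start") -> None:
    """Assign every annotation into its chromosome's windows in place.

    ``mode`` is ``"point"`` or ``"segment"``.  Annotations must already be
    validated (every chrom known, coordinates in bound).
    """
    if mode not in ("point", "segment"):
        raise ValueError(f"unknown annotation mode {mode!r}")
    for a in annotations:
        windows = windows_by_chrom[a.chrom]
        if mode == "point":
            assign_point(a, windows, anchor=anchor)
        else:
            assign_segment(a, windows)
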