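"""Color parsing, interpolation, and categorical palettes.

Colors are accepted as ``#rrggbb`` / ``#rgb`` hex or a small set of CSS
names, and normalized to lowercase ``#rrggbb`` on output so rendered
documents are byte-stable.
"""

from __future__ import annotations

import colorsys
from typing import List, Sequence, Tuple

__all__ = [
    "parse_color",
    "to_hex",
    "interpolate",
    "piecewise_interpolate",
    "distinct_colors",
    "DEFAULT_CATEGORY_PALETTE",
    "DEFAULT_HEATMAP_ANCHORS",
]

RGB = Tuple[int, int, int]

_NAMED = {
    "black": (0, 0, 0), "white": (255, 255, 255), "red": (255, 0, 0),
    "green": (0, 128, 0), "blue": (0, 0, 255), "yellow": (255, 255, 0),
    "orange": (255, 165, 0), "purple": (128, 0, 128), "grey": (128, 128, 128),
    "gray": (128, 128, 128), "steelblue": (70, 130, 180),
    "lightgreen": (144, 238, 144), "darkgreen": (0, 100, 0),
    "gold": (255, 215, 0), "pink": (255, 192, 203), "brown": (165, 42, 42),
    "cyan": (0, 255, 255), "magenta": (255, 0, 255), "navy": (0, 0, 128),
    "teal": (0, 128, 128), "olive": (128, 128, 0), "maroon": (128, 0, 0),
    "salmon": (250, 128, 114), "darkorange": (255, 140, 0),
}

#: fixed 20-color cycle for categorical data (first-appearance order);
#: colorblind-aware tableau-style hues
DEFAULT_CATEGORY_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
    "#aec7e8", "#ffbb78", "#98df8a", "#ff9896", "#c5b0d5",
    "#c49c94", "#f7b6d2", "#c7c7c7", "#dbdb8d", "#9edae5",
)

#: default 2-anchor heatmap scale: white -> steel blue
DEFAULT_HEATMAP_ANCHORS = ("#ffffff", "#4682b4")


def parse_color(color: str) -> RGB:
    """Parse ``#rrggbb``, ``#rgb`` or a known CSS name into an RGB triple."""
    c = color.strip().lower()
    if c in _NAMED:
        return _NAMED[c]
    if c.startswith("#"):
        h = c[1:]
        if len(h) == 3:
            h = "".join(ch * 2 for ch in h)
        if len(h) == 6:
            try:
                return (int(h[0:2], 16), int(h[2:4], 16), int(h[4:6], 16))
            except ValueError:
                pass
    raise ValueError(f"unrecognized color {color!r}")


def to_hex(rgb: RGB) -> str:
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def interpolate(a: RGB, b: RGB, t: float) -> RGB:
    """Linear RGB interpolation; t=0 gives a exactly, t=1 gives b exactly."""
    t = min(max(t, 0.0), 1.0)
    return tuple(round(a[i] + (b[i] - a[i]) * t) for i in range(3))  # type: ignore


def piecewise_interpolate(anchors: Sequence[RGB], t: float) -> RGB:
    """Piecewise-linear interpolation across >=1 anchors over t in [0, 1]."""
    if not anchors:
        raise ValueError("need at least one color anchor")
    if len(anchors) == 1:
        return anchors[0]
    t = min(max(t, 0.0), 1.0)
    n_seg = len(anchors) - 1
    pos = t * n_seg
    seg = min(int(pos), n_seg - 1)
    return interpolate(anchors[seg], anchors[seg + 1], pos - seg)


def distinct_colors(n: int, palette: Sequence[str] = DEFAULT_CATEGORY_PALETTE,
                    ) -> List[str]:
    """n visually distinct colors: the palette first, then golden-ratio hues."""
    out = [to_hex(parse_color(c)) for c in palette[:n]]
    phi = 0.6180339887498949
    h = 0.0
    while len(out) < n:
        h = (h + phi) % 1.0
        rgb = tuple(round(255 * v) for v in colorsys.hsv_to_rgb(h, 0.65, 0.9))
        hx = to_hex(rgb)  # type: ignore[arg-type]
        if hx not in out:
            out.append(hx)
    return out
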