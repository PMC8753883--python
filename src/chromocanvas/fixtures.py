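"""Seeded synthetic input generator.

Produces chromosome / annotation / link TSVs in the package's input
dialect, with controlled statistical structure: uniform feature starts,
a chosen value model (normal or lognormal numeric data emulating logFC
or methylation scores, or k-category labels emulating pathway
membership), a known fraction of deliberately out-of-bound features, and
optional links and hyperlinks.  A sidecar JSON manifest records the
ground truth — which rows are out of bound, and each in-bound feature's
point-window index computed by an independent linear scan over
enumerated window spans — so tests can compare engine output against
recorded truth.

Everything derives from ``spec.seed``: the same spec always writes
byte-identical files.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .windowing import DEFAULT_TARGET_WINDOWS

__all__ = ["FixtureSpec", "generate_fixture"]

_VALUE_MODEL = re.compile(
    r"^(none|normal|lognormal|categorical)"
    r"(?:\(\s*(-?[\d.]+)\s*(?:,\s*(-?[\d.]+)\s*)?\))?$")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``value_model`` is ``"none"``, ``"normal(mu,sigma)"``,
    ``"lognormal(mu,sigma)"`` or ``"categorical(k)"``.  ``n_features``
    counts features per set; exactly ``round(oob_fraction * n_features)``
    of them are deliberately out of bound.
    """

    n_sets: int = 1
    chroms_per_set: int = 3
    length_range: Tuple[int, int] = (500_000, 2_000_000)
    n_features: int = 100
    value_model: str = "normal(0,1)"
    oob_fraction: float = 0.1
    link_count: int = 0
    link_categories: int = 0
    directed_fraction: float = 0.0
    hyperlink_fraction: float = 0.0
    feature_length_range: Tuple[int, int] = (1, 5000)
    include_centromeres: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sets, self.chroms_per_set, self.n_features,
               self.link_count) < 0:
            raise ValueError("all counts must be >= 0")
        if not 0.0 <= self.oob_fraction <= 1.0:
            raise ValueError(
                f"oob_fraction must be in [0, 1], got {self.oob_fraction}")
        if _VALUE_MODEL.match(self.value_model) is None:
            raise ValueError(f"unrecognized value model {self.value_model!r}")


def _parse_value_model(model: str):
    m = _VALUE_MODEL.match(model)
    kind = m.group(1)
    p1 = float(m.group(2)) if m.group(2) is not None else None
    p2 = float(m.group(3)) if m.group(3) is not None else None
    if kind in ("normal", "lognormal"):
        return kind, (p1 if p1 is not None else 0.0,
                      p2 if p2 is not None else 1.0)
    if kind == "categorical":
        k = int(p1) if p1 is not None else 3
        if k < 1:
            raise ValueError("categorical model needs k >= 1")
        return kind, (k,)
    return "none", ()


def _fmt_float(v: float) -> str:
    return f"{v:.4f}"


def _oracle_point_window(start: int, chrom_start: int, chrom_end: int,
                         window_size: int) -> int:
    """Linear scan over enumerated window spans (independent oracle)."""
    spans = []
    s = chrom_start
    while s <= chrom_end:
        spans.append((s, min(s + window_size - 1, chrom_end)))
        s += window_size
    for k, (lo, hi) in enumerate(spans):
        if lo <= start <= hi:
            return k
    return len(spans) - 1


def generate_fixture(spec: FixtureSpec, outdir) -> Dict[str, object]:
    """Write the fixture files and manifest; return their paths.

    Per set: ``chromosomes_<i>.tsv`` and ``annotations_<i>.tsv``; plus
    ``links.tsv`` when ``link_count > 0`` and always ``manifest.json``.
    Returns ``{"chromosome_files": [...], "annotation_files": [...],
    "links_file": path-or-None, "manifest_file": path, "manifest": dict}``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    kind, params = _parse_value_model(spec.value_model)

    chromosome_files: List[str] = []
    annotation_files: List[str] = []
    manifest_sets = []
    all_inbound_ids: List[str] = []

    for si in range(spec.n_sets):
        chroms = []
        for ci in range(spec.chroms_per_set):
            length = int(rng.integers(spec.length_range[0],
                                      spec.length_range[1] + 1))
            chroms.append((f"s{si + 1}chr{ci + 1}", 1, length))
        l_max = max(c[2] for c in chroms)
        window_size = max(math.ceil(l_max / DEFAULT_TARGET_WINDOWS), 1)

        n = spec.n_features
        n_oob = round(spec.oob_fraction * n)
        oob_ids: List[str] = []
        inbound_ids: List[str] = []
        oracle_windows: Dict[str, dict] = {}
        rows = []
        oob_slots = set(rng.choice(n, size=n_oob, replace=False).tolist()
                        ) if n_oob else set()
        for fi in range(n):
            eid = f"s{si + 1}f{fi + 1}"
            name, cstart, cend = chroms[int(rng.integers(len(chroms)))]
            flen = int(rng.integers(spec.feature_length_range[0],
                                    spec.feature_length_range[1] + 1))
            if fi in oob_slots:
                # place the interval end past the chromosome boundary
                start = int(rng.integers(cend - flen + 1, cend + flen + 1))
                end = max(start + flen - 1, cend + 1)
                oob_ids.append(eid)
            else:
                start = int(rng.integers(cstart, cend + 1))
                end = min(start + flen - 1, cend)
                inbound_ids.append(eid)
                oracle_windows[eid] = {
                    "chrom": name,
                    "point_window": _oracle_point_window(
                        start, cstart, cend, window_size)}
            value: "str | None" = None
            if kind == "normal":
                value = _fmt_float(rng.normal(params[0], params[1]))
            elif kind == "lognormal":
                value = _fmt_float(rng.lognormal(params[0], params[1]))
            elif kind == "categorical":
                value = f"group{int(rng.integers(params[0])) + 1}"
            hyperlink = None
            if spec.hyperlink_fraction and rng.random() < spec.hyperlink_fraction:
                hyperlink = f"https://example.org/feature/{eid}"
            row = [eid, name, str(start), str(end)]
            if value is not None or hyperlink is not None:
                row.append(value if value is not None else "")
            if hyperlink is not None:
                row.append(hyperlink)
            rows.append("\t".join(row))

        cfile = outdir / f"chromosomes_{si + 1}.tsv"
        clines = []
        for name, cstart, cend in chroms:
            fields = [name, str(cstart), str(cend)]
            if spec.include_centromeres:
                fields.append(str((cstart + cend) // 2))
            clines.append("\t".join(fields))
        cfile.write_text("\n".join(clines) + "\n", encoding="utf-8")
        afile = outdir / f"annotations_{si + 1}.tsv"
        afile.write_text("\n".join(rows) + ("\n" if rows else ""),
                         encoding="utf-8")
        chromosome_files.append(str(cfile))
        annotation_files.append(str(afile))
        all_inbound_ids.extend(inbound_ids)
        manifest_sets.append({
            "chromosome_file": str(cfile),
            "annotation_file": str(afile),
            "chromosomes": [{"name": c[0], "start": c[1], "end": c[2]}
                            for c in chroms],
            "window_size": window_size,
            "target_windows": DEFAULT_TARGET_WINDOWS,
            "in_bound_ids": inbound_ids,
            "out_of_bound_ids": oob_ids,
            "oracle_point_windows": oracle_windows,
        })

    links_file = None
    if spec.link_count > 0:
        if len(all_inbound_ids) < 2:
            raise ValueError("need >= 2 in-bound features to generate links")
        llines = []
        for li in range(spec.link_count):
            a, b = rng.choice(len(all_inbound_ids), size=2, replace=False)
            fields = [all_inbound_ids[int(a)], all_inbound_ids[int(b)]]
            directed = bool(rng.random() < spec.directed_fraction)
            if spec.link_categories > 0:
                fields.append(
                    f"linkgrp{int(rng.integers(spec.link_categories)) + 1}")
            elif directed:
                fields.append("")
            if directed:
                fields.append("1")
            llines.append("\t".join(fields))
        links_path = outdir / "links.tsv"
        links_path.write_text("\n".join(llines) + "\n", encoding="utf-8")
        links_file = str(links_path)

    spec_dict = {k: list(v) if isinstance(v, tuple) else v
                 for k, v in asdict(spec).items()}
    manifest = {
        "spec": spec_dict,
        "sets": manifest_sets,
        "links_file": links_file,
    }
    manifest_file = outdir / "manifest.json"
    manifest_file.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    return {
        "chromosome_files": chromosome_files,
        "annotation_files": annotation_files,
        "links_file": links_file,
        "manifest_file": str(manifest_file),
        "manifest": manifest,
    }
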