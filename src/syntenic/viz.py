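"""Deterministic SVG renderers: dotplot, chromosome painting, synteny map.

All three outputs are SVG 1.1 (vector, zoomable).  Element coordinates are
affine functions of gene rank (or nucleotide position for the painting when
coordinates exist), so tests can parse a file and invert positions.  Hover
labels are embedded as ``<title>`` children — the static counterpart of an
interactive pop-up.  Rendering identical inputs with a fixed spec yields
byte-identical files.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .genome_io import Genome
from .homology import HomologyPair
from .synteny import BreakpointRegion, SyntenyBlock

MARGIN = 40.0
TRACK_H = 14.0
CHROM_GAP_UNITS = 5  # blank rank units between chromosomes on one axis


def default_palette(n: int) -> list[str]:
    """Fixed chromosome palette (tab20 order), reproducible across runs."""
    import matplotlib
    from matplotlib import colors as mcolors

    cmap = matplotlib.colormaps["tab20"]
    return [mcolors.to_hex(cmap(i % 20)) for i in range(n)]


@dataclass
class RenderSpec:
    """Where and how to draw one image."""

    path: str
    kind: str = "dotplot"  # dotplot | painting | map
    scale: float = 2.0  # drawing units per rank (or per kilobase)
    colors: Optional[dict[str, str]] = None
    tooltip: bool = True

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.kind not in ("dotplot", "painting", "map"):
            raise ValueError(f"unknown image kind {self.kind!r}")


def _chrom_colors(genome: Genome, spec: RenderSpec) -> dict[str, str]:
    if spec.colors:
        return spec.colors
    chroms = list(genome.chromosomes)
    return dict(zip(chroms, default_palette(len(chroms))))


def _axis_offsets(genome: Genome) -> tuple[dict[str, int], int]:
    """Cumulative rank offset of each chromosome along one axis."""
    offsets: dict[str, int] = {}
    pos = 0
    for chrom, genes in genome.chromosomes.items():
        offsets[chrom] = pos
        pos += len(genes) + CHROM_GAP_UNITS
    return offsets, max(pos - CHROM_GAP_UNITS, 1)


def _svg_root(width: float, height: float) -> ET.Element:
    return ET.Element("svg", {
        "xmlns": "http://www.w3.org/2000/svg", "version": "1.1",
        "width": f"{width:.1f}", "height": f"{height:.1f}",
        "viewBox": f"0 0 {width:.1f} {height:.1f}"})


def _write(root: ET.Element, path: str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = ET.tostring(root, encoding="unicode")
    path.write_text('<?xml version="1.0" encoding="UTF-8"?>\n' + data + "\n")
    return path


def _title(parent: ET.Element, text: str, spec: RenderSpec) -> None:
    if spec.tooltip:
        ET.SubElement(parent, "title").text = text


def render_dotplot(pairs: list[HomologyPair], genomes: tuple[Genome, Genome],
                   spec: RenderSpec) -> Path:
    """One mark per homolog pair at (rank in A, rank in B).

    Chromosome boundaries are drawn as gridlines; the mark count equals the
    pair count.
    """
    ga, gb = genomes
    off_a, len_a = _axis_offsets(ga)
    off_b, len_b = _axis_offsets(gb)
    s = spec.scale
    width = 2 * MARGIN + len_a * s
    height = 2 * MARGIN + len_b * s
    root = _svg_root(width, height)
    grid = ET.SubElement(root, "g", {"class": "grid", "stroke": "#bbbbbb",
                                     "stroke-width": "0.5"})
    for chrom, off in off_a.items():
        x = MARGIN + off * s
        ET.SubElement(grid, "line", {
            "x1": f"{x:.2f}", "y1": f"{MARGIN:.2f}",
            "x2": f"{x:.2f}", "y2": f"{height - MARGIN:.2f}"})
        lbl = ET.SubElement(root, "text", {
            "x": f"{x:.2f}", "y": f"{MARGIN - 6:.2f}", "font-size": "9"})
        lbl.text = chrom
    for chrom, off in off_b.items():
        y = MARGIN + off * s
        ET.SubElement(grid, "line", {
            "x1": f"{MARGIN:.2f}", "y1": f"{y:.2f}",
            "x2": f"{width - MARGIN:.2f}", "y2": f"{y:.2f}"})
        lbl = ET.SubElement(root, "text", {
            "x": "4", "y": f"{y:.2f}", "font-size": "9"})
        lbl.text = chrom
    marks = ET.SubElement(root, "g", {"class": "marks"})
    for p in pairs:
        x = MARGIN + (off_a[p.gene_a.chromosome] + p.gene_a.rank) * s
        y = MARGIN + (off_b[p.gene_b.chromosome] + p.gene_b.rank) * s
        c = ET.SubElement(marks, "circle", {
            "class": f"homolog {p.kind.lower()}",
            "cx": f"{x:.2f}", "cy": f"{y:.2f}", "r": f"{max(s / 2, 1.0):.2f}",
            "fill": "#d62728" if p.kind == "RBH" else "#1f77b4"})
        _title(c, f"{p.gene_a.id} - {p.gene_b.id}", spec)
    return _write(root, spec.path)


def render_painting(blocks: list[SyntenyBlock], genomes: tuple[Genome, Genome],
                    spec: RenderSpec) -> Path:
    """Reference chromosomes as bars segmented and colored by partner chromosome."""
    ga, gb = genomes
    colors = _chrom_colors(gb, spec)
    s = spec.scale
    rows = list(ga.chromosomes)
    width = 2 * MARGIN + max(
        (len(g) for g in ga.chromosomes.values()), default=1) * s
    height = 2 * MARGIN + len(rows) * 3 * TRACK_H
    root = _svg_root(width, height)
    for r, chrom in enumerate(rows):
        genes = ga.chromosomes[chrom]
        y = MARGIN + r * 3 * TRACK_H
        bar = ET.SubElement(root, "rect", {
            "class": "chromosome", "x": f"{MARGIN:.2f}", "y": f"{y:.2f}",
            "width": f"{len(genes) * s:.2f}", "height": f"{TRACK_H:.2f}",
            "fill": "#eeeeee", "stroke": "#555555"})
        _title(bar, f"{ga.id} {chrom}", spec)
        lbl = ET.SubElement(root, "text", {
            "x": "4", "y": f"{y + TRACK_H - 3:.2f}", "font-size": "9"})
        lbl.text = chrom
        for b in sorted(blocks, key=lambda b: b.id):
            if ga.id not in (b.genome_id_a, b.genome_id_b) \
                    or b.chrom_on(ga.id) != chrom:
                continue
            lo, hi = b.span_on(ga.id)
            partner = b.chrom_b if b.genome_id_a == ga.id else b.chrom_a
            seg = ET.SubElement(root, "rect", {
                "class": "block-segment",
                "x": f"{MARGIN + lo * s:.2f}", "y": f"{y:.2f}",
                "width": f"{(hi - lo + 1) * s:.2f}",
                "height": f"{TRACK_H:.2f}",
                "fill": colors.get(partner, "#999999")})
            _title(seg, f"{b.id}: {chrom} ~ {partner}", spec)
        cen = ga.centromeres.get(chrom)
        if cen is not None:
            # centromere given in nt; place proportionally along the bar
            clen = ga.chromosome_nt_length(chrom) or 1
            x = MARGIN + (cen / clen) * len(genes) * s
            ET.SubElement(root, "circle", {
                "class": "centromere", "cx": f"{x:.2f}",
                "cy": f"{y + TRACK_H / 2:.2f}", "r": "4", "fill": "black"})
    return _write(root, spec.path)


_FEATURE_GLYPH_POINTS = "0,6 3,0 6,6"  # upward triangle


def render_synteny_map(blocks: list[SyntenyBlock],
                       breakpoints: list[BreakpointRegion],
                       genomes: tuple[Genome, Genome],
                       spec: RenderSpec) -> Path:
    """Two parallel chromosome tracks with per-pair connectors.

    Connector class encodes relative orientation (``parallel`` for
    same-strand pairs, ``crossing`` for opposite strands); breakpoint
    regions show their genes (rectangles) and features (triangles), each
    carrying its name as an embedded label.
    """
    ga, gb = genomes
    off_a, len_a = _axis_offsets(ga)
    off_b, len_b = _axis_offsets(gb)
    s = spec.scale
    width = 2 * MARGIN + max(len_a, len_b) * s
    y_a = MARGIN + TRACK_H
    y_b = y_a + 140.0
    root = _svg_root(width, y_b + TRACK_H + MARGIN)

    def track(genome: Genome, offsets: dict[str, int], y: float) -> None:
        for chrom, genes in genome.chromosomes.items():
            x0 = MARGIN + offsets[chrom] * s
            bar = ET.SubElement(root, "rect", {
                "class": "chromosome", "x": f"{x0:.2f}", "y": f"{y:.2f}",
                "width": f"{len(genes) * s:.2f}", "height": f"{TRACK_H:.2f}",
                "fill": "#f5f5f5", "stroke": "#333333"})
            _title(bar, f"{genome.id} {chrom} ({len(genes)} genes)", spec)

    track(ga, off_a, y_a)
    track(gb, off_b, y_b)

    conns = ET.SubElement(root, "g", {"class": "connectors"})
    for b in sorted(blocks, key=lambda b: b.id):
        for p in b.member_pairs():
            xa = MARGIN + (off_a[p.gene_a.chromosome] + p.gene_a.rank) * s
            xb = MARGIN + (off_b[p.gene_b.chromosome] + p.gene_b.rank) * s
            sa = p.gene_a.strand if p.gene_a.strand in "+-" else "+"
            sb = p.gene_b.strand if p.gene_b.strand in "+-" else "+"
            cls = "parallel" if sa == sb else "crossing"
            el = ET.SubElement(conns, "line", {
                "class": f"connector {cls} {p.kind.lower()}",
                "x1": f"{xa:.2f}", "y1": f"{y_a + TRACK_H:.2f}",
                "x2": f"{xb:.2f}", "y2": f"{y_b:.2f}",
                "stroke": "#d62728" if p.kind == "RBH" else "#1f77b4",
                "stroke-dasharray": "none" if cls == "parallel" else "4,2"})
            _title(el, f"{p.gene_a.id} - {p.gene_b.id} ({p.kind}, {cls})", spec)

    glyphs = ET.SubElement(root, "g", {"class": "breakpoints"})
    by_genome = {ga.id: (ga, off_a, y_a - TRACK_H),
                 gb.id: (gb, off_b, y_b + TRACK_H + 2)}
    for region in breakpoints:
        if region.genome_id not in by_genome:
            continue
        genome, offsets, y = by_genome[region.genome_id]
        if region.chromosome not in offsets:
            continue
        group = ET.SubElement(glyphs, "g", {
            "class": "breakpoint-region",
            "data-left": region.left_block, "data-right": region.right_block})
        for gid in region.gene_ids:
            gene = genome[gid]
            x = MARGIN + (offsets[region.chromosome] + gene.rank) * s
            el = ET.SubElement(group, "rect", {
                "class": "breakpoint-gene", "x": f"{x - 2:.2f}",
                "y": f"{y:.2f}", "width": "4", "height": "6",
                "fill": "#444444"})
            _title(el, gid, spec)
        for fid in region.feature_ids:
            feat = next(f for f in genome.features if f.id == fid)
            clen = genome.chromosome_nt_length(region.chromosome) or 1
            n = len(genome.chromosomes[region.chromosome])
            x = MARGIN + (offsets[region.chromosome]
                          + (feat.start / clen) * n) * s
            el = ET.SubElement(group, "polygon", {
                "class": f"breakpoint-feature {feat.kind}",
                "points": _FEATURE_GLYPH_POINTS,
                "transform": f"translate({x - 3:.2f},{y + 7:.2f})",
                "fill": "#2ca02c"})
            _title(el, f"{fid} ({feat.kind})", spec)
    return _write(root, spec.path)
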