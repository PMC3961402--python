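"""Synteny-block reconstruction: anchor chaining, completion, breakpoints.

Blocks are built in two passes.  First, reciprocal best hits are chained
into blocks under the Δ1 stringency: two RBH on the same chromosome pair
are linked when strictly fewer than Δ1 RBH-genes lie between them in each
genome (counting only RBH-genes, so any number of non-RBH insertions is
tolerated), and blocks are the connected components of that relation with
at least ``min_anchors`` members.  Second, each block is completed with
non-RBH homologs lying within Δ2 genes (all genes counted this time) of one
of its anchors in both genomes.  When a single Δ is supplied it sets both
Δ1 and Δ2.

Breakpoint regions are the intervals left between consecutive blocks on
each chromosome, carrying the genes and annotated features they contain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from scipy.stats import kendalltau

from .genome_io import Gene, Genome
from .homology import NONRBH, RBH, AlignmentParams, HomologyPair, test_nonrbh_homology


@dataclass(frozen=True)
class SyntenyParams:
    """Block-reconstruction stringency parameters.

    ``delta1`` governs anchor chaining (intervening RBH-genes), ``delta2``
    the completion reach (intervening genes of any kind); both default to
    the single Δ = 5 used for standard runs.
    """

    delta1: int = 5
    delta2: Optional[int] = None
    min_anchors: int = 2

    def __post_init__(self) -> None:
        if self.delta1 < 1:
            raise ValueError("delta1 must be >= 1")
        if self.delta2 is not None and self.delta2 < 1:
            raise ValueError("delta2 must be >= 1")
        if self.min_anchors < 2:
            raise ValueError("min_anchors must be >= 2")

    @property
    def effective_delta2(self) -> int:
        return self.delta1 if self.delta2 is None else self.delta2

    @classmethod
    def single_delta(cls, delta: int, min_anchors: int = 2) -> "SyntenyParams":
        return cls(delta1=delta, delta2=None, min_anchors=min_anchors)


@dataclass
class Anchor:
    """A syntenic RBH with its positions in both rank systems.

    ``rank_*`` is the position among all genes of the chromosome,
    ``rbh_rank_*`` the position among RBH-genes only — the coordinate the
    Δ1 chain is measured in.
    """

    pair: HomologyPair
    rank_a: int
    rank_b: int
    rbh_rank_a: int
    rbh_rank_b: int


@dataclass
class SyntenyBlock:
    """A chained run of RBH anchors plus its non-RBH completions."""

    id: str
    genome_id_a: str
    genome_id_b: str
    chrom_a: str
    chrom_b: str
    anchors: list[Anchor]
    completions: list[HomologyPair] = field(default_factory=list)
    span_a: tuple[int, int] = (0, 0)
    span_b: tuple[int, int] = (0, 0)
    nt_span_a: Optional[tuple[int, int]] = None
    nt_span_b: Optional[tuple[int, int]] = None
    orientation: int = 0

    def member_pairs(self) -> list[HomologyPair]:
        return [a.pair for a in self.anchors] + list(self.completions)

    def genes_a(self) -> list[Gene]:
        return [p.gene_a for p in self.member_pairs()]

    def genes_b(self) -> list[Gene]:
        return [p.gene_b for p in self.member_pairs()]

    def span_on(self, genome_id: str) -> tuple[int, int]:
        if genome_id == self.genome_id_a:
            return self.span_a
        if genome_id == self.genome_id_b:
            return self.span_b
        raise KeyError(genome_id)

    def chrom_on(self, genome_id: str) -> str:
        return self.chrom_a if genome_id == self.genome_id_a else self.chrom_b


@dataclass
class BreakpointRegion:
    """Interval between two consecutive synteny blocks on one chromosome."""

    genome_id: str
    chromosome: str
    left_block: str
    right_block: str
    gene_ids: list[str]
    feature_ids: list[str]
    length_genes: int
    length_nt: Optional[int] = None
    rank_interval: tuple[int, int] = (0, 0)  # ranks strictly inside the gap


CHROM_START = "CHR_START"
CHROM_END = "CHR_END"


def _rbh_ranks(rbh: Iterable[HomologyPair], genome: Genome,
               side: str) -> dict[str, int]:
    """Position of each RBH-gene among the RBH-genes of its chromosome."""
    per_chrom: dict[str, list[tuple[int, str]]] = {}
    for p in rbh:
        g = p.gene_a if side == "a" else p.gene_b
        if g.id not in genome:
            raise ValueError(f"RBH pair references unknown gene {g.id!r}")
        per_chrom.setdefault(g.chromosome, []).append((g.rank, g.id))
    out: dict[str, int] = {}
    for chrom, entries in per_chrom.items():
        entries.sort()
        for i, (_, gid) in enumerate(entries):
            out[gid] = i
    return out


def make_anchors(rbh: list[HomologyPair], genome_a: Genome,
                 genome_b: Genome) -> list[Anchor]:
    ranks_a = _rbh_ranks(rbh, genome_a, "a")
    ranks_b = _rbh_ranks(rbh, genome_b, "b")
    return [Anchor(pair=p, rank_a=p.gene_a.rank, rank_b=p.gene_b.rank,
                   rbh_rank_a=ranks_a[p.gene_a.id], rbh_rank_b=ranks_b[p.gene_b.id])
            for p in rbh]


def chain_anchors(rbh: list[HomologyPair], genome_a: Genome, genome_b: Genome,
                  delta1: int) -> list[list[Anchor]]:
    """Partition RBH pairs into Δ1-synteny connected components.

    Two RBH are linked when they share both chromosomes and strictly fewer
    than ``delta1`` RBH-genes lie between their genes in each genome.
    Components are returned sorted by (chrom_a, first rank_a) with their
    anchors in ascending rank_a order.
    """
    anchors = make_anchors(rbh, genome_a, genome_b)
    parent = list(range(len(anchors)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    groups: dict[tuple[str, str], list[int]] = {}
    for i, a in enumerate(anchors):
        groups.setdefault((a.pair.gene_a.chromosome, a.pair.gene_b.chromosome),
                          []).append(i)
    for idxs in groups.values():
        idxs.sort(key=lambda i: anchors[i].rbh_rank_a)
        for u in range(len(idxs)):
            au = anchors[idxs[u]]
            for v in range(u + 1, len(idxs)):
                av = anchors[idxs[v]]
                if av.rbh_rank_a - au.rbh_rank_a > delta1:
                    break  # sorted: every later v is even farther in A
                if abs(av.rbh_rank_b - au.rbh_rank_b) <= delta1:
                    union(idxs[u], idxs[v])

    comps: dict[int, list[Anchor]] = {}
    for i, a in enumerate(anchors):
        comps.setdefault(find(i), []).append(a)
    out = [sorted(c, key=lambda a: a.rank_a) for c in comps.values()]
    out.sort(key=lambda c: (c[0].pair.gene_a.chromosome, c[0].rank_a,
                            c[0].pair.gene_b.chromosome))
    return out


def block_orientation(block: SyntenyBlock) -> int:
    """Sign of the Kendall rank correlation of anchor positions."""
    xs = [a.rank_a for a in block.anchors]
    ys = [a.rank_b for a in block.anchors]
    tau = kendalltau(xs, ys).statistic
    if tau != tau or tau == 0:  # NaN (degenerate) or exactly zero
        return 0
    return 1 if tau > 0 else -1


def _update_spans(block: SyntenyBlock) -> None:
    ga, gb = block.genes_a(), block.genes_b()
    block.span_a = (min(g.rank for g in ga), max(g.rank for g in ga))
    block.span_b = (min(g.rank for g in gb), max(g.rank for g in gb))

    def nt_span(genes: list[Gene]) -> Optional[tuple[int, int]]:
        ss = [g.start for g in genes if g.start is not None]
        es = [g.end for g in genes if g.end is not None]
        return (min(ss), max(es)) if ss and es else None

    block.nt_span_a = nt_span(ga)
    block.nt_span_b = nt_span(gb)


def build_blocks(components: list[list[Anchor]],
                 params: SyntenyParams) -> list[SyntenyBlock]:
    """Emit one block per component with at least ``min_anchors`` anchors.

    Anchors of emitted blocks (and the RBH of discarded small components)
    get their ``syntenic`` flag set, so the non-syntenic RBH census falls
    out of the pair list.
    """
    blocks: list[SyntenyBlock] = []
    n = 0
    for comp in components:
        if len(comp) < params.min_anchors:
            for a in comp:
                a.pair.syntenic = False
            continue
        n += 1
        pa, pb = comp[0].pair.gene_a, comp[0].pair.gene_b
        block = SyntenyBlock(id=f"B{n:05d}", genome_id_a=pa.genome_id,
                             genome_id_b=pb.genome_id, chrom_a=pa.chromosome,
                             chrom_b=pb.chromosome, anchors=list(comp))
        for a in comp:
            a.pair.syntenic = True
        _update_spans(block)
        block.orientation = block_orientation(block)
        blocks.append(block)
    return blocks


def complete_block(block: SyntenyBlock, genome_a: Genome, genome_b: Genome,
                   delta2: int,
                   tester: Callable[[str, str], tuple[bool, object]],
                   rbh_gene_ids_a: set[str], rbh_gene_ids_b: set[str],
                   _cache: Optional[dict] = None) -> SyntenyBlock:
    """Add non-RBH homologs lying within Δ2 genes of an anchor in both genomes.

    Candidate pairs must sit on the block's chromosome pair, at strictly
    fewer than ``delta2`` genes from the same anchor in each genome, and at
    least one member must not be an RBH-gene.  Pairs passing ``tester`` are
    appended to ``completions`` (one gene may complete several blocks, and
    may pair with several partners within one block); spans are extended to
    cover them.
    """
    genes_chrom_a = genome_a.chromosomes[block.chrom_a]
    genes_chrom_b = genome_b.chromosomes[block.chrom_b]
    anchor_keys = {a.pair.key for a in block.anchors}
    cache = _cache if _cache is not None else {}
    candidates: dict[tuple[str, str], tuple[Gene, Gene]] = {}
    for anchor in block.anchors:
        lo_a = max(0, anchor.rank_a - delta2 + 1)
        hi_a = min(len(genes_chrom_a), anchor.rank_a + delta2)
        lo_b = max(0, anchor.rank_b - delta2 + 1)
        hi_b = min(len(genes_chrom_b), anchor.rank_b + delta2)
        for ga in genes_chrom_a[lo_a:hi_a]:
            a_is_rbh = ga.id in rbh_gene_ids_a
            for gb in genes_chrom_b[lo_b:hi_b]:
                if a_is_rbh and gb.id in rbh_gene_ids_b:
                    continue
                key = (ga.id, gb.id)
                if key in anchor_keys or key in candidates:
                    continue
                candidates[key] = (ga, gb)
    for key in sorted(candidates):
        ga, gb = candidates[key]
        hit = cache.get(key)
        if hit is None:
            hit = tester(ga.protein, gb.protein)
            cache[key] = hit
        passes, result = hit
        if passes:
            block.completions.append(HomologyPair(
                gene_a=ga, gene_b=gb, kind=NONRBH, result=result, syntenic=True))
    if block.completions:
        _update_spans(block)
    return block


def reconstruct_blocks(rbh: list[HomologyPair], genome_a: Genome,
                       genome_b: Genome, params: SyntenyParams,
                       align_params: Optional[AlignmentParams] = None
                       ) -> list[SyntenyBlock]:
    """Full block reconstruction: chain, filter, complete."""
    if align_params is None:
        align_params = AlignmentParams()
    components = chain_anchors(rbh, genome_a, genome_b, params.delta1)
    blocks = build_blocks(components, params)
    rbh_a = {p.gene_a.id for p in rbh}
    rbh_b = {p.gene_b.id for p in rbh}
    tester = lambda pa, pb: test_nonrbh_homology(pa, pb, align_params)
    cache: dict = {}
    for block in blocks:
        complete_block(block, genome_a, genome_b, params.effective_delta2,
                       tester, rbh_a, rbh_b, _cache=cache)
    return blocks


def make_block(block_id: str, genome_a: Genome, genome_b: Genome,
               anchor_pairs: list[HomologyPair],
               completion_pairs: list[HomologyPair]) -> SyntenyBlock:
    """Rebuild a block object from serialized member pairs."""
    anchors = make_anchors(anchor_pairs, genome_a, genome_b)
    anchors.sort(key=lambda a: a.rank_a)
    pa, pb = anchors[0].pair.gene_a, anchors[0].pair.gene_b
    block = SyntenyBlock(id=block_id, genome_id_a=pa.genome_id,
                         genome_id_b=pb.genome_id, chrom_a=pa.chromosome,
                         chrom_b=pb.chromosome, anchors=anchors,
                         completions=list(completion_pairs))
    _update_spans(block)
    block.orientation = block_orientation(block)
    return block


def extract_breakpoints(blocks: list[SyntenyBlock],
                        genome: Genome) -> list[BreakpointRegion]:
    """Breakpoint regions between consecutive blocks on each chromosome.

    Overlapping block spans are merged before gap extraction; a gap is
    emitted between consecutive merged spans and between chromosome ends
    and the terminal blocks (zero-length gaps included).  Each region lists
    the genes strictly between the flanking spans and the features inside
    the nucleotide gap when coordinates exist.
    """
    spans_per_chrom: dict[str, list[tuple[int, int, str, Optional[int], Optional[int]]]] = {}
    for b in blocks:
        if genome.id not in (b.genome_id_a, b.genome_id_b):
            raise ValueError(f"block {b.id} does not involve genome {genome.id!r}")
        chrom = b.chrom_on(genome.id)
        lo, hi = b.span_on(genome.id)
        nt = b.nt_span_a if genome.id == b.genome_id_a else b.nt_span_b
        spans_per_chrom.setdefault(chrom, []).append(
            (lo, hi, b.id, nt[0] if nt else None, nt[1] if nt else None))

    regions: list[BreakpointRegion] = []
    for chrom, genes in genome.chromosomes.items():
        spans = sorted(spans_per_chrom.get(chrom, []))
        # merge overlapping / adjacent-overlapping spans into disjoint runs
        merged: list[list] = []
        for lo, hi, bid, nlo, nhi in spans:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
                merged[-1][2] = bid  # rightmost block names the edge
                if nhi is not None:
                    merged[-1][4] = max(merged[-1][4] or nhi, nhi)
            else:
                merged.append([lo, hi, bid, nlo, nhi, bid])
        bounds = []
        left_name = CHROM_START
        left_nt = 1  # nucleotide coordinates are 1-based
        prev_hi = -1
        for lo, hi, bid_r, nlo, nhi, bid_l in merged:
            bounds.append((prev_hi + 1, lo - 1, left_name, bid_l, left_nt,
                           nlo - 1 if nlo is not None else None))
            left_name, prev_hi = bid_r, hi
            left_nt = nhi + 1 if nhi is not None else None
        chrom_len = genome.chromosome_nt_length(chrom)
        bounds.append((prev_hi + 1, len(genes) - 1, left_name, CHROM_END,
                       left_nt, chrom_len))
        for lo, hi, lname, rname, ntlo, nthi in bounds:
            gene_ids = [g.id for g in genes[lo:hi + 1]]
            feats: list[str] = []
            length_nt = None
            if ntlo is not None and nthi is not None:
                length_nt = max(0, nthi - ntlo + 1)
                feats = [f.id for f in genome.features
                         if f.chromosome == chrom and f.start >= ntlo
                         and f.end <= nthi]
            regions.append(BreakpointRegion(
                genome_id=genome.id, chromosome=chrom, left_block=lname,
                right_block=rname, gene_ids=gene_ids, feature_ids=feats,
                length_genes=len(gene_ids), length_nt=length_nt,
                rank_interval=(lo, hi)))
    return regions
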