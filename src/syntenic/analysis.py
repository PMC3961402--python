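"""Per-comparison statistics, cross-tool congruence scanning and the
direct-neighbor analysis of two-anchor blocks.

The congruence scan compares 2-3 block reconstructions (e.g. from different
tools) projected on a common reference genome: wherever reference intervals
of two tools overlap, the tools are *congruent* if their partner-genome
intervals overlap too; with self-overlapping block sets a region counts as
congruent when at least one of the overlapping blocks is.  Pairwise
verdicts are intersected into maximal regions of constant class.

The neighbor-probability model quantifies how likely two homolog pairs are
to land at adjacent positions in both genomes purely by chance — the null
against which two-anchor blocks of direct neighbors are judged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome_io import Genome
from .homology import RBH, HomologyPair
from .synteny import BreakpointRegion, SyntenyBlock


@dataclass
class PairwiseStats:
    """Summary statistics of one pairwise synteny reconstruction."""

    n_blocks: int
    n_syntenic_homologs: int
    n_syntenic_homologs_dedup: int
    n_syntenic_rbh: int
    pct_genes_in_synteny: float
    pct_genome_in_blocks: Optional[float]
    pct_ranks_in_blocks: float
    mean_ortholog_similarity: Optional[float]
    mean_breakpoint_len_nt: Optional[float]
    mean_breakpoint_len_genes: Optional[float]
    mean_genes_per_block: Optional[float]
    pct_adjacent_blocks_same_chrom: Optional[float]


def _dedup_count(block: SyntenyBlock) -> int:
    """Relationships kept when each gene may appear once per block."""
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    n = 0
    for p in block.member_pairs():
        if p.gene_a.id in seen_a or p.gene_b.id in seen_b:
            continue
        seen_a.add(p.gene_a.id)
        seen_b.add(p.gene_b.id)
        n += 1
    return n


def compute_stats(blocks: list[SyntenyBlock],
                  breakpoints: list[BreakpointRegion],
                  genomes: tuple[Genome, Genome],
                  rbh: list[HomologyPair]) -> PairwiseStats:
    """Compute every pairwise summary field; means of empty sets are None.

    Genome-fraction fields are computed on the first genome of ``genomes``
    (the reference); gene fractions pool both genomes.
    """
    ga, gb = genomes
    n_blocks = len(blocks)
    n_hom = sum(len(b.member_pairs()) for b in blocks)
    n_dedup = sum(_dedup_count(b) for b in blocks)
    n_syntenic_rbh = sum(len(b.anchors) for b in blocks)

    in_blocks_a: set[str] = set()
    in_blocks_b: set[str] = set()
    sims: list[float] = []
    for b in blocks:
        for p in b.member_pairs():
            in_blocks_a.add(p.gene_a.id)
            in_blocks_b.add(p.gene_b.id)
            sims.append(p.result.similarity_pct)
    total_genes = ga.n_genes + gb.n_genes
    pct_genes = 100.0 * (len(in_blocks_a) + len(in_blocks_b)) / total_genes \
        if total_genes else 0.0

    # nucleotide coverage on the reference genome
    pct_nt: Optional[float] = None
    total_nt = 0
    covered_nt = 0
    have_nt = True
    for chrom in ga.chromosomes:
        clen = ga.chromosome_nt_length(chrom)
        if clen is None:
            have_nt = False
            break
        total_nt += clen
        ivals = []
        for b in blocks:
            if b.genome_id_a == ga.id and b.chrom_a == chrom and b.nt_span_a:
                ivals.append(b.nt_span_a)
            elif b.genome_id_b == ga.id and b.chrom_b == chrom and b.nt_span_b:
                ivals.append(b.nt_span_b)
        covered_nt += _union_length(ivals)
    if have_nt and total_nt:
        pct_nt = 100.0 * covered_nt / total_nt
    # rank coverage on the reference genome
    covered_ranks = 0
    for chrom, genes in ga.chromosomes.items():
        ivals = [b.span_on(ga.id) for b in blocks if b.chrom_on(ga.id) == chrom
                 and ga.id in (b.genome_id_a, b.genome_id_b)]
        covered_ranks += _union_length(ivals)
    pct_ranks = 100.0 * covered_ranks / ga.n_genes if ga.n_genes else 0.0

    bp_nt = [r.length_nt for r in breakpoints if r.length_nt is not None]
    bp_genes = [r.length_genes for r in breakpoints]
    genes_per_block = [(len({p.gene_a.id for p in b.member_pairs()})
                        + len({p.gene_b.id for p in b.member_pairs()})) / 2
                       for b in blocks]

    # adjacent-block partner-chromosome conservation, on the reference
    def partner_chrom(b: SyntenyBlock) -> str:
        return b.chrom_b if b.genome_id_a == ga.id else b.chrom_a

    same = 0
    adjacent = 0
    for chrom in ga.chromosomes:
        chrom_blocks = sorted(
            (b for b in blocks if b.chrom_on(ga.id) == chrom),
            key=lambda b: b.span_on(ga.id))
        for left, right in zip(chrom_blocks, chrom_blocks[1:]):
            adjacent += 1
            same += partner_chrom(left) == partner_chrom(right)
    return PairwiseStats(
        n_blocks=n_blocks,
        n_syntenic_homologs=n_hom,
        n_syntenic_homologs_dedup=n_dedup,
        n_syntenic_rbh=n_syntenic_rbh,
        pct_genes_in_synteny=pct_genes,
        pct_genome_in_blocks=pct_nt,
        pct_ranks_in_blocks=pct_ranks,
        mean_ortholog_similarity=float(np.mean(sims)) if sims else None,
        mean_breakpoint_len_nt=float(np.mean(bp_nt)) if bp_nt else None,
        mean_breakpoint_len_genes=float(np.mean(bp_genes)) if bp_genes else None,
        mean_genes_per_block=float(np.mean(genes_per_block)) if genes_per_block else None,
        pct_adjacent_blocks_same_chrom=100.0 * same / adjacent if adjacent else None,
    )


def _union_length(intervals: Sequence[tuple[int, int]]) -> int:
    """Total length of a union of closed integer intervals."""
    total = 0
    hi_prev = None
    for lo, hi in sorted(intervals):
        if hi_prev is not None and lo <= hi_prev:
            lo = hi_prev + 1
        if hi >= lo:
            total += hi - lo + 1
            hi_prev = hi if hi_prev is None else max(hi_prev, hi)
    return total


# ---------------------------------------------------------------------------
# congruence scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToolBlock:
    """One tool's block projected on the reference and target genomes."""

    tool: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    tgt_chrom: str
    tgt_start: int
    tgt_end: int

    def __post_init__(self) -> None:
        if self.ref_end < self.ref_start or self.tgt_end < self.tgt_start:
            raise ValueError(f"malformed interval in block of {self.tool!r}")


@dataclass
class CongruenceRegion:
    chromosome: str
    start: int
    end: int
    covered_by: frozenset[str]
    congruent_pairs: frozenset[frozenset[str]]
    congruence_class: str
    detail: str
    included_flag: bool


def _coarse_class(covered: frozenset[str], congruent: frozenset[frozenset[str]],
                  n_tools: int) -> str:
    if not covered:
        return "uncovered"
    if len(covered) == 1:
        return "single-tool"
    n_pairs = len(covered) * (len(covered) - 1) // 2
    if len(congruent) == n_pairs:
        return ("all-three-congruent"
                if len(covered) == 3 and n_tools == 3 else "pair-congruent")
    if congruent:
        return "pair-congruent"
    return "covered-but-discordant"


def _tgt_overlap(b1: ToolBlock, b2: ToolBlock) -> bool:
    return (b1.tgt_chrom == b2.tgt_chrom
            and b1.tgt_start <= b2.tgt_end and b2.tgt_start <= b1.tgt_end)


def congruence_scan(block_sets: dict[str, list[ToolBlock]]
                    ) -> list[CongruenceRegion]:
    """Classify the reference genome into maximal constant-congruence regions.

    For every pair of tools covering a region the verdict is congruent iff
    some covering block of each maps overlapping target intervals (at least
    one shared nucleotide; with overlapping blocks of one tool, one
    congruent block suffices).  Regions produced only by blocks included
    inside a larger block of their own tool are flagged ``included``.
    """
    tools = sorted(block_sets)
    if not 2 <= len(tools) <= 3:
        raise ValueError("congruence scan compares 2 or 3 block sets")
    # flag blocks contained in a strictly larger block of the same tool
    included_blocks: set[ToolBlock] = set()
    for tool, blist in block_sets.items():
        for b1, b2 in itertools.permutations(blist, 2):
            if (b1.ref_chrom == b2.ref_chrom
                    and b2.ref_start <= b1.ref_start and b1.ref_end <= b2.ref_end
                    and (b1.ref_end - b1.ref_start) < (b2.ref_end - b2.ref_start)):
                included_blocks.add(b1)

    chroms = sorted({b.ref_chrom for bl in block_sets.values() for b in bl})
    regions: list[CongruenceRegion] = []
    for chrom in chroms:
        on_chrom = {t: [b for b in bl if b.ref_chrom == chrom]
                    for t, bl in block_sets.items()}
        cuts = sorted({c for bl in on_chrom.values() for b in bl
                       for c in (b.ref_start, b.ref_end + 1)})
        for lo, nxt in zip(cuts, cuts[1:]):
            hi = nxt - 1
            cover = {t: [b for b in bl if b.ref_start <= lo and hi <= b.ref_end]
                     for t, bl in on_chrom.items()}
            covered = frozenset(t for t, bl in cover.items() if bl)
            if not covered:
                continue  # inter-block gaps are not emitted as regions
            congruent = frozenset(
                frozenset((t1, t2))
                for t1, t2 in itertools.combinations(sorted(covered), 2)
                if any(_tgt_overlap(b1, b2)
                       for b1 in cover[t1] for b2 in cover[t2]))
            included = any(b in included_blocks
                           for bl in cover.values() for b in bl)
            detail = "cov=%s|cong=%s" % (
                "+".join(sorted(covered)) or "-",
                ",".join(sorted("&".join(sorted(p)) for p in congruent)) or "-")
            cls = _coarse_class(covered, congruent, len(tools))
            prev = regions[-1] if regions else None
            if (prev and prev.chromosome == chrom and prev.end == lo - 1
                    and prev.detail == detail and prev.included_flag == included):
                prev.end = hi
            else:
                regions.append(CongruenceRegion(
                    chromosome=chrom, start=lo, end=hi, covered_by=covered,
                    congruent_pairs=congruent, congruence_class=cls,
                    detail=detail, included_flag=included))
    return regions


def venn_summary(regions: list[CongruenceRegion],
                 genome_nt_length: int) -> dict:
    """Percent of the reference genome per congruence class.

    Returned dict maps ``(congruence_class, included_flag)`` to percent of
    ``genome_nt_length``, plus ``("union-covered", None)`` — the share of
    the genome covered by at least one tool, which is at least the largest
    single-tool share (discordant regions are only counted once here).
    """
    out: dict = {}
    union = 0
    for r in regions:
        length = r.end - r.start + 1
        union += length
        key = (r.congruence_class, r.included_flag)
        out[key] = out.get(key, 0) + length
    summary = {k: 100.0 * v / genome_nt_length for k, v in sorted(out.items())}
    summary[("union-covered", None)] = 100.0 * union / genome_nt_length
    return summary


# ---------------------------------------------------------------------------
# two-gene blocks and the direct-neighbor null model
# ---------------------------------------------------------------------------

def count_direct_neighbor_two_gene_blocks(
        blocks: list[SyntenyBlock]) -> tuple[int, int]:
    """Count 2-anchor blocks, and those whose anchors are direct neighbors.

    Direct neighbors = the two genes sit at adjacent all-gene ranks in
    *both* genomes.
    """
    n_two = 0
    n_direct = 0
    for b in blocks:
        if len(b.anchors) != 2:
            continue
        n_two += 1
        a1, a2 = b.anchors
        if (abs(a1.rank_a - a2.rank_a) == 1 and abs(a1.rank_b - a2.rank_b) == 1):
            n_direct += 1
    return n_two, n_direct


@dataclass(frozen=True)
class NeighborProbModel:
    """Gene counts and chromosome sizes of the two genomes under the null."""

    n_genes_1: int
    n_genes_2: int
    chrom_sizes_1: tuple[int, ...]
    chrom_sizes_2: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_genes_1 < 2 or self.n_genes_2 < 2:
            raise ValueError("need at least 2 genes per genome")
        if sum(self.chrom_sizes_1) != self.n_genes_1 \
                or sum(self.chrom_sizes_2) != self.n_genes_2:
            raise ValueError("chromosome sizes must sum to the gene count")


def _adjacency_probability(n: int, sizes: tuple[int, ...]) -> float:
    # P(two specific genes adjacent) = sum over chromosomes of
    # P(both on chromosome j) * P(adjacent | both on j)
    #   = sum_j [c_j (c_j - 1) / (n (n - 1))] * [2 / c_j]
    return sum(2.0 * (c - 1) for c in sizes) / (n * (n - 1))


def neighbor_pair_probability(model: NeighborProbModel) -> float:
    """Chance that two homolog pairs are direct neighbors in both genomes.

    Under independent uniform-random gene orders, the two genes of a pair
    are adjacent in one genome with probability
    ``sum_j 2 (c_j - 1) / (n (n - 1))``; the joint probability is the
    product over the two genomes.  This closed form is a reconstruction
    validated against permutation simulation (see the test suite).
    """
    return (_adjacency_probability(model.n_genes_1, model.chrom_sizes_1)
            * _adjacency_probability(model.n_genes_2, model.chrom_sizes_2))


def simulate_neighbor_pair_probability(model: NeighborProbModel, n_draws: int,
                                       rng: np.random.Generator) -> tuple[float, float]:
    """Monte-Carlo estimate (mean, standard error) of the same probability."""
    # draw positions of the two tracked genes directly: a uniform random
    # placement of all genes induces a uniform random position pair
    # (without replacement) for the two tracked genes
    bounds_1 = np.cumsum((0,) + model.chrom_sizes_1)
    bounds_2 = np.cumsum((0,) + model.chrom_sizes_2)

    def adjacent(n: int, bounds: np.ndarray, k: int) -> np.ndarray:
        p0 = rng.integers(0, n, size=k)
        p1 = rng.integers(0, n - 1, size=k)
        p1 = p1 + (p1 >= p0)  # uniform over positions != p0
        same_chrom = (np.searchsorted(bounds, p0, side="right")
                      == np.searchsorted(bounds, p1, side="right"))
        return (np.abs(p0 - p1) == 1) & same_chrom

    a1 = adjacent(model.n_genes_1, bounds_1, n_draws)
    a2 = adjacent(model.n_genes_2, bounds_2, n_draws)
    both = a1 & a2
    p = both.mean()
    se = np.sqrt(max(p * (1 - p), 1e-300) / n_draws)
    return float(p), float(se)
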