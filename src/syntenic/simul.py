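"""Synthetic genome-pair evolution with known ground truth.

An ancestral genome of random proteins is evolved along two independent
lineages: per-site substitutions (drawn from the background amino-acid
distribution), gene loss, gene gain, tandem duplication, then balanced
rearrangements — inversions (segment reversal with strand flip), reciprocal
translocations, chromosome fusions and fissions.  The generator returns,
besides the two genomes, a :class:`TruthSet` holding the surviving ortholog
matching, the true synteny segmentation (maximal colinear ortholog runs)
and the breakpoint gaps between those runs — the oracle that recovery of
blocks and breakpoints is scored against.

Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .genome_io import Gene, Genome
from .synteny import SyntenyBlock

# Robinson & Robinson style background amino-acid frequencies
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
AA_FREQS = np.array([
    0.0785, 0.0512, 0.0447, 0.0536, 0.0168, 0.0398, 0.0632, 0.0733,
    0.0227, 0.0597, 0.0996, 0.0585, 0.0242, 0.0408, 0.0489, 0.0714,
    0.0567, 0.0113, 0.0303, 0.0681])
AA_FREQS = AA_FREQS / AA_FREQS.sum()

INTERGENE_NT = 200


@dataclass(frozen=True)
class SimParams:
    """Study conditions of a simulated genome pair.

    Defaults describe a moderately diverged pair of 2x500-gene genomes with
    a handful of balanced rearrangements per lineage and no gene turnover.
    ``protein_length`` is a fixed int or an inclusive uniform (min, max).
    """

    n_chromosomes: int = 2
    genes_per_chromosome: Union[int, Sequence[int]] = 500
    protein_length: Union[int, tuple[int, int]] = (100, 500)
    divergence: float = 0.15
    n_inversions: int = 5
    n_translocations: int = 2
    n_fusions: int = 0
    n_fissions: int = 0
    p_gene_loss: float = 0.0
    p_gene_gain: float = 0.0
    p_tandem_dup: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        for p in (self.divergence, self.p_gene_loss, self.p_gene_gain,
                  self.p_tandem_dup):
            if not 0 <= p < 1:
                raise ValueError("probabilities must lie in [0, 1)")

    def chrom_sizes(self) -> list[int]:
        if isinstance(self.genes_per_chromosome, int):
            return [self.genes_per_chromosome] * self.n_chromosomes
        sizes = list(self.genes_per_chromosome)
        if len(sizes) != self.n_chromosomes:
            raise ValueError("genes_per_chromosome length != n_chromosomes")
        return sizes


@dataclass
class TruthSet:
    """Simulator ground truth for one evolved genome pair."""

    ortholog_map: dict[str, str]  # genome-A gene id -> genome-B gene id
    true_breakpoints: dict[str, list[tuple[str, int, int]]]  # genome -> (chrom, left rank, right rank)
    true_blocks: list[dict]
    event_log: list[dict] = field(default_factory=list)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(len(AA_ALPHABET), size=length, p=AA_FREQS)
    return "".join(AA_ALPHABET[i] for i in idx)


def _draw_length(rng: np.random.Generator,
                 spec: Union[int, tuple[int, int]]) -> int:
    if isinstance(spec, int):
        return spec
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


def _layout(genes: list[Gene]) -> None:
    """Assign 1-based nucleotide coordinates along each chromosome."""
    pos: dict[str, int] = {}
    for g in genes:
        start = pos.get(g.chromosome, 1)
        g.start = start
        g.end = start + 3 * len(g.protein) + 2
        pos[g.chromosome] = g.end + 1 + INTERGENE_NT


def simulate_ancestor(params: SimParams,
                      rng: Optional[np.random.Generator] = None) -> Genome:
    """Random ancestral genome; deterministic under ``params.seed``."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    chromosomes: dict[str, list[Gene]] = {}
    gid = 0
    for c, size in enumerate(params.chrom_sizes(), start=1):
        chrom = f"chr{c}"
        genes: list[Gene] = []
        for rank in range(size):
            gid += 1
            genes.append(Gene(
                id=f"g{gid:06d}", genome_id="ancestor", chromosome=chrom,
                rank=rank, protein=_random_protein(
                    rng, _draw_length(rng, params.protein_length)),
                strand="+" if rng.random() < 0.5 else "-"))
        chromosomes[chrom] = genes
    genome = Genome(id="ancestor", chromosomes=chromosomes)
    _layout(list(genome.genes()))
    return genome


class _LineageGene:
    __slots__ = ("anc_id", "protein", "strand")

    def __init__(self, anc_id: Optional[str], protein: str, strand: str):
        self.anc_id = anc_id
        self.protein = protein
        self.strand = strand


def _mutate(rng: np.random.Generator, protein: str, rate: float) -> str:
    if rate == 0:
        return protein
    arr = np.frombuffer(protein.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.shape[0]) < rate
    n = int(hit.sum())
    if n:
        repl = rng.choice(len(AA_ALPHABET), size=n, p=AA_FREQS)
        arr[hit] = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)[repl]
    return arr.tobytes().decode()


def _flip(strand: str) -> str:
    return {"+": "-", "-": "+"}.get(strand, ".")


def _evolve_lineage(ancestor: Genome, params: SimParams,
                    rng: np.random.Generator, prefix: str,
                    event_log: list[dict]) -> dict[str, list[_LineageGene]]:
    chroms: dict[str, list[_LineageGene]] = {}
    n_gain = 0
    n_dup = 0
    for chrom, genes in ancestor.chromosomes.items():
        out: list[_LineageGene] = []
        for g in genes:
            if params.p_gene_loss and rng.random() < params.p_gene_loss:
                event_log.append({"lineage": prefix, "event": "loss",
                                  "gene": g.id, "chromosome": chrom})
                continue
            out.append(_LineageGene(g.id, _mutate(rng, g.protein,
                                                  params.divergence), g.strand))
            if params.p_tandem_dup and rng.random() < params.p_tandem_dup:
                n_dup += 1
                out.append(_LineageGene(
                    None, _mutate(rng, g.protein, params.divergence), g.strand))
                event_log.append({"lineage": prefix, "event": "tandem_dup",
                                  "gene": g.id, "chromosome": chrom})
            if params.p_gene_gain and rng.random() < params.p_gene_gain:
                n_gain += 1
                out.append(_LineageGene(
                    None, _random_protein(
                        rng, _draw_length(rng, params.protein_length)),
                    "+" if rng.random() < 0.5 else "-"))
                event_log.append({"lineage": prefix, "event": "gain",
                                  "chromosome": chrom})
        chroms[chrom] = out

    def pick_chrom(min_genes: int) -> str:
        ok = sorted(c for c, gl in chroms.items() if len(gl) >= min_genes)
        if not ok:
            raise ValueError(
                f"no chromosome with >= {min_genes} genes for rearrangement")
        return ok[int(rng.integers(len(ok)))]

    for _ in range(params.n_inversions):
        chrom = pick_chrom(2)
        gl = chroms[chrom]
        i = int(rng.integers(0, len(gl) - 1))
        j = int(rng.integers(i + 1, len(gl)))
        seg = gl[i:j + 1][::-1]
        for lg in seg:
            lg.strand = _flip(lg.strand)
        chroms[chrom] = gl[:i] + seg + gl[j + 1:]
        event_log.append({"lineage": prefix, "event": "inversion",
                          "chromosome": chrom, "start": i, "end": j})
    for _ in range(params.n_translocations):
        names = sorted(c for c, gl in chroms.items() if len(gl) >= 2)
        if len(names) < 2:
            raise ValueError("reciprocal translocation needs two chromosomes "
                             "with at least 2 genes")
        c1, c2 = rng.choice(len(names), size=2, replace=False)
        c1, c2 = names[int(c1)], names[int(c2)]
        b1 = int(rng.integers(1, len(chroms[c1])))
        b2 = int(rng.integers(1, len(chroms[c2])))
        chroms[c1], chroms[c2] = (chroms[c1][:b1] + chroms[c2][b2:],
                                  chroms[c2][:b2] + chroms[c1][b1:])
        event_log.append({"lineage": prefix, "event": "translocation",
                          "chromosomes": (c1, c2), "breaks": (b1, b2)})
    for _ in range(params.n_fusions):
        names = sorted(chroms)
        if len(names) < 2:
            raise ValueError("fusion needs two chromosomes")
        c1, c2 = rng.choice(len(names), size=2, replace=False)
        c1, c2 = names[int(c1)], names[int(c2)]
        chroms[c1] = chroms[c1] + chroms[c2]
        del chroms[c2]
        event_log.append({"lineage": prefix, "event": "fusion",
                          "chromosomes": (c1, c2)})
    for k in range(params.n_fissions):
        chrom = pick_chrom(2)
        gl = chroms[chrom]
        b = int(rng.integers(1, len(gl)))
        new = f"{chrom}_f{k + 1}"
        chroms[chrom] = gl[:b]
        chroms[new] = gl[b:]
        event_log.append({"lineage": prefix, "event": "fission",
                          "chromosome": chrom, "break": b, "new": new})
    return chroms


def _materialize(chroms: dict[str, list[_LineageGene]], genome_id: str,
                 prefix: str) -> tuple[Genome, dict[str, str]]:
    """Build a Genome from lineage gene lists; returns (genome, anc->id map)."""
    chromosomes: dict[str, list[Gene]] = {}
    anc_to_id: dict[str, str] = {}
    extra = 0
    for chrom in sorted(chroms):
        genes: list[Gene] = []
        for lg in chroms[chrom]:
            if lg.anc_id is not None:
                gid = f"{prefix}{lg.anc_id}"
                anc_to_id[lg.anc_id] = gid
            else:
                extra += 1
                gid = f"{prefix}x{extra:05d}"
            genes.append(Gene(id=gid, genome_id=genome_id, chromosome=chrom,
                              rank=len(genes), protein=lg.protein,
                              strand=lg.strand))
        chromosomes[chrom] = genes
    genome = Genome(id=genome_id, chromosomes=chromosomes)
    _layout(list(genome.genes()))
    return genome, anc_to_id


def _colinear_truth(genome_a: Genome, genome_b: Genome,
                    ortholog_map: dict[str, str]) -> tuple[
                        dict[str, list[tuple[str, int, int]]], list[dict]]:
    """Segment the ortholog matching into maximal colinear runs.

    A run breaks between consecutive orthologs of genome A whenever their
    partners in B are on different chromosomes or are not consecutive
    orthologs there (in either direction).  Returns the breakpoint gaps for
    both genomes and the list of paired run intervals.
    """
    partner = dict(ortholog_map)
    b_members = set(ortholog_map.values())
    b_orank: dict[str, tuple[str, int]] = {}
    b_ranks: dict[str, int] = {}
    for chrom, genes in genome_b.chromosomes.items():
        k = 0
        for g in genes:
            if g.id in b_members:
                b_orank[g.id] = (chrom, k)
                b_ranks[g.id] = g.rank
                k += 1

    breakpoints_a: list[tuple[str, int, int]] = []
    blocks: list[dict] = []
    for chrom, genes in genome_a.chromosomes.items():
        run: list[Gene] = []
        prev: Optional[Gene] = None
        for g in genes:
            if g.id not in partner:
                continue
            if prev is not None:
                pc, pk = b_orank[partner[prev.id]]
                cc, ck = b_orank[partner[g.id]]
                if pc != cc or abs(ck - pk) != 1:
                    breakpoints_a.append((chrom, prev.rank, g.rank))
                    blocks.append(_run_to_block(run, partner, genome_b, b_ranks))
                    run = []
            run.append(g)
            prev = g
        if run:
            blocks.append(_run_to_block(run, partner, genome_b, b_ranks))

    # mirror segmentation on genome B
    inverse = {v: k for k, v in ortholog_map.items()}
    a_pos = {g.id: (g.chromosome, g.rank) for g in genome_a.genes()}
    a_orank: dict[str, tuple[str, int]] = {}
    for chrom, genes in genome_a.chromosomes.items():
        k = 0
        for g in genes:
            if g.id in partner:
                a_orank[g.id] = (chrom, k)
                k += 1
    breakpoints_b: list[tuple[str, int, int]] = []
    for chrom, genes in genome_b.chromosomes.items():
        prev = None
        for g in genes:
            if g.id not in inverse:
                continue
            if prev is not None:
                pc, pk = a_orank[inverse[prev.id]]
                cc, ck = a_orank[inverse[g.id]]
                if pc != cc or abs(ck - pk) != 1:
                    breakpoints_b.append((chrom, prev.rank, g.rank))
            prev = g
    return ({genome_a.id: breakpoints_a, genome_b.id: breakpoints_b}, blocks)


def _run_to_block(run: list[Gene], partner: dict[str, str], genome_b: Genome,
                  b_ranks: dict[str, int]) -> dict:
    branks = [b_ranks[partner[g.id]] for g in run]
    return {"chrom_a": run[0].chromosome,
            "span_a": (run[0].rank, run[-1].rank),
            "chrom_b": genome_b[partner[run[0].id]].chromosome,
            "span_b": (min(branks), max(branks)),
            "n_orthologs": len(run)}


def evolve_pair(ancestor: Genome,
                params: SimParams) -> tuple[Genome, Genome, TruthSet]:
    """Evolve two lineages from the ancestor; returns (A, B, truth).

    Each lineage independently applies substitutions and gene turnover,
    then the configured numbers of inversions, reciprocal translocations,
    fusions and fissions.  The truth set records the surviving ortholog
    matching and the colinearity breakpoints of the final pair.
    """
    rng = np.random.default_rng((params.seed, 1))
    event_log: list[dict] = []
    lin_a = _evolve_lineage(ancestor, params, rng, "A_", event_log)
    lin_b = _evolve_lineage(ancestor, params, rng, "B_", event_log)
    genome_a, anc_a = _materialize(lin_a, "A", "A_")
    genome_b, anc_b = _materialize(lin_b, "B", "B_")
    shared = sorted(set(anc_a) & set(anc_b))
    ortholog_map = {anc_a[aid]: anc_b[aid] for aid in shared}
    breakpoints, blocks = _colinear_truth(genome_a, genome_b, ortholog_map)
    truth = TruthSet(ortholog_map=ortholog_map, true_breakpoints=breakpoints,
                     true_blocks=blocks, event_log=event_log)
    return genome_a, genome_b, truth


def simulate_pair(params: SimParams) -> tuple[Genome, Genome, TruthSet]:
    """Convenience wrapper: ancestor + evolution in one call."""
    return evolve_pair(simulate_ancestor(params), params)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryScores:
    pair_precision: Optional[float]
    pair_recall: float
    breakpoint_recall: Optional[float]
    breakpoint_precision: Optional[float]


def score_recovery(predicted_blocks: list[SyntenyBlock], truth: TruthSet,
                   tolerance: int,
                   genomes: Optional[tuple[Genome, Genome]] = None
                   ) -> RecoveryScores:
    """Score predicted blocks against the simulator truth.

    Pair precision/recall compare the homolog pairs inside blocks with the
    ortholog matching.  A true breakpoint gap is recovered when a predicted
    block boundary lies within ``tolerance`` genes of it; boundary
    precision (the extended report) conversely checks predicted internal
    boundaries against true gaps, ignoring boundaries at chromosome ends
    when ``genomes`` is provided.
    """
    predicted = {(p.gene_a.id, p.gene_b.id)
                 for b in predicted_blocks for p in b.member_pairs()}
    true_pairs = set(truth.ortholog_map.items())
    tp = len(predicted & true_pairs)
    precision = tp / len(predicted) if predicted else None
    recall = tp / len(true_pairs) if true_pairs else 0.0

    edges: dict[tuple[str, str], list[int]] = {}
    for b in predicted_blocks:
        for gid in (b.genome_id_a, b.genome_id_b):
            chrom = b.chrom_on(gid)
            lo, hi = b.span_on(gid)
            edges.setdefault((gid, chrom), []).extend((lo, hi))

    def gap_distance(edge: int, left: int, right: int) -> int:
        if left <= edge <= right:
            return 0
        return min(abs(edge - left), abs(edge - right))

    n_true = 0
    n_found = 0
    for genome_id, gaps in truth.true_breakpoints.items():
        for chrom, left, right in gaps:
            n_true += 1
            cand = edges.get((genome_id, chrom), [])
            if any(gap_distance(e, left, right) <= tolerance for e in cand):
                n_found += 1
    bp_recall = n_found / n_true if n_true else None

    bp_precision = None
    if genomes is not None:
        by_id = {g.id: g for g in genomes}
        n_pred = 0
        n_good = 0
        for (genome_id, chrom), es in edges.items():
            genes = by_id[genome_id].chromosomes.get(chrom, [])
            gaps = [g for g in truth.true_breakpoints.get(genome_id, [])
                    if g[0] == chrom]
            for e in es:
                if e <= 0 or e >= len(genes) - 1:
                    continue  # chromosome end, not a claimed breakpoint
                n_pred += 1
                if any(gap_distance(e, left, right) <= tolerance
                       for _, left, right in gaps):
                    n_good += 1
        bp_precision = n_good / n_pred if n_pred else None
    return RecoveryScores(pair_precision=precision, pair_recall=recall,
                          breakpoint_recall=bp_recall,
                          breakpoint_precision=bp_precision)
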