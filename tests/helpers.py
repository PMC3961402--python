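"""Independent oracles and small builders shared by the test suite.

Everything here is deliberately written from first principles (plain
dictionaries, exhaustive loops, Biopython reference calls) so it exercises
the same definitions as the package without sharing its code paths.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from syntenic.genome_io import Gene, Genome
from syntenic.homology import AlignmentResult, HomologyPair

AA20 = "ARNDCQEGHILKMFPSTWYV"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=length))


def mutate(rng: np.random.Generator, protein: str, rate: float) -> str:
    return "".join(AA20[rng.integers(0, 20)] if rng.random() < rate else c
                   for c in protein)


def build_genome(genome_id: str, layout: dict[str, list[tuple]],
                 with_coords: bool = False) -> Genome:
    """Build a genome from {chrom: [(gene id, protein[, strand]), ...]}."""
    chromosomes = {}
    for chrom, entries in layout.items():
        genes = []
        pos = 1
        for rank, entry in enumerate(entries):
            gid, protein = entry[0], entry[1]
            strand = entry[2] if len(entry) > 2 else "+"
            start = end = None
            if with_coords:
                start = pos
                end = pos + 3 * len(protein) + 2
                pos = end + 201
            genes.append(Gene(id=gid, genome_id=genome_id, chromosome=chrom,
                              rank=rank, protein=protein, strand=strand,
                              start=start, end=end))
        chromosomes[chrom] = genes
    return Genome(id=genome_id, chromosomes=chromosomes)


def fake_result(similarity: float = 90.0) -> AlignmentResult:
    return AlignmentResult(score_0_100=similarity, similarity_pct=similarity,
                           match_len=100, len_query=100, len_target=100,
                           raw_score=100.0)


def make_pair(genome_a: Genome, genome_b: Genome, id_a: str, id_b: str,
              kind: str = "RBH") -> HomologyPair:
    return HomologyPair(gene_a=genome_a[id_a], gene_b=genome_b[id_b],
                        kind=kind, result=fake_result())


# ---------------------------------------------------------------------------
# alignment oracles
# ---------------------------------------------------------------------------

def biopython_matrix(name: str):
    from Bio.Align import substitution_matrices
    return substitution_matrices.load(name)


def gotoh_endfree_score(a: str, b: str, matrix, gap_open: float,
                        gap_extend: float) -> float:
    """Pure-Python affine-gap global alignment with free terminal gaps.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
    """
    neg = float("-inf")
    m, n = len(a), len(b)
    S = [[0.0] * (n + 1) for _ in range(m + 1)]
    P = [[neg] * (n + 1) for _ in range(m + 1)]
    Q = [[neg] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            P[i][j] = max(S[i - 1][j] - gap_open, P[i - 1][j] - gap_extend)
            Q[i][j] = max(S[i][j - 1] - gap_open, Q[i][j - 1] - gap_extend)
            S[i][j] = max(S[i - 1][j - 1] + matrix[a[i - 1], b[j - 1]],
                          P[i][j], Q[i][j])
    return max(max(S[m][j] for j in range(n + 1)),
               max(S[i][n] for i in range(m + 1)))


def smith_waterman_score(a: str, b: str, matrix, gap_open: float,
                         gap_extend: float) -> float:
    neg = float("-inf")
    m, n = len(a), len(b)
    S = [[0.0] * (n + 1) for _ in range(m + 1)]
    P = [[neg] * (n + 1) for _ in range(m + 1)]
    Q = [[neg] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            P[i][j] = max(S[i - 1][j] - gap_open, P[i - 1][j] - gap_extend)
            Q[i][j] = max(S[i][j - 1] - gap_open, Q[i][j - 1] - gap_extend)
            S[i][j] = max(0.0, S[i - 1][j - 1] + matrix[a[i - 1], b[j - 1]],
                          P[i][j], Q[i][j])
            best = max(best, S[i][j])
    return best


def prefilter_oracle(query: str, targets: list[tuple[str, str]], k: int,
                     kuple: int, threshold: int) -> list[str]:
    """Exhaustive offset enumeration of shared k-word counts."""
    scores = {}
    for tid, t in targets:
        best = 0
        for offset in range(-(len(t) - kuple), len(query) - kuple + 1):
            count = 0
            for qi in range(len(query) - kuple + 1):
                ti = qi - offset
                if 0 <= ti <= len(t) - kuple \
                        and query[qi:qi + kuple] == t[ti:ti + kuple]:
                    count += 1
            best = max(best, count)
        scores[tid] = best
    ranked = sorted((tid for tid, s in scores.items() if s >= threshold),
                    key=lambda tid: (-scores[tid], tid))
    return ranked[:k]


# ---------------------------------------------------------------------------
# chaining oracle
# ---------------------------------------------------------------------------

def chain_closure_oracle(rbh: list[HomologyPair], genome_a: Genome,
                         genome_b: Genome, delta1: int) -> set[frozenset]:
    """Connected components of the Δ1 relation by explicit transitive closure."""
    def rbh_rank(side: str) -> dict[str, int]:
        per_chrom: dict[str, list[tuple[int, str]]] = {}
        for p in rbh:
            g = p.gene_a if side == "a" else p.gene_b
            per_chrom.setdefault(g.chromosome, []).append((g.rank, g.id))
        out = {}
        for entries in per_chrom.values():
            for i, (_, gid) in enumerate(sorted(entries)):
                out[gid] = i
        return out

    ra, rb = rbh_rank("a"), rbh_rank("b")
    g = nx.Graph()
    g.add_nodes_from(range(len(rbh)))
    for i, j in itertools.combinations(range(len(rbh)), 2):
        pi, pj = rbh[i], rbh[j]
        if pi.gene_a.chromosome != pj.gene_a.chromosome:
            continue
        if pi.gene_b.chromosome != pj.gene_b.chromosome:
            continue
        between_a = abs(ra[pi.gene_a.id] - ra[pj.gene_a.id]) - 1
        between_b = abs(rb[pi.gene_b.id] - rb[pj.gene_b.id]) - 1
        if between_a < delta1 and between_b < delta1:
            g.add_edge(i, j)
    return {frozenset((rbh[i].gene_a.id, rbh[i].gene_b.id) for i in comp)
            for comp in nx.connected_components(g)}


def components_as_sets(components) -> set[frozenset]:
    return {frozenset(a.pair.key for a in comp) for comp in components}
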