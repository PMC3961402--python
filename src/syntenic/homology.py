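"""Homology detection: reciprocal best hits and the non-RBH homology test.

The RBH search mimics the two-stage strategy of FASTA-style ortholog
scanners: a fast ungapped word-match prefilter proposes, for every query
protein, its K most similar partners in the other proteome; only these
candidates are then refined with an end-gap-free global alignment whose
score is normalized to the 0-100 range as the percentage of
positive-scoring aligned columns.  A pair is an RBH when each gene is the
other's best refined candidate, the normalized score reaches the homology
threshold and the protein lengths differ by at most the allowed ratio.

Non-RBH homologs — used later to complete synteny blocks — are called from
a gapped local alignment: at least 30% positive columns and a match length
(internal gaps included) strictly greater than half the shorter protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _align
from .genome_io import Gene, Genome

RBH = "RBH"
NONRBH = "NONRBH"


@dataclass(frozen=True)
class AlignmentParams:
    """Tunable thresholds of the homology stage (defaults = standard run)."""

    K: int = 6
    kuple: int = 2
    refine_matrix: str = "BLOSUM62"
    rbh_score_threshold: float = 40.0
    rbh_length_ratio_max: float = 1.3
    nonrbh_min_similarity: float = 30.0
    nonrbh_min_coverage: float = 0.5
    nonrbh_matrix: str = "BLOSUM62"
    prefilter_lower_threshold: int = 5
    gap_open: float = 12.0
    gap_extend: float = 2.0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.kuple < 1:
            raise ValueError("kuple must be >= 1")
        if not 0 <= self.rbh_score_threshold <= 100:
            raise ValueError("rbh_score_threshold outside [0, 100]")
        if self.rbh_length_ratio_max < 1:
            raise ValueError("rbh_length_ratio_max must be >= 1")
        if not 0 <= self.nonrbh_min_similarity <= 100:
            raise ValueError("nonrbh_min_similarity outside [0, 100]")
        if not 0 <= self.nonrbh_min_coverage <= 1:
            raise ValueError("nonrbh_min_coverage outside [0, 1]")


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one pairwise protein alignment."""

    score_0_100: float
    similarity_pct: float
    match_len: int
    len_query: int
    len_target: int
    raw_score: float = 0.0


@dataclass
class HomologyPair:
    """A homologous gene pair between two genomes (the atomic evidence unit)."""

    gene_a: Gene
    gene_b: Gene
    kind: str
    result: AlignmentResult
    syntenic: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.gene_a.genome_id == self.gene_b.genome_id:
            raise ValueError("homology pair within a single genome")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a.id, self.gene_b.id)


def prefilter_candidates(query_protein: str,
                         target_proteome: list[tuple[str, str]],
                         params: AlignmentParams) -> list[str]:
    """Rank targets by best shifted k-word match count; keep the top K.

    The score of a target is the maximum, over all relative offsets of the
    two (ungapped) sequences, of the number of k-words shared at that
    offset.  Targets scoring below ``prefilter_lower_threshold`` are
    dropped; ties rank by ascending target id.
    """
    if not query_protein:
        raise ValueError("empty query protein")
    if len(query_protein) < params.kuple:
        raise ValueError("query shorter than the word size")
    if not target_proteome:
        return []
    alphabet, _ = _align.load_matrix(params.refine_matrix)
    A = len(alphabet)
    qwords = _align.word_encode(_align.encode(query_protein, alphabet),
                                params.kuple, A)
    ids = [tid for tid, _ in target_proteome]
    word_lists = [
        _align.word_encode(_align.encode(seq, alphabet), params.kuple, A)
        for _, seq in target_proteome]
    sorted_pos, buckets, offsets = _align.build_word_buckets(word_lists, A ** params.kuple)
    max_tw = max(w.shape[0] for w in word_lists)
    scores = _align.prefilter_scores(qwords, sorted_pos, buckets, offsets, max_tw)
    ranked = sorted(
        (tid for tid, s in zip(ids, scores) if s >= params.prefilter_lower_threshold),
        key=lambda tid: (-int(scores[ids.index(tid)]), tid))
    return ranked[:params.K]


def _result_from_counts(raw: float, cols: int, positives: int,
                        len_a: int, len_b: int,
                        min_self_score: Optional[float] = None) -> AlignmentResult:
    """Assemble an AlignmentResult from alignment counts.

    ``similarity_pct`` is the percentage of positive-scoring columns.
    ``score_0_100`` is the raw score normalized by the smaller self-score
    (identical sequences score 100, spurious short overlaps near 0); when
    no self-score is given (local alignments) it falls back to the
    similarity percentage.
    """
    pct = 100.0 * positives / cols if cols else 0.0
    if min_self_score is not None and min_self_score > 0:
        score = min(max(100.0 * raw / min_self_score, 0.0), 100.0)
    else:
        score = pct
    # lengths in canonical (shorter, longer) order so results are symmetric
    return AlignmentResult(score_0_100=score, similarity_pct=pct, match_len=cols,
                           len_query=min(len_a, len_b),
                           len_target=max(len_a, len_b), raw_score=raw)


def refine_score(protein_a: str, protein_b: str,
                 params: AlignmentParams) -> AlignmentResult:
    """End-gap-free global alignment normalized to the 0-100 range.

    ``score_0_100`` is the raw alignment score as a percentage of the
    smaller sequence's self-alignment score; ``similarity_pct`` the
    percentage of positive-scoring columns between the first and last
    aligned residue pair; ``match_len`` counts those columns including
    internal gaps.  Symmetric in its two arguments.
    """
    if not protein_a or not protein_b:
        raise ValueError("empty protein sequence")
    alphabet, mat = _align.load_matrix(params.refine_matrix)
    ea = _align.encode(protein_a, alphabet)
    eb = _align.encode(protein_b, alphabet)
    # canonical argument order makes the traceback (and thus the column
    # statistics) exactly symmetric
    if (len(protein_a), protein_a) <= (len(protein_b), protein_b):
        raw, cols, positives = _align.global_align(ea, eb, mat,
                                                   params.gap_open, params.gap_extend)
    else:
        raw, cols, positives = _align.global_align(eb, ea, mat,
                                                   params.gap_open, params.gap_extend)
    self_a = float(mat[ea, ea].sum())
    self_b = float(mat[eb, eb].sum())
    return _result_from_counts(raw, cols, positives, len(protein_a),
                               len(protein_b), min(self_a, self_b))


def test_nonrbh_homology(protein_a: str, protein_b: str,
                         params: AlignmentParams) -> tuple[bool, AlignmentResult]:
    """Local-alignment homology test for block completion.

    Passes iff the local alignment shows at least ``nonrbh_min_similarity``
    percent positive columns and the match length over the shorter protein
    is strictly greater than ``nonrbh_min_coverage``.
    """
    if not protein_a or not protein_b:
        raise ValueError("empty protein sequence")
    alphabet, mat = _align.load_matrix(params.nonrbh_matrix)
    ea = _align.encode(protein_a, alphabet)
    eb = _align.encode(protein_b, alphabet)
    if (len(protein_a), protein_a) <= (len(protein_b), protein_b):
        raw, cols, positives = _align.local_align(ea, eb, mat,
                                                  params.gap_open, params.gap_extend)
    else:
        raw, cols, positives = _align.local_align(eb, ea, mat,
                                                  params.gap_open, params.gap_extend)
    res = _result_from_counts(raw, cols, positives, len(protein_a), len(protein_b))
    coverage = res.match_len / min(res.len_query, res.len_target)
    passes = (res.similarity_pct >= params.nonrbh_min_similarity
              and coverage > params.nonrbh_min_coverage)
    return passes, res


class _ProteomeIndex:
    """Word-bucket index of one proteome for batch prefiltering."""

    def __init__(self, genome: Genome, params: AlignmentParams, alphabet: str,
                 mat: np.ndarray):
        self.ids: list[str] = []
        self.enc: list[np.ndarray] = []
        self.self_scores: list[float] = []
        A = len(alphabet)
        word_lists = []
        for g in genome.genes():
            self.ids.append(g.id)
            e = _align.encode(g.protein, alphabet)
            self.enc.append(e)
            self.self_scores.append(float(mat[e, e].sum()))
            word_lists.append(_align.word_encode(e, params.kuple, A))
        self.words = word_lists
        self.sorted_pos, self.buckets, self.offsets = _align.build_word_buckets(
            word_lists, A ** params.kuple)
        self.max_words = max((w.shape[0] for w in word_lists), default=0)
        order = np.argsort(np.array(self.ids))  # tie-break ranking by id
        self.id_rank = np.empty(len(self.ids), dtype=np.int64)
        self.id_rank[order] = np.arange(len(self.ids))


def _top_candidates(scores: np.ndarray, index: _ProteomeIndex,
                    params: AlignmentParams) -> list[int]:
    keep = np.flatnonzero(scores >= params.prefilter_lower_threshold)
    if keep.size == 0:
        return []
    order = np.lexsort((index.id_rank[keep], -scores[keep]))
    return [int(keep[i]) for i in order[:params.K]]


def find_rbh(genome_a: Genome, genome_b: Genome,
             params: AlignmentParams | None = None) -> list[HomologyPair]:
    """Identify reciprocal best hits between two genomes.

    For every gene the prefilter proposes up to K candidates which are then
    refined; a pair is reported when each gene is the other's best refined
    candidate (ties broken toward the lexicographically smallest id), the
    normalized score reaches ``rbh_score_threshold`` and the length ratio
    (longest over shortest) is at most ``rbh_length_ratio_max``.  The
    result is a matching: no gene occurs twice.
    """
    if params is None:
        params = AlignmentParams()
    if genome_a.n_genes == 0 or genome_b.n_genes == 0:
        raise ValueError("cannot search an empty genome")
    alphabet, mat = _align.load_matrix(params.refine_matrix)
    ix_a = _ProteomeIndex(genome_a, params, alphabet, mat)
    ix_b = _ProteomeIndex(genome_b, params, alphabet, mat)

    cache: dict[tuple[int, int], AlignmentResult] = {}

    def refined(i: int, j: int) -> AlignmentResult:
        res = cache.get((i, j))
        if res is None:
            ea, eb = ix_a.enc[i], ix_b.enc[j]
            # canonical order by (length, sequence bytes) for symmetry
            if (ea.shape[0], ea.tobytes()) <= (eb.shape[0], eb.tobytes()):
                raw, cols, positives = _align.global_align(
                    ea, eb, mat, params.gap_open, params.gap_extend)
            else:
                raw, cols, positives = _align.global_align(
                    eb, ea, mat, params.gap_open, params.gap_extend)
            res = _result_from_counts(raw, cols, positives,
                                      ea.shape[0], eb.shape[0],
                                      min(ix_a.self_scores[i], ix_b.self_scores[j]))
            cache[(i, j)] = res
        return res

    def best_partner(qi: int, qix: _ProteomeIndex, tix: _ProteomeIndex,
                     forward: bool) -> Optional[int]:
        qwords = qix.words[qi]
        if qwords.shape[0] == 0 or tix.max_words == 0:
            return None
        scores = _align.prefilter_scores(qwords, tix.sorted_pos, tix.buckets,
                                         tix.offsets, tix.max_words)
        cands = _top_candidates(scores, tix, params)
        best_j: Optional[int] = None
        best_key: Optional[tuple] = None
        for j in cands:
            res = refined(qi, j) if forward else refined(j, qi)
            key = (-res.score_0_100, tix.ids[j])
            if best_key is None or key < best_key:
                best_key = key
                best_j = j
        return best_j

    best_ab = {i: best_partner(i, ix_a, ix_b, True) for i in range(len(ix_a.ids))}
    best_ba = {j: best_partner(j, ix_b, ix_a, False) for j in range(len(ix_b.ids))}

    pairs: list[HomologyPair] = []
    for i, j in best_ab.items():
        if j is None or best_ba.get(j) != i:
            continue
        res = refined(i, j)
        la, lb = res.len_query, res.len_target
        if res.score_0_100 < params.rbh_score_threshold:
            continue
        if max(la, lb) / min(la, lb) > params.rbh_length_ratio_max:
            continue
        pairs.append(HomologyPair(gene_a=genome_a[ix_a.ids[i]],
                                  gene_b=genome_b[ix_b.ids[j]],
                                  kind=RBH, result=res))
    pairs.sort(key=lambda p: p.key)
    return pairs
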