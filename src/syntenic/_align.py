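"""Low-level protein alignment kernels.

Implements the two alignment flavours the pipeline relies on:

* an end-gap-free global alignment (Gotoh affine gaps, zero-cost terminal
  gaps) used to refine reciprocal-best-hit candidates, and
* a local affine alignment (Smith-Waterman) used by the non-RBH homology
  test.

Both report, besides the raw score, the number of alignment columns between
the first and last aligned residue pair (internal gaps included) and the
number of columns whose substitution score is strictly positive.  Scores are
normalized downstream as ``100 * positives / columns``.

A gap of length L costs ``gap_open + (L - 1) * gap_extend``; terminal gaps
of the global mode are free.  Tie-breaking in the traceback is fixed
(diagonal, then vertical, then horizontal; gap-open before gap-extend) so
results are deterministic.

Substitution matrices come from Biopython's collection or from any
NCBI-format matrix file.
"""

from __future__ import annotations

import os
from functools import lru_cache

import numpy as np
from numba import njit

NEG = -1e30


@lru_cache(maxsize=None)
def load_matrix(name_or_path: str) -> tuple[str, np.ndarray]:
    """Load a substitution matrix by Biopython name or file path.

    Returns ``(alphabet, matrix)`` where *matrix* is a dense float64 array
    indexed by alphabet position.
    """
    from Bio.Align import substitution_matrices

    if os.path.sep in name_or_path or os.path.exists(name_or_path):
        m = substitution_matrices.read(name_or_path)
    else:
        m = substitution_matrices.load(name_or_path)
    alphabet = "".join(m.alphabet)
    return alphabet, np.asarray(m, dtype=np.float64)


@lru_cache(maxsize=None)
def _alphabet_lut(alphabet: str) -> np.ndarray:
    lut = np.full(128, -1, dtype=np.int8)
    for i, c in enumerate(alphabet):
        lut[ord(c)] = i
    return lut


def encode(seq: str, alphabet: str) -> np.ndarray:
    """Encode an amino-acid string as matrix-alphabet indices.

    Raises ``ValueError`` naming the first character outside the alphabet.
    """
    lut = _alphabet_lut(alphabet)
    arr = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    enc = lut[np.minimum(arr, 127)]
    if (enc < 0).any():
        bad = seq[int(np.argmax(enc < 0))]
        raise ValueError(f"residue {bad!r} not in substitution-matrix alphabet")
    return enc.astype(np.int8)


# traceback pointer codes
_DIAG, _UP, _LEFT = 0, 1, 2


@njit(cache=True, nogil=True)
def _trim_counts(kinds, pos, n):  # pragma: no cover - exercised via wrappers
    """Columns / positives between the first and last diagonal step."""
    first = -1
    last = -1
    for t in range(n):
        if kinds[t] == 0:
            if first < 0:
                first = t
            last = t
    if first < 0:
        return 0, 0
    cols = last - first + 1
    positives = 0
    for t in range(first, last + 1):
        if kinds[t] == 0 and pos[t] == 1:
            positives += 1
    return cols, positives


@njit(cache=True, nogil=True)
def global_align(a, b, mat, gap_open, gap_extend):  # pragma: no cover
    """End-gap-free global alignment.

    Returns ``(raw_score, columns, positives)`` where columns span the
    region between the first and the last aligned residue pair.
    """
    m = a.shape[0]
    n = b.shape[0]
    S = np.empty((m + 1, n + 1))
    P = np.empty((m + 1, n + 1))
    Q = np.empty((m + 1, n + 1))
    ptrS = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrP = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrQ = np.zeros((m + 1, n + 1), dtype=np.uint8)
    for j in range(n + 1):
        S[0, j] = 0.0
        P[0, j] = NEG
        Q[0, j] = NEG
    for i in range(1, m + 1):
        S[i, 0] = 0.0
        P[i, 0] = NEG
        Q[i, 0] = NEG
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            po = S[i - 1, j] - gap_open
            pe = P[i - 1, j] - gap_extend
            if po >= pe:
                P[i, j] = po
                ptrP[i, j] = 0
            else:
                P[i, j] = pe
                ptrP[i, j] = 1
            qo = S[i, j - 1] - gap_open
            qe = Q[i, j - 1] - gap_extend
            if qo >= qe:
                Q[i, j] = qo
                ptrQ[i, j] = 0
            else:
                Q[i, j] = qe
                ptrQ[i, j] = 1
            d = S[i - 1, j - 1] + mat[ai, b[j - 1]]
            best = d
            ptr = _DIAG
            if P[i, j] > best:
                best = P[i, j]
                ptr = _UP
            if Q[i, j] > best:
                best = Q[i, j]
                ptr = _LEFT
            S[i, j] = best
            ptrS[i, j] = ptr
    # best cell on the bottom row or right column (free trailing gaps)
    bi, bj = m, 0
    best = S[m, 0]
    for j in range(1, n + 1):
        if S[m, j] > best:
            best = S[m, j]
            bi, bj = m, j
    for i in range(m + 1):
        if S[i, n] > best:
            best = S[i, n]
            bi, bj = i, n
    kinds = np.empty(m + n, dtype=np.uint8)  # 0 diag, 1 gap
    pos = np.zeros(m + n, dtype=np.uint8)
    t = 0
    i, j = bi, bj
    state = 0  # 0 -> S, 1 -> P, 2 -> Q
    while i > 0 and j > 0:
        if state == 0:
            ptr = ptrS[i, j]
            if ptr == _DIAG:
                kinds[t] = 0
                if mat[a[i - 1], b[j - 1]] > 0:
                    pos[t] = 1
                t += 1
                i -= 1
                j -= 1
            elif ptr == _UP:
                state = 1
            else:
                state = 2
        elif state == 1:
            kinds[t] = 1
            t += 1
            if ptrP[i, j] == 0:
                state = 0
            i -= 1
        else:
            kinds[t] = 1
            t += 1
            if ptrQ[i, j] == 0:
                state = 0
            j -= 1
    cols, positives = _trim_counts(kinds, pos, t)
    return best, cols, positives


@njit(cache=True, nogil=True)
def local_align(a, b, mat, gap_open, gap_extend):  # pragma: no cover
    """Affine-gap local alignment; returns (raw_score, columns, positives)."""
    m = a.shape[0]
    n = b.shape[0]
    S = np.zeros((m + 1, n + 1))
    P = np.empty((m + 1, n + 1))
    Q = np.empty((m + 1, n + 1))
    ptrS = np.full((m + 1, n + 1), 3, dtype=np.uint8)  # 3 -> stop
    ptrP = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrQ = np.zeros((m + 1, n + 1), dtype=np.uint8)
    for j in range(n + 1):
        P[0, j] = NEG
        Q[0, j] = NEG
    for i in range(1, m + 1):
        P[i, 0] = NEG
        Q[i, 0] = NEG
    best = 0.0
    bi, bj = 0, 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            po = S[i - 1, j] - gap_open
            pe = P[i - 1, j] - gap_extend
            if po >= pe:
                P[i, j] = po
                ptrP[i, j] = 0
            else:
                P[i, j] = pe
                ptrP[i, j] = 1
            qo = S[i, j - 1] - gap_open
            qe = Q[i, j - 1] - gap_extend
            if qo >= qe:
                Q[i, j] = qo
                ptrQ[i, j] = 0
            else:
                Q[i, j] = qe
                ptrQ[i, j] = 1
            d = S[i - 1, j - 1] + mat[ai, b[j - 1]]
            v = d
            ptr = _DIAG
            if P[i, j] > v:
                v = P[i, j]
                ptr = _UP
            if Q[i, j] > v:
                v = Q[i, j]
                ptr = _LEFT
            if v <= 0.0:
                S[i, j] = 0.0
                ptrS[i, j] = 3
            else:
                S[i, j] = v
                ptrS[i, j] = ptr
                if v > best:
                    best = v
                    bi, bj = i, j
    kinds = np.empty(m + n, dtype=np.uint8)
    pos = np.zeros(m + n, dtype=np.uint8)
    t = 0
    i, j = bi, bj
    state = 0
    while i > 0 and j > 0 and not (state == 0 and ptrS[i, j] == 3):
        if state == 0:
            ptr = ptrS[i, j]
            if ptr == _DIAG:
                kinds[t] = 0
                if mat[a[i - 1], b[j - 1]] > 0:
                    pos[t] = 1
                t += 1
                i -= 1
                j -= 1
            elif ptr == _UP:
                state = 1
            else:
                state = 2
        elif state == 1:
            kinds[t] = 1
            t += 1
            if ptrP[i, j] == 0:
                state = 0
            i -= 1
        else:
            kinds[t] = 1
            t += 1
            if ptrQ[i, j] == 0:
                state = 0
            j -= 1
    cols, positives = _trim_counts(kinds, pos, t)
    return best, cols, positives


# ---------------------------------------------------------------------------
# fastp-style ungapped word-match prefilter
# ---------------------------------------------------------------------------


def word_encode(enc: np.ndarray, k: int, alphabet_size: int) -> np.ndarray:
    """Rolling k-word codes of an index-encoded sequence (len - k + 1 words)."""
    n = enc.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int32)
    w = np.zeros(n, dtype=np.int32)
    for off in range(k):
        w = w * alphabet_size + enc[off:off + n].astype(np.int32)
    return w


def build_word_buckets(word_lists: list[np.ndarray], n_words: int):
    """Counting-sort word positions per target for fast diagonal lookups.

    Returns ``(sorted_pos, bucket_offsets, target_offsets)`` flattened over
    targets; positions of word ``w`` in target ``t`` are
    ``sorted_pos[target_offsets[t] + bucket_offsets[t, w] :
                 target_offsets[t] + bucket_offsets[t, w + 1]]``.
    """
    n_t = len(word_lists)
    lens = np.array([w.shape[0] for w in word_lists], dtype=np.int64)
    target_offsets = np.zeros(n_t + 1, dtype=np.int64)
    np.cumsum(lens, out=target_offsets[1:])
    sorted_pos = np.empty(int(target_offsets[-1]), dtype=np.int32)
    bucket_offsets = np.zeros((n_t, n_words + 1), dtype=np.int32)
    for t, words in enumerate(word_lists):
        counts = np.bincount(words, minlength=n_words)
        bucket_offsets[t, 1:] = np.cumsum(counts)
        order = np.argsort(words, kind="stable")
        sorted_pos[target_offsets[t]:target_offsets[t + 1]] = order.astype(np.int32)
    return sorted_pos, bucket_offsets, target_offsets


@njit(cache=True, nogil=True)
def prefilter_scores(qwords, sorted_pos, bucket_offsets, target_offsets,
                     max_target_words):  # pragma: no cover
    """Best shifted word-match count of one query against every target.

    The score of a target is the maximum over all relative offsets of the
    number of k-words shared at that offset (no gaps, each diagonal scored
    independently).
    """
    n_t = bucket_offsets.shape[0]
    nq = qwords.shape[0]
    scores = np.zeros(n_t, dtype=np.int32)
    diag = np.zeros(nq + max_target_words + 1, dtype=np.int32)
    touched = np.empty(nq + max_target_words + 1, dtype=np.int64)
    for t in range(n_t):
        base = target_offsets[t]
        n_touched = 0
        best = 0
        for qi in range(nq):
            w = qwords[qi]
            lo = base + bucket_offsets[t, w]
            hi = base + bucket_offsets[t, w + 1]
            for p in range(lo, hi):
                d = sorted_pos[p] - qi + nq  # shift to non-negative
                if diag[d] == 0:
                    touched[n_touched] = d
                    n_touched += 1
                diag[d] += 1
                if diag[d] > best:
                    best = diag[d]
        scores[t] = best
        for u in range(n_touched):
            diag[touched[u]] = 0
    return scores
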