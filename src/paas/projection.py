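"""Positional local-similarity projection scores.

A training sequence ``D`` is slid against a query ``Q`` at every shift with at
least one residue of overlap.  For a shift ``h`` (pairing query position ``x``
with ``D`` position ``x + h``) the cumulative similarity up to query position
``i`` is::

    A(i, h) = sum over x <= i with 1 <= x + h <= m of sim(q_x, d_{x+h})

with ``A(i, h) = 0`` for ``i <= 0``.  The frame score ending at ``i`` is
``W(i, h) = A(i, h) - A(i - F, h)`` — the similarity collected by a window of
at most ``F`` aligned positions terminating at ``i``.  The best frame ending
at ``i`` over all shifts is ``R_i = max_h W(i, h)``, and the projection score
at position ``i`` is the best score of any frame containing ``i``::

    S_i = max over j in 0..F-1 with i + j <= n of R_{i+j}

Frames never extend past the query: frame ends ``< F`` positions into the
query are truncated, and ``S_i`` maximises only over frame ends ``<= n``.

The fast path runs in O(n*m) time and O(n+m) working memory per sequence
pair; :func:`brute_force_projection_scores` recomputes the same contract by
explicit triple loop and serves as the verification oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence as SeqOf

import numpy as np
from numba import njit

from .errors import PaasError
from .seqio import CANONICAL_RESIDUES, RESIDUE_ALPHABET, Sequence, SubstitutionMatrix

MEASURE_NAMES = ("blosum62-normalized", "identity", "raw-matrix")


class SimilarityMeasure:
    """Residue-pair similarity function backed by a lookup table.

    Three measures are supported:

    ``identity``
        sim(a, b) = 1 if a == b else 0.
    ``blosum62-normalized`` (default; any symmetric matrix accepted)
        sim(a, b) = clamp(score(a, b) / sqrt(score(a, a) * score(b, b)), 0, 1);
        any pair involving a letter with a missing or non-positive diagonal
        entry scores 0.  Values lie in [0, 1] with sim(a, a) = 1 for canonical
        residues.
    ``raw-matrix``
        the untransformed (possibly negative) matrix scores.

    Letters absent from the backing matrix score 0 against everything.
    """

    def __init__(self, name: str, alphabet: str, table: np.ndarray,
                 matrix: SubstitutionMatrix | None = None) -> None:
        if name not in MEASURE_NAMES:
            raise PaasError(f"unknown measure {name!r}; expected one of {MEASURE_NAMES}")
        self.name = name
        self.alphabet = alphabet
        #: (K+1, K+1) float table; the last row/column is the catch-all code
        #: for letters outside ``alphabet`` and scores 0 everywhere.
        self.table = np.ascontiguousarray(table, dtype=np.float64)
        self.matrix = matrix
        self._codes = np.full(128, len(alphabet), dtype=np.uint8)
        for i, ch in enumerate(alphabet):
            self._codes[ord(ch)] = i

    @property
    def normalized(self) -> bool:
        """True when sim values are guaranteed to lie in [0, 1]."""
        return self.name != "raw-matrix"

    def encode(self, residues: str) -> np.ndarray:
        """Map a residue string to table row/column codes."""
        return self._codes[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]

    def sim(self, a: str, b: str) -> float:
        """Similarity of a single residue pair."""
        return float(self.table[self._codes[ord(a)], self._codes[ord(b)]])

    @classmethod
    def identity(cls) -> "SimilarityMeasure":
        alphabet = RESIDUE_ALPHABET
        k = len(alphabet)
        table = np.zeros((k + 1, k + 1))
        table[:k, :k] = np.eye(k)
        return cls("identity", alphabet, table)

    @classmethod
    def blosum62_normalized(
        cls, matrix: SubstitutionMatrix | None = None
    ) -> "SimilarityMeasure":
        matrix = matrix if matrix is not None else SubstitutionMatrix.blosum62()
        k = len(matrix.alphabet)
        diag = np.diag(matrix.scores)
        table = np.zeros((k + 1, k + 1))
        valid = diag > 0
        denom = np.sqrt(np.outer(np.where(valid, diag, 1.0), np.where(valid, diag, 1.0)))
        norm = np.clip(matrix.scores / denom, 0.0, 1.0)
        norm[~valid, :] = 0.0
        norm[:, ~valid] = 0.0
        table[:k, :k] = norm
        return cls("blosum62-normalized", matrix.alphabet, table, matrix)

    @classmethod
    def raw(cls, matrix: SubstitutionMatrix | None = None) -> "SimilarityMeasure":
        matrix = matrix if matrix is not None else SubstitutionMatrix.blosum62()
        k = len(matrix.alphabet)
        table = np.zeros((k + 1, k + 1))
        table[:k, :k] = matrix.scores
        return cls("raw-matrix", matrix.alphabet, table, matrix)

    @classmethod
    def from_name(
        cls, name: str, matrix: SubstitutionMatrix | None = None
    ) -> "SimilarityMeasure":
        if name == "identity":
            return cls.identity()
        if name == "blosum62-normalized":
            return cls.blosum62_normalized(matrix)
        if name == "raw-matrix":
            return cls.raw(matrix)
        raise PaasError(f"unknown measure {name!r}; expected one of {MEASURE_NAMES}")


DEFAULT_MEASURE_NAME = "blosum62-normalized"

_default_measure: SimilarityMeasure | None = None


def default_measure() -> SimilarityMeasure:
    """Shared BLOSUM62-normalized measure (built once)."""
    global _default_measure
    if _default_measure is None:
        _default_measure = SimilarityMeasure.blosum62_normalized()
    return _default_measure


@dataclass(frozen=True)
class ProjectionProfile:
    """Per-position projection scores of one query against one training sequence."""

    query_id: str
    train_id: str
    frame: int
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.scores)


@njit(cache=True)
def _project_kernel(q: np.ndarray, d: np.ndarray, table: np.ndarray, F: int) -> np.ndarray:
    n = q.shape[0]
    m = d.shape[0]
    NEG = -1.0e300
    R = np.full(n, NEG)
    cover = np.zeros(n, np.int64)
    n_shifts = n + m - 1
    abuf = np.zeros(F)
    for h in range(1 - n, m):
        x0 = 1 - h
        if x0 < 1:
            x0 = 1
        x1 = m - h
        if x1 > n:
            x1 = n
        hi = x1 + F
        if hi > n:
            hi = n
        A = 0.0
        for i in range(x0, hi + 1):
            if i <= x1:
                A += table[q[i - 1], d[i + h - 1]]
            if i - F >= x0:
                W = A - abuf[(i - F) % F]
            else:
                W = A  # A(i-F, h) = 0: window truncated at the overlap start
            abuf[i % F] = A
            if W > R[i - 1]:
                R[i - 1] = W
            cover[i - 1] += 1
    for i in range(n):
        # shifts whose window misses position i contribute W = 0
        if cover[i] < n_shifts and R[i] < 0.0:
            R[i] = 0.0
    S = np.empty(n)
    for i in range(n):
        hi = i + F
        if hi > n:
            hi = n
        best = R[i]
        for j in range(i + 1, hi):
            if R[j] > best:
                best = R[j]
        S[i] = best
    return S


@njit(cache=True)
def _pairwise_sums_kernel(
    codes: np.ndarray, offsets: np.ndarray, table: np.ndarray, F: int
) -> np.ndarray:
    N = offsets.shape[0] - 1
    T = np.zeros((N, N))
    for a in range(N):
        q = codes[offsets[a]: offsets[a + 1]]
        for b in range(N):
            d = codes[offsets[b]: offsets[b + 1]]
            T[a, b] = np.sum(_project_kernel(q, d, table, F))
    return T


@njit(cache=True)
def _query_sums_kernel(
    q: np.ndarray, codes: np.ndarray, offsets: np.ndarray, table: np.ndarray, F: int
) -> np.ndarray:
    N = offsets.shape[0] - 1
    out = np.empty(N)
    for b in range(N):
        d = codes[offsets[b]: offsets[b + 1]]
        out[b] = np.sum(_project_kernel(q, d, table, F))
    return out


def _check_pair(Q: Sequence, D: Sequence, F: int) -> None:
    if F < 1:
        raise PaasError(f"frame must be >= 1, got {F}")
    if len(Q) < 1 or len(D) < 1:
        raise PaasError("sequences must be non-empty")


def projection_scores(
    Q: Sequence, D: Sequence, F: int, measure: SimilarityMeasure | None = None
) -> ProjectionProfile:
    """Project training sequence ``D`` onto query ``Q`` with frame ``F``.

    Returns the per-position score vector ``S`` of length ``len(Q)``.  For
    normalized measures ``0 <= S_i <= F``.
    """
    measure = measure if measure is not None else default_measure()
    _check_pair(Q, D, F)
    S = _project_kernel(measure.encode(Q.residues), measure.encode(D.residues),
                        measure.table, F)
    return ProjectionProfile(Q.id, D.id, F, S)


def brute_force_projection_scores(
    Q: Sequence, D: Sequence, F: int, measure: SimilarityMeasure | None = None
) -> ProjectionProfile:
    """Oracle implementation of :func:`projection_scores`.

    Explicit triple loop over (frame end, shift, in-frame offset), no
    cumulative sums.  Intended for n*m*F up to ~1e6.
    """
    measure = measure if measure is not None else default_measure()
    _check_pair(Q, D, F)
    n, m = len(Q), len(D)
    q, d = Q.residues, D.residues
    R = [float("-inf")] * (n + 1)  # R[e] = best frame score ending at e (1-based)
    for e in range(1, n + 1):
        best = float("-inf")
        for h in range(1 - n, m):
            w = 0.0
            for x in range(max(1, e - F + 1), e + 1):
                y = x + h
                if 1 <= y <= m:
                    w += measure.sim(q[x - 1], d[y - 1])
            if w > best:
                best = w
        R[e] = best
    S = np.empty(n)
    for i in range(1, n + 1):
        S[i - 1] = max(R[i: min(n, i + F - 1) + 1])
    return ProjectionProfile(Q.id, D.id, F, S)


def profile_matrix(
    Q: Sequence,
    trainset: SeqOf[Sequence],
    F: int,
    measure: SimilarityMeasure | None = None,
) -> np.ndarray:
    """Matrix ``S[i, k]``: projection score at query position ``i`` (row) for
    the ``k``-th training sequence (column, in ``trainset`` order)."""
    if not trainset:
        raise PaasError("trainset must be non-empty")
    measure = measure if measure is not None else default_measure()
    cols = [projection_scores(Q, D, F, measure).scores for D in trainset]
    return np.column_stack(cols)


def _concat_codes(sequences: SeqOf[Sequence], measure: SimilarityMeasure):
    offsets = np.zeros(len(sequences) + 1, dtype=np.int64)
    parts = []
    for i, s in enumerate(sequences):
        c = measure.encode(s.residues)
        parts.append(c)
        offsets[i + 1] = offsets[i] + len(c)
    return np.concatenate(parts), offsets


def pairwise_profile_sums(
    sequences: SeqOf[Sequence], F: int, measure: SimilarityMeasure | None = None
) -> np.ndarray:
    """All-pairs total projection scores.

    ``T[a, b] = sum_i S_i`` of sequence ``a`` as query against sequence ``b``
    as training sequence (note: not symmetric).  With position-independent
    class weights the B statistic depends on the profiles only through these
    totals, so the leave-one-out and split protocols reuse one such matrix.
    """
    if not sequences:
        raise PaasError("need at least one sequence")
    if F < 1:
        raise PaasError(f"frame must be >= 1, got {F}")
    measure = measure if measure is not None else default_measure()
    codes, offsets = _concat_codes(sequences, measure)
    return _pairwise_sums_kernel(codes, offsets, measure.table, F)


def query_profile_sums(
    Q: Sequence,
    trainset: SeqOf[Sequence],
    F: int,
    measure: SimilarityMeasure | None = None,
) -> np.ndarray:
    """Total projection score of ``Q`` against each training sequence."""
    if not trainset:
        raise PaasError("trainset must be non-empty")
    measure = measure if measure is not None else default_measure()
    _check_pair(Q, trainset[0], F)
    codes, offsets = _concat_codes(trainset, measure)
    return _query_sums_kernel(measure.encode(Q.residues), codes, offsets,
                              measure.table, F)
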