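"""Candidate verification: local alignment, bitscores and E-values.

Candidates surviving the voting stage are verified with an affine-gap
Smith-Waterman alignment (Biopython's PairwiseAligner, which implements
the exact dynamic program in C).  Raw scores are converted to bitscores
and expectations with gapped Karlin-Altschul statistics,

    bits = (lambda * S - ln K) / ln 2,      E = m * n * 2 ** -bits,

using the published BLAST parameters for BLOSUM62 with gap open 11 /
extend 1 (lambda = 0.267, K = 0.041) by default, so scores are directly
comparable to BLAST output.  Search space is raw ``m * n`` (query length
times database residues) without BLAST's finite-size edge correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numba import njit
from Bio.Align import PairwiseAligner, substitution_matrices

from .alphabet import SubstitutionMatrix
from .index import SuffixIndex

#: Published gapped Karlin-Altschul parameters for BLOSUM62, gaps 11/1.
BLOSUM62_GAPPED_LAMBDA = 0.267
BLOSUM62_GAPPED_K = 0.041


@dataclass(frozen=True)
class KarlinAltschulParams:
    lam: float = BLOSUM62_GAPPED_LAMBDA
    k: float = BLOSUM62_GAPPED_K
    gap_open: int = 11
    gap_extend: int = 1
    db_residues: int = 0

    def __post_init__(self):
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be positive")


@dataclass(frozen=True)
class AlignmentResult:
    raw_score: int
    q_start: int = 0  # 1-based inclusive; 0 when raw_score == 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0
    aligned_length: int = 0
    identities: int = 0
    mismatches: int = 0
    gap_openings: int = 0
    gaps: int = 0

    @property
    def percent_identity(self) -> float:
        if self.aligned_length == 0:
            return 0.0
        return 100.0 * self.identities / self.aligned_length


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    subject_ordinal: int
    result: AlignmentResult
    bitscore: float
    evalue: float


@lru_cache(maxsize=8)
def _aligner(symbols: str, scores_bytes: bytes, gap_open: int, gap_extend: int):
    n = len(symbols)
    arr = substitution_matrices.Array(alphabet=symbols, dims=2)
    arr[:, :] = np.frombuffer(scores_bytes, dtype=np.int64).reshape(n, n)
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = arr
    # Biopython charges open_gap_score for the first gapped position, so a
    # length-g gap costs open + (g-1)*extend; BLAST's convention of
    # gap_open + g*gap_extend therefore maps to open = -(gap_open+gap_extend).
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def get_aligner(matrix: SubstitutionMatrix, gap_open: int = 11, gap_extend: int = 1):
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    return _aligner(matrix.symbols, matrix.scores.astype(np.int64).tobytes(),
                    gap_open, gap_extend)


def local_score(q: str, s: str, matrix: SubstitutionMatrix,
                gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal local alignment score only (no traceback)."""
    if not q or not s:
        raise ValueError("sequences must be non-empty")
    return int(get_aligner(matrix, gap_open, gap_extend).score(q, s))


@njit(cache=True)
def _sw_score_one(q, s, mat, go, ge):
    """Affine-gap local alignment score; first gap costs go + ge."""
    m = len(q)
    h = np.zeros(m + 1, dtype=np.int64)   # best ending in match state
    e = np.full(m + 1, -(1 << 60), dtype=np.int64)  # gap in subject (up)
    best = np.int64(0)
    for j in range(len(s)):
        diag = np.int64(0)
        f = np.int64(-(1 << 60))          # gap in query (left)
        for i in range(1, m + 1):
            e[i] = max(e[i] - ge, h[i] - go - ge)
            f = max(f - ge, h[i - 1] - go - ge)
            sc = diag + mat[q[i - 1], s[j]]
            diag = h[i]
            v = sc
            if e[i] > v:
                v = e[i]
            if f > v:
                v = f
            if v < 0:
                v = 0
            h[i] = v
            if v > best:
                best = v
    return best


@njit(cache=True)
def _sw_score_many(q, text, starts, ends, mat, go, ge):
    out = np.empty(len(starts), dtype=np.int64)
    for c in range(len(starts)):
        out[c] = _sw_score_one(q, text[starts[c] : ends[c]], mat, go, ge)
    return out


def _traceback_stats(alignment, q: str, s: str) -> AlignmentResult:
    qa, sa_ = alignment.aligned  # blocks [(start, end), ...] per sequence
    q_start, q_end = int(qa[0][0]), int(qa[-1][1])
    s_start, s_end = int(sa_[0][0]), int(sa_[-1][1])
    identities = mismatches = 0
    for (qs, qe), (ss, _) in zip(qa, sa_):
        for off in range(qe - qs):
            if q[qs + off] == s[ss + off]:
                identities += 1
            else:
                mismatches += 1
    gap_cols = 0
    gap_openings = 0
    for i in range(1, len(qa)):
        qgap = int(qa[i][0]) - int(qa[i - 1][1])
        sgap = int(sa_[i][0]) - int(sa_[i - 1][1])
        if qgap:
            gap_openings += 1
            gap_cols += qgap
        if sgap:
            gap_openings += 1
            gap_cols += sgap
    return AlignmentResult(
        raw_score=int(alignment.score),
        q_start=q_start + 1,
        q_end=q_end,
        s_start=s_start + 1,
        s_end=s_end,
        aligned_length=identities + mismatches + gap_cols,
        identities=identities,
        mismatches=mismatches,
        gap_openings=gap_openings,
        gaps=gap_cols,
    )


def smith_waterman(q: str, s: str, matrix: SubstitutionMatrix,
                   gap_open: int = 11, gap_extend: int = 1) -> AlignmentResult:
    """Optimal affine-gap local alignment with composition statistics.

    When several alignments are co-optimal, the aligner's first traceback
    is reported.  A score of zero (nothing aligns positively) yields a
    result with no coordinates.
    """
    if not q or not s:
        raise ValueError("sequences must be non-empty")
    aligner = get_aligner(matrix, gap_open, gap_extend)
    score = aligner.score(q, s)
    if score <= 0:
        return AlignmentResult(raw_score=0)
    alignment = next(iter(aligner.align(q, s)))
    return _traceback_stats(alignment, q, s)


def bitscore(raw_score: float, params: KarlinAltschulParams) -> float:
    return (params.lam * raw_score - math.log(params.k)) / math.log(2)


def evalue(raw_score: float, q_len: int, params: KarlinAltschulParams
           ) -> tuple[float, float]:
    """(bitscore, E-value) for a raw score in an m*n search space."""
    if raw_score < 0:
        raise ValueError("raw score must be >= 0")
    bits = bitscore(raw_score, params)
    e = q_len * params.db_residues * 2.0 ** (-bits)
    return bits, e


def rank_hits(
    candidates: list[int],
    query_id: str,
    query_seq: str,
    index: SuffixIndex,
    matrix: SubstitutionMatrix,
    params: KarlinAltschulParams,
    H: int = 1000,
    evalue_max: float = 1.0,
) -> list[AlignmentHit]:
    """Align candidates, filter by E-value and keep the top ``H`` hits.

    Hits are ordered by (bitscore desc, evalue asc, subject ordinal asc).
    Full tracebacks are computed only for the hits actually reported.
    """
    if H < 1:
        raise ValueError("H must be >= 1")
    if not query_seq or not candidates:
        return []
    # Score pass on the rank-encoded index text (no decoding); tracebacks
    # are computed only for the hits actually reported.
    q_codes = index.ordering.encode(query_seq)
    mat = matrix.rank_scores(index.ordering)
    ordinals = np.asarray(candidates, dtype=np.int64)
    starts = index.boundaries[ordinals]
    ends = np.where(
        ordinals + 1 < index.n_proteins,
        index.boundaries[np.minimum(ordinals + 1, index.n_proteins - 1)] - 1,
        len(index.text) - 1,
    )
    raw_scores = _sw_score_many(
        q_codes, index.text, starts, ends, mat,
        np.int64(params.gap_open), np.int64(params.gap_extend),
    )
    scored = []
    for ordinal, raw in zip(candidates, raw_scores):
        if raw <= 0:
            continue
        bits, e = evalue(int(raw), len(query_seq), params)
        if e > evalue_max:
            continue
        scored.append((-bits, e, ordinal))
    scored.sort()
    hits = []
    for neg_bits, e, ordinal in scored[:H]:
        sseq = index.protein_sequence(ordinal)
        result = smith_waterman(query_seq, sseq, matrix,
                                params.gap_open, params.gap_extend)
        hits.append(
            AlignmentHit(
                query_id=query_id,
                subject_id=index.ids[ordinal],
                subject_ordinal=ordinal,
                result=result,
                bitscore=-neg_bits,
                evalue=e,
            )
        )
    return hits
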