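"""Asymmetric suffix array neighbourhood search (SANS).

Candidate retrieval works in three steps.  Each query suffix of length
>= ``min_suffix`` is located in the suffix array by binary search (its
*insertion point* ``k``).  Two *frontiers* per suffix — one walking up
from ``k``, one walking down from ``k - 1`` — are kept in a global
priority queue keyed by the *scored seed* value of the database suffix
at the frontier: the maximum gapless prefix alignment score between the
query suffix and that database suffix.  Until the global vote budget
``V`` is spent, the highest-scoring frontier is popped, the protein
owning its suffix receives one vote, and the frontier advances one
suffix-array position and is re-scored and re-queued.  The budget thus
concentrates on regions of the array that look most like the query,
instead of the fixed symmetric windows of classic SANS (retained here
as :func:`symmetric_sans`, the baseline and limiting case of a constant
score function).

Ties between equal frontier scores break first-in-first-out via a
monotone insertion counter, which makes the search fully deterministic.
Suffix-array positions whose suffix begins with the record delimiter
represent no residue: frontiers step over them without voting and
without spending budget.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from numba import njit

from .index import SuffixIndex
from .alphabet import SubstitutionMatrix

#: Minimum query-suffix length fed to the engine.
DEFAULT_MIN_SUFFIX = 8

#: Sentinel for "delimiter-initial suffix; never expand over".
SCORE_MIN = np.int64(-(1 << 62))


@dataclass
class VoteTable:
    """Per-protein vote counts accumulated by one query's search."""

    votes: np.ndarray  # int64 per protein ordinal
    budget_used: int
    #: votes spent by each frontier (asymmetric search only), for diagnostics
    frontier_expansions: np.ndarray | None = None

    def nonzero(self) -> dict[int, int]:
        idx = np.nonzero(self.votes)[0]
        return {int(i): int(self.votes[i]) for i in idx}


def _compare_suffix(text: np.ndarray, tpos: int, q: np.ndarray) -> int:
    """-1/0/+1 comparison of the text suffix at ``tpos`` against ``q``.

    A text suffix that runs out of characters first is the smaller; a
    query that is a prefix of the text suffix compares smaller (0 is
    returned only for an exact full-length match of both).
    """
    m = min(len(text) - tpos, len(q))
    a = text[tpos : tpos + m]
    b = q[:m]
    neq = np.nonzero(a != b)[0]
    if neq.size:
        i = neq[0]
        return -1 if a[i] < b[i] else 1
    if len(text) - tpos < len(q):
        return -1
    if len(text) - tpos > len(q):
        return 1
    return 0


def insertion_point(index: SuffixIndex, q_codes: np.ndarray) -> int:
    """Leftmost suffix-array position where ``q_codes`` could be inserted
    preserving collation order (lower-bound semantics)."""
    sa = index.sa
    lo, hi = 0, len(sa)
    while lo < hi:
        mid = (lo + hi) // 2
        if _compare_suffix(index.text, int(sa[mid]), q_codes) < 0:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def _seed_score_kernel(text, sa, mat, q_codes, q_mask, q_start, sa_pos, delim_dist):
    """Max gapless prefix-sum score of query suffix vs suffix at sa_pos.

    Masked query positions contribute 0.  Scoring stops at the query end,
    the text end, or the first database delimiter.  Delimiter-initial
    suffixes score the sentinel minimum.
    """
    t0 = sa[sa_pos]
    lim = delim_dist[t0]
    if lim == 0:
        return SCORE_MIN
    rem = len(q_codes) - q_start
    if rem < lim:
        lim = rem
    s = np.int64(0)
    best = SCORE_MIN
    for i in range(lim):
        if not q_mask[q_start + i]:
            s += mat[q_codes[q_start + i], text[t0 + i]]
        if s > best:
            best = s
    return best


def seed_score(
    index: SuffixIndex,
    matrix: SubstitutionMatrix,
    q_codes: np.ndarray,
    q_start: int,
    sa_pos: int,
    q_mask: np.ndarray | None = None,
) -> int:
    """Scored-seed value for one (query suffix, suffix-array position) pair."""
    if not 0 <= sa_pos < len(index.sa):
        raise IndexError(f"suffix array position {sa_pos} out of range")
    if q_mask is None:
        q_mask = np.zeros(len(q_codes), dtype=np.bool_)
    mat = matrix.rank_scores(index.ordering)
    s = _seed_score_kernel(
        index.text,
        index.sa,
        mat,
        np.asarray(q_codes, dtype=np.uint8),
        q_mask.astype(np.bool_),
        q_start,
        sa_pos,
        index.delim_dist,
    )
    return int(s)


# ---------------------------------------------------------------------------
# Frontier machinery


@njit(cache=True)
def _skip_delims(sa, delim_dist, pos, step):
    nsa = len(sa)
    while 0 <= pos < nsa and delim_dist[sa[pos]] == 0:
        pos += step
    return pos


@njit(cache=True)
def _heap_less(score, counter, a, b):
    # max-heap on score, FIFO (min counter) among ties
    if score[a] != score[b]:
        return score[a] > score[b]
    return counter[a] < counter[b]


@njit(cache=True)
def _heap_push(heap, size, score, counter, f):
    heap[size] = f
    i = size
    while i > 0:
        p = (i - 1) // 2
        if _heap_less(score, counter, heap[i], heap[p]):
            heap[i], heap[p] = heap[p], heap[i]
            i = p
        else:
            break
    return size + 1


@njit(cache=True)
def _heap_sift_down(heap, size, score, counter):
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        best = i
        if l < size and _heap_less(score, counter, heap[l], heap[best]):
            best = l
        if r < size and _heap_less(score, counter, heap[r], heap[best]):
            best = r
        if best == i:
            break
        heap[i], heap[best] = heap[best], heap[i]
        i = best


@njit(cache=True)
def _heap_pop(heap, size, score, counter):
    top = heap[0]
    size -= 1
    heap[0] = heap[size]
    _heap_sift_down(heap, size, score, counter)
    return top, size


@njit(cache=True)
def _init_frontier_arrays(text, sa, mat, q_codes, q_mask, starts, ks, delim_dist, constant_mode):
    max_f = 2 * len(starts)
    pos = np.empty(max_f, dtype=np.int64)
    qstart = np.empty(max_f, dtype=np.int64)
    direction = np.empty(max_f, dtype=np.int8)
    score = np.empty(max_f, dtype=np.int64)
    counter = np.empty(max_f, dtype=np.int64)
    nf = 0
    for s_i in range(len(starts)):
        k = ks[s_i]
        # upper frontier: starts at k, moves up
        p = _skip_delims(sa, delim_dist, k, 1)
        if 0 <= p < len(sa):
            pos[nf] = p
            qstart[nf] = starts[s_i]
            direction[nf] = 1
            if constant_mode:
                score[nf] = 0
            else:
                score[nf] = _seed_score_kernel(
                    text, sa, mat, q_codes, q_mask, starts[s_i], p, delim_dist
                )
            counter[nf] = nf
            nf += 1
        # lower frontier: starts at k - 1, moves down
        p = _skip_delims(sa, delim_dist, k - 1, -1)
        if 0 <= p < len(sa):
            pos[nf] = p
            qstart[nf] = starts[s_i]
            direction[nf] = -1
            if constant_mode:
                score[nf] = 0
            else:
                score[nf] = _seed_score_kernel(
                    text, sa, mat, q_codes, q_mask, starts[s_i], p, delim_dist
                )
            counter[nf] = nf
            nf += 1
    return pos[:nf], qstart[:nf], direction[:nf], score[:nf], counter[:nf]


@njit(cache=True)
def _sans_kernel(
    text,
    sa,
    prot_of_pos,
    mat,
    q_codes,
    q_mask,
    starts,
    ks,
    V,
    n_proteins,
    delim_dist,
    constant_mode,
):
    votes = np.zeros(n_proteins, dtype=np.int64)
    pos, qstart, direction, score, counter = _init_frontier_arrays(
        text, sa, mat, q_codes, q_mask, starts, ks, delim_dist, constant_mode
    )
    nf = len(pos)
    heap = np.empty(nf, dtype=np.int64)
    expansions = np.zeros(nf, dtype=np.int64)
    size = 0
    for f in range(nf):
        size = _heap_push(heap, size, score, counter, f)
    next_counter = np.int64(nf)
    budget = np.int64(0)
    nsa = len(sa)
    while budget < V and size > 0:
        f = heap[0]
        votes[prot_of_pos[sa[pos[f]]]] += 1
        expansions[f] += 1
        budget += 1
        p = _skip_delims(sa, delim_dist, pos[f] + direction[f], direction[f])
        if 0 <= p < nsa:
            # replace-top: rescore in place and restore the heap once
            pos[f] = p
            if constant_mode:
                score[f] = 0
            else:
                score[f] = _seed_score_kernel(
                    text, sa, mat, q_codes, q_mask, qstart[f], p, delim_dist
                )
            counter[f] = next_counter
            next_counter += 1
            _heap_sift_down(heap, size, score, counter)
        else:
            _, size = _heap_pop(heap, size, score, counter)
    return votes, budget, expansions


def query_suffix_starts(q_len: int, min_suffix: int = DEFAULT_MIN_SUFFIX) -> np.ndarray:
    """Start offsets of the query suffixes fed to the engine."""
    if q_len < min_suffix:
        return np.empty(0, dtype=np.int64)
    return np.arange(0, q_len - min_suffix + 1, dtype=np.int64)


def _prepare_query(index, matrix, q_codes, q_mask, min_suffix):
    q_codes = np.asarray(q_codes, dtype=np.uint8)
    if q_mask is None:
        q_mask = np.zeros(len(q_codes), dtype=np.bool_)
    q_mask = np.asarray(q_mask, dtype=np.bool_)
    starts = query_suffix_starts(len(q_codes), min_suffix)
    ks = np.array(
        [insertion_point(index, q_codes[s:]) for s in starts], dtype=np.int64
    )
    mat = matrix.rank_scores(index.ordering)
    return q_codes, q_mask, starts, ks, mat


def init_frontiers(
    index: SuffixIndex,
    matrix: SubstitutionMatrix,
    q_codes: np.ndarray,
    q_mask: np.ndarray | None = None,
    min_suffix: int = DEFAULT_MIN_SUFFIX,
) -> list[dict]:
    """Initial frontier states (for inspection and tests)."""
    q_codes, q_mask, starts, ks, mat = _prepare_query(
        index, matrix, q_codes, q_mask, min_suffix
    )
    if len(starts) == 0:
        return []
    pos, qstart, direction, score, counter = _init_frontier_arrays(
        index.text, index.sa, mat, q_codes, q_mask, starts, ks,
        index.delim_dist, False,
    )
    return [
        {
            "position": int(pos[i]),
            "q_start": int(qstart[i]),
            "direction": "upper" if direction[i] == 1 else "lower",
            "score": int(score[i]),
        }
        for i in range(len(pos))
    ]


def asymmetric_sans(
    index: SuffixIndex,
    matrix: SubstitutionMatrix,
    q_codes: np.ndarray,
    V: int,
    q_mask: np.ndarray | None = None,
    min_suffix: int = DEFAULT_MIN_SUFFIX,
    constant_score: bool = False,
) -> VoteTable:
    """Run the budgeted asymmetric search for one encoded query.

    ``constant_score=True`` replaces the scored-seed function with a
    constant, reducing the search to round-robin frontier expansion (the
    symmetric-window limit); used for validation.
    """
    if V < 0:
        raise ValueError("vote budget must be >= 0")
    q_codes, q_mask, starts, ks, mat = _prepare_query(
        index, matrix, q_codes, q_mask, min_suffix
    )
    if len(starts) == 0 or V == 0:
        return VoteTable(np.zeros(index.n_proteins, dtype=np.int64), 0)
    votes, used, expansions = _sans_kernel(
        index.text,
        index.sa,
        index.protein_of_pos,
        mat,
        q_codes,
        q_mask,
        starts,
        ks,
        np.int64(V),
        index.n_proteins,
        index.delim_dist,
        constant_score,
    )
    return VoteTable(votes, int(used), expansions)


def symmetric_sans(
    index: SuffixIndex,
    q_codes: np.ndarray,
    W: int,
    min_suffix: int = DEFAULT_MIN_SUFFIX,
) -> VoteTable:
    """Classic SANS: a fixed window of ``W`` suffix-array positions per
    query suffix (floor(W/2) below the insertion point, ceil(W/2) at and
    above), clipped at the array ends; delimiter-initial positions are
    skipped without replacement."""
    if W < 0:
        raise ValueError("window must be >= 0")
    q_codes = np.asarray(q_codes, dtype=np.uint8)
    votes = np.zeros(index.n_proteins, dtype=np.int64)
    used = 0
    delim = index.ordering.delimiter_rank
    nsa = len(index.sa)
    for s in query_suffix_starts(len(q_codes), min_suffix):
        k = insertion_point(index, q_codes[s:])
        lo = max(0, k - W // 2)
        hi = min(nsa, k + (W + 1) // 2)
        for p in range(lo, hi):
            tpos = int(index.sa[p])
            if index.text[tpos] == delim:
                continue
            votes[index.protein_of_pos[tpos]] += 1
            used += 1
    return VoteTable(votes, used)


def expandable_positions(
    index: SuffixIndex,
    q_codes: np.ndarray,
    min_suffix: int = DEFAULT_MIN_SUFFIX,
) -> int:
    """Total votes available to a query if the budget were unlimited."""
    q_codes = np.asarray(q_codes, dtype=np.uint8)
    delim = index.ordering.delimiter_rank
    non_delim = index.text[index.sa] != delim
    prefix = np.concatenate([[0], np.cumsum(non_delim)])
    total = 0
    for s in query_suffix_starts(len(q_codes), min_suffix):
        k = insertion_point(index, q_codes[s:])
        total += prefix[len(index.sa)] - prefix[k]  # upper frontier sweep
        total += prefix[k]  # lower frontier sweep
    return int(total)


def top_candidates(vt: VoteTable, N: int) -> list[int]:
    """Top-``N`` protein ordinals by (votes desc, ordinal asc).

    Maintained with a bounded min-heap so at most ``N`` candidates are
    tracked at any time.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    heap: list[tuple[int, int]] = []  # (votes, -ordinal); min-heap evicts worst
    idx = np.nonzero(vt.votes)[0]
    for i in idx:
        item = (int(vt.votes[i]), -int(i))
        if len(heap) < N:
            heapq.heappush(heap, item)
        elif item > heap[0]:
            heapq.heapreplace(heap, item)
    ranked = sorted(heap, key=lambda t: (-t[0], -t[1]))
    return [-o for _, o in ranked]
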