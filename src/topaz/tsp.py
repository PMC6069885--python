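"""TSP solvers for the optimal substitution ordering.

Finding the collation order that minimises the summed quasi-distance
between adjacent symbols (including the edge closing the cycle) is a
travelling-salesman problem over the 25 alphabet symbols.  Two solvers
are provided: an exact Held-Karp dynamic program for small sub-alphabets
and a 2-opt/Or-opt local search with random restarts for the full
alphabet, where the bitmask DP is no longer desk-sized.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .alphabet import AlphabetOrdering, QuasiDistanceMatrix

#: Largest sub-alphabet the exact solver accepts (2^n * n * 8 bytes of DP).
EXACT_LIMIT = 18


class TSPSizeError(ValueError):
    """Exact solver asked for a problem beyond its bitmask-DP bound."""


@njit(cache=True)
def _held_karp(dist):
    n = dist.shape[0]
    full = 1 << n
    INF = np.int64(1) << 60
    # dp[mask, j]: cheapest path over `mask` starting at 0 and ending at j
    dp = np.full((full, n), INF, dtype=np.int64)
    parent = np.full((full, n), -1, dtype=np.int32)
    dp[1, 0] = 0
    for mask in range(3, full, 2):  # masks containing city 0
        for j in range(1, n):
            if not mask & (1 << j):
                continue
            prev_mask = mask ^ (1 << j)
            best = INF
            arg = -1
            for i in range(n):
                if not prev_mask & (1 << i):
                    continue
                if dp[prev_mask, i] >= INF:
                    continue
                c = dp[prev_mask, i] + dist[i, j]
                if c < best:
                    best = c
                    arg = i
            dp[mask, j] = best
            parent[mask, j] = arg
    best = INF
    last = -1
    for j in range(1, n):
        c = dp[full - 1, j] + dist[j, 0]
        if c < best:
            best = c
            last = j
    tour = np.empty(n, dtype=np.int32)
    mask = full - 1
    j = last
    for pos in range(n - 1, -1, -1):
        tour[pos] = j
        nj = parent[mask, j]
        mask ^= 1 << j
        j = nj
    return tour, best


@njit(cache=True)
def _tour_cost(tour, dist):
    n = tour.shape[0]
    total = np.int64(0)
    for i in range(n):
        total += dist[tour[i], tour[(i + 1) % n]]
    return total


@njit(cache=True)
def _two_opt(tour, dist):
    """In-place 2-opt + Or-opt (segment lengths 1-3) to a local optimum."""
    n = tour.shape[0]
    improved = True
    while improved:
        improved = False
        # 2-opt: reverse tour[i+1..j]
        for i in range(n - 1):
            a, b = tour[i], tour[i + 1]
            for j in range(i + 2, n):
                c = tour[j]
                d = tour[(j + 1) % n]
                if i == 0 and (j + 1) % n == 0:
                    continue
                delta = dist[a, c] + dist[b, d] - dist[a, b] - dist[c, d]
                if delta < 0:
                    lo, hi = i + 1, j
                    while lo < hi:
                        tour[lo], tour[hi] = tour[hi], tour[lo]
                        lo += 1
                        hi -= 1
                    improved = True
                    b = tour[i + 1]
        # Or-opt: relocate short segments
        for seg in range(1, 4):
            for i in range(n - seg):
                p = tour[(i - 1) % n]
                s0 = tour[i]
                s1 = tour[i + seg - 1]
                q = tour[(i + seg) % n]
                removal = dist[p, s0] + dist[s1, q] - dist[p, q]
                for j in range(n):
                    if i - 1 <= j <= i + seg - 1:
                        continue
                    u = tour[j]
                    v = tour[(j + 1) % n]
                    if (j + 1) % n == i:
                        continue
                    delta = dist[u, s0] + dist[s1, v] - dist[u, v] - removal
                    if delta < 0:
                        segment = tour[i : i + seg].copy()
                        keep = np.empty(n - seg, dtype=tour.dtype)
                        w = 0
                        for t in range(n):
                            if t < i or t >= i + seg:
                                keep[w] = tour[t]
                                w += 1
                        # position of u in `keep`
                        for t in range(n - seg):
                            if keep[t] == u:
                                pos = t
                                break
                        w = 0
                        for t in range(pos + 1):
                            tour[w] = keep[t]
                            w += 1
                        for t in range(seg):
                            tour[w] = segment[t]
                            w += 1
                        for t in range(pos + 1, n - seg):
                            tour[w] = keep[t]
                            w += 1
                        improved = True
                        break
                else:
                    continue
                break
    return tour


def _canonical(order: str) -> str:
    """Rotate a cyclic ordering to start at its first symbol alphabetically
    and pick the lexicographically smaller direction, so equal cycles
    compare equal as strings."""
    n = len(order)
    start = order.index(min(order))
    fwd = "".join(order[(start + i) % n] for i in range(n))
    rev = "".join(order[(start - i) % n] for i in range(n))
    return min(fwd, rev)


def _subset_distances(qd: QuasiDistanceMatrix, subset: str) -> np.ndarray:
    if len(subset) != len(set(subset)):
        raise ValueError("subset contains duplicate symbols")
    idx = [qd.symbols.index(c) for c in subset]
    return np.ascontiguousarray(qd.dist[np.ix_(idx, idx)]).astype(np.int64)


def solve_ordering_exact(
    qd: QuasiDistanceMatrix, subset: str | None = None
) -> tuple[AlphabetOrdering, int]:
    """Provably minimal cyclic ordering of ``subset`` by Held-Karp DP.

    Raises :class:`TSPSizeError` above :data:`EXACT_LIMIT` symbols; use
    :func:`solve_ordering_heuristic` for the full alphabet.
    """
    subset = qd.symbols if subset is None else subset
    if len(subset) > EXACT_LIMIT:
        raise TSPSizeError(
            f"{len(subset)} symbols exceeds the exact bound of {EXACT_LIMIT}; "
            "use solve_ordering_heuristic"
        )
    if len(subset) < 2:
        raise ValueError("need at least 2 symbols")
    dist = _subset_distances(qd, subset)
    tour, cost = _held_karp(dist)
    order = _canonical("".join(subset[i] for i in tour))
    return AlphabetOrdering(order=order), int(cost)


def solve_ordering_heuristic(
    qd: QuasiDistanceMatrix,
    subset: str | None = None,
    restarts: int = 200,
    seed: int = 0,
) -> tuple[AlphabetOrdering, int]:
    """Best cyclic ordering found by 2-opt/Or-opt over random restarts.

    Deterministic for a fixed seed; the returned cost is recomputed from
    the returned tour.
    """
    subset = qd.symbols if subset is None else subset
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    dist = _subset_distances(qd, subset)
    n = len(subset)
    rng = np.random.default_rng(seed)
    best_tour = None
    best_cost = None
    for _ in range(restarts):
        tour = rng.permutation(n).astype(np.int32)
        tour = _two_opt(tour, dist)
        cost = int(_tour_cost(tour, dist))
        if best_cost is None or cost < best_cost:
            best_cost = cost
            best_tour = tour.copy()
    order = _canonical("".join(subset[i] for i in best_tour))
    return AlphabetOrdering(order=order), best_cost
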