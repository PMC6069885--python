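"""Synthetic proteomes and graded-identity homolog benchmarks.

Decoy proteins are drawn i.i.d. from the BLOSUM62 background residue
frequencies (the Robinson-Robinson-style composition the matrix was
built against), and homologs are derived by substituting a fixed number
of positions with residues sampled from the BLOSUM62-conditional
substitution preference P(b | a) ~ p_b * 2^(score(a,b)/2), excluding the
identity.  This keeps synthetic homology statistically consistent with
the scoring matrix the engine uses.  Planted identities are exact by
construction (substitutions only; indels are available but off by
default so identity accounting stays exact).

These fixtures emulate composition and graded divergence, not real
protein features: no domain structure, no true indel patterns, no
low-complexity regions beyond what i.i.d. sampling produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alphabet import SubstitutionMatrix, load_matrix
from .index import ProteinDatabase, ProteinRecord

#: Standard residues, in BLOSUM62 background-frequency table order.
STANDARD_RESIDUES = "ARNDCQEGHILKMFPSTWYV"

#: BLOSUM62 background amino-acid frequencies (normalized below).
_BACKGROUND = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}


def background_frequencies() -> np.ndarray:
    """Background residue probabilities in :data:`STANDARD_RESIDUES` order."""
    p = np.array([_BACKGROUND[c] for c in STANDARD_RESIDUES])
    return p / p.sum()


def substitution_preferences(matrix: SubstitutionMatrix | None = None) -> np.ndarray:
    """Row-stochastic P(b | a) over standard residues, identity excluded.

    Derived from the matrix's log-odds form: target frequencies are
    proportional to ``p_a * p_b * 2**(score/2)`` for a half-bit matrix.
    """
    matrix = matrix or load_matrix("BLOSUM62")
    p = background_frequencies()
    n = len(STANDARD_RESIDUES)
    pref = np.zeros((n, n))
    for i, a in enumerate(STANDARD_RESIDUES):
        for j, b in enumerate(STANDARD_RESIDUES):
            if i == j:
                continue
            pref[i, j] = p[j] * 2.0 ** (matrix.score(a, b) / 2.0)
        pref[i] /= pref[i].sum()
    return pref


def random_proteome(
    n: int,
    length_range: tuple[int, int] = (60, 120),
    seed: int = 0,
    prefix: str = "decoy",
) -> ProteinDatabase:
    """``n`` i.i.d. random proteins with BLOSUM62 background composition."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length range")
    rng = np.random.default_rng(seed)
    p = background_frequencies()
    residues = np.frombuffer(STANDARD_RESIDUES.encode(), dtype=np.uint8)
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = residues[rng.choice(len(residues), size=length, p=p)].tobytes().decode()
        records.append(ProteinRecord(f"{prefix}{i}", "", seq))
    return ProteinDatabase(records=records)


def mutate_homolog(
    seq: str,
    identity_target: float,
    seed: int = 0,
    indels: bool = False,
    matrix: SubstitutionMatrix | None = None,
) -> str:
    """Substitute ``ceil((1 - identity) * len)`` positions of ``seq``.

    Positions are chosen uniformly without replacement; replacement
    residues follow the BLOSUM62-conditional preference and never equal
    the original residue, so pairwise identity is exact.  With
    ``indels=True`` a single short (1-3 residue) deletion is additionally
    introduced, making identity approximate.
    """
    if not 0 < identity_target <= 1:
        raise ValueError("identity target must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_sub = math.ceil((1.0 - identity_target) * len(seq))
    out = list(seq)
    if n_sub:
        pref = substitution_preferences(matrix)
        idx = {c: i for i, c in enumerate(STANDARD_RESIDUES)}
        positions = rng.choice(len(seq), size=n_sub, replace=False)
        for pos in positions:
            row = pref[idx[seq[pos]]]
            out[pos] = STANDARD_RESIDUES[rng.choice(len(row), p=row)]
    if indels and len(out) > 10:
        start = int(rng.integers(1, len(out) - 4))
        del out[start : start + int(rng.integers(1, 4))]
    return "".join(out)


@dataclass(frozen=True)
class BenchmarkSet:
    """A decoy proteome with planted homolog families and their truth."""

    database: ProteinDatabase
    queries: ProteinDatabase
    #: query_id -> {subject_id: target identity}
    truth: dict[str, dict[str, float]]
    seed: int


def benchmark_set(
    db_size: int = 5_000,
    homologs_per_query: int = 3,
    identity_grid: tuple[float, ...] = (0.9, 0.7, 0.5),
    seed: int = 0,
    n_queries: int = 20,
    length_range: tuple[int, int] = (60, 120),
) -> BenchmarkSet:
    """Plant graded-identity homolog families inside a random proteome.

    Each of ``n_queries`` random query proteins gets
    ``homologs_per_query`` mutated copies per identity level appended to
    the decoy database; ``truth`` records every planted pair.
    """
    if db_size < 1 or homologs_per_query < 1 or n_queries < 1:
        raise ValueError("sizes must be positive")
    if not all(0 < t <= 1 for t in identity_grid):
        raise ValueError("identities must be in (0, 1]")
    decoys = random_proteome(db_size, length_range, seed=seed)
    qdb = random_proteome(n_queries, length_range, seed=seed + 1, prefix="query")
    records = list(decoys.records)
    truth: dict[str, dict[str, float]] = {}
    child = np.random.default_rng(seed + 2)
    for q in qdb.records:
        truth[q.id] = {}
        for ident in identity_grid:
            for j in range(homologs_per_query):
                hom_seed = int(child.integers(0, 2**31 - 1))
                hseq = mutate_homolog(q.sequence, ident, seed=hom_seed)
                hid = f"{q.id}_h{int(ident * 100)}_{j}"
                records.append(ProteinRecord(hid, "", hseq))
                truth[q.id][hid] = ident
    return BenchmarkSet(
        database=ProteinDatabase(records=records),
        queries=qdb,
        truth=truth,
        seed=seed,
    )


def write_fasta(db: ProteinDatabase, path) -> None:
    with open(path, "w") as fh:
        for rec in db.records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
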