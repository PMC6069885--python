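"""Amino-acid alphabet, substitution matrices and collation orderings.

The search engine collates database suffixes under a permutation of a
25-symbol alphabet: the 20 standard residues, the ambiguity codes B
(D/N), Z (E/Q), J (I/L), the wildcard X, and the record delimiter '*'.
Placing residues with high substitution scores next to each other in
the collation order keeps homologous suffixes close together in the
suffix array, which is what the optimal substitution ordering below is
minimising (see :mod:`topaz.tsp`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

#: Canonical symbol order used to store matrices (NCBI order + J, '*' last).
SYMBOLS = "ARNDCQEGHILKMFPSTWYVBZXJ*"

#: Record delimiter appended after every database sequence.
DELIMITER = "*"

#: Collation order minimising summed substitution quasi-distances between
#: adjacent symbols (cyclic), computed from BLOSUM62.  Many co-optimal
#: orderings exist; this one is the shipped default for index construction.
OPTIMAL_ORDERING = "ACMLJIVTSKRQZEDBNHYFWXP*G"

# Residues outside the 25-symbol alphabet are mapped to X on input.
_RARE_RESIDUES = {"U": "X", "O": "X"}


class AlphabetError(ValueError):
    """Raised for unknown matrices, malformed matrix files or bad symbols."""


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric integer substitution scores over the 25-symbol alphabet."""

    symbols: str
    scores: np.ndarray  # (25, 25) int
    name: str
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if len(self.symbols) != len(set(self.symbols)):
            raise AlphabetError("duplicate symbols in alphabet")
        if self.scores.shape != (len(self.symbols), len(self.symbols)):
            raise AlphabetError("score matrix shape does not match alphabet")
        if not np.array_equal(self.scores, self.scores.T):
            raise AlphabetError(f"matrix {self.name!r} is not symmetric")
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.symbols)})

    def score(self, a: str, b: str) -> int:
        return int(self.scores[self._index[a], self._index[b]])

    def rank_scores(self, ordering: "AlphabetOrdering") -> np.ndarray:
        """Score matrix permuted so it can be indexed by ordering ranks."""
        perm = np.array([self._index[c] for c in ordering.order])
        return np.ascontiguousarray(self.scores[np.ix_(perm, perm)]).astype(np.int64)


@dataclass(frozen=True)
class QuasiDistanceMatrix:
    """Non-negative TSP distances derived from a substitution matrix.

    Off-diagonal distances are ``-score + 5``; self-distances are 0.  With
    BLOSUM62 (largest off-diagonal score +4) all distances are >= 1.
    """

    symbols: str
    dist: np.ndarray  # (25, 25) int
    derived_from: str

    def distance(self, a: str, b: str) -> int:
        i, j = self.symbols.index(a), self.symbols.index(b)
        return int(self.dist[i, j])


@dataclass(frozen=True)
class AlphabetOrdering:
    """A permutation of the alphabet defining suffix-array collation order."""

    order: str
    rank: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if len(self.order) != len(set(self.order)):
            raise AlphabetError("ordering is not a permutation (duplicates)")
        object.__setattr__(self, "rank", {c: i for i, c in enumerate(self.order)})

    def __len__(self) -> int:
        return len(self.order)

    def encode(self, seq: str) -> np.ndarray:
        """Map a (normalized) residue string to a uint8 rank vector."""
        out = np.empty(len(seq), dtype=np.uint8)
        rank = self.rank
        for i, c in enumerate(seq):
            try:
                out[i] = rank[c]
            except KeyError:
                raise AlphabetError(
                    f"unmappable character {c!r} at position {i}"
                ) from None
        return out

    def decode(self, codes: np.ndarray) -> str:
        return "".join(self.order[int(c)] for c in codes)

    @property
    def delimiter_rank(self) -> int:
        return self.rank[DELIMITER]


def normalize_sequence(seq: str) -> str:
    """Uppercase and map rare residues (U, O) to X."""
    s = seq.upper()
    for raw, repl in _RARE_RESIDUES.items():
        s = s.replace(raw, repl)
    return s


def _complete_with_j(bio_matrix) -> tuple[str, np.ndarray]:
    """Extend a 24-symbol NCBI matrix (no J row) to the 25-symbol alphabet.

    J (I or L) scores are the truncated-toward-zero average of the I and L
    rows; J-vs-J averages the four I/L self and cross scores.  This matches
    the common extended-BLOSUM62 convention (J/J = 3, J/I = J/L = 3).
    """
    alpha = "".join(bio_matrix.alphabet)
    base = {a: {b: int(bio_matrix[a, b]) for b in alpha} for a in alpha}
    scores = np.zeros((len(SYMBOLS), len(SYMBOLS)), dtype=np.int64)
    for i, a in enumerate(SYMBOLS):
        for j, b in enumerate(SYMBOLS):
            if a == "J" and b == "J":
                v = (base["I"]["I"] + base["I"]["L"] + base["L"]["I"] + base["L"]["L"]) / 4
            elif a == "J":
                v = (base["I"][b] + base["L"][b]) / 2
            elif b == "J":
                v = (base[a]["I"] + base[a]["L"]) / 2
            else:
                v = base[a][b]
            scores[i, j] = int(v)  # int() truncates toward zero
    return SYMBOLS, scores


def load_matrix(name: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a built-in matrix by name, or an NCBI-format matrix text file.

    Built-in matrices come from the canonical NCBI tables and are completed
    to the 25-symbol alphabet (J synthesised from I/L when absent).
    """
    import os

    if os.path.exists(str(name)):
        try:
            with open(name) as fh:
                bio = substitution_matrices.read(fh)
        except Exception as exc:  # biopython raises mixed types on bad input
            raise AlphabetError(f"cannot parse matrix file {name!r}: {exc}") from None
    else:
        try:
            bio = substitution_matrices.load(name)
        except FileNotFoundError:
            raise AlphabetError(f"unknown substitution matrix {name!r}") from None
    alpha = "".join(bio.alphabet)
    missing = set(SYMBOLS) - set(alpha) - {"J"}
    if missing:
        raise AlphabetError(
            f"matrix {name!r} lacks required symbols: {sorted(missing)}"
        )
    symbols, scores = _complete_with_j(bio) if "J" not in alpha else (None, None)
    if symbols is None:
        idx = {c: i for i, c in enumerate(alpha)}
        perm = np.array([idx[c] for c in SYMBOLS])
        scores = np.asarray(bio).astype(np.int64)[np.ix_(perm, perm)]
        symbols = SYMBOLS
    return SubstitutionMatrix(symbols=symbols, scores=scores, name=str(name))


def quasi_distances(matrix: SubstitutionMatrix) -> QuasiDistanceMatrix:
    """Convert substitution scores to TSP quasi-distances.

    ``dist(a, b) = -score(a, b) + 5`` for a != b and ``dist(a, a) = 0``.
    """
    d = -matrix.scores + 5
    np.fill_diagonal(d, 0)
    if (d < 0).any():
        raise AlphabetError(
            f"matrix {matrix.name!r} has off-diagonal scores > 5; "
            "quasi-distances would be negative"
        )
    return QuasiDistanceMatrix(symbols=matrix.symbols, dist=d, derived_from=matrix.name)


def lexicographic_ordering(symbols: str = SYMBOLS) -> AlphabetOrdering:
    """Plain character-code ordering of the alphabet ('*' collates first)."""
    return AlphabetOrdering(order="".join(sorted(symbols)))


def optimal_ordering() -> AlphabetOrdering:
    """The shipped BLOSUM62-optimised collation ordering."""
    return AlphabetOrdering(order=OPTIMAL_ORDERING)


def cycle_cost(order: str, qd: QuasiDistanceMatrix) -> int:
    """Total quasi-distance around the cyclic tour spelled by ``order``.

    Includes the closing edge between the last and first symbol.
    """
    if set(order) != set(qd.symbols) or len(order) != len(qd.symbols):
        raise AlphabetError("ordering symbols do not match distance matrix")
    idx = {c: i for i, c in enumerate(qd.symbols)}
    total = 0
    for a, b in zip(order, order[1:] + order[0]):
        total += int(qd.dist[idx[a], idx[b]])
    return total
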