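import numpy as np
import pytest

import topaz as tz


@pytest.fixture(scope="session")
def blosum62():
    return tz.load_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def ordering():
    return tz.optimal_ordering()


@pytest.fixture(scope="session")
def lex_ordering():
    return tz.lexicographic_ordering()


@pytest.fixture(scope="session")
def quasi(blosum62):
    return tz.quasi_distances(blosum62)


def random_database(rng, n_proteins, length_range=(10, 40)):
    """Small random database for index/search unit tests."""
    from topaz.synthetic import STANDARD_RESIDUES

    residues = np.frombuffer(STANDARD_RESIDUES.encode(), dtype=np.uint8)
    pairs = []
    for i in range(n_proteins):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = residues[rng.integers(0, len(residues), size=length)].tobytes().decode()
        pairs.append((f"p{i}", seq))
    return tz.database_from_sequences(pairs)


def naive_suffix_array(text_codes):
    """Comparison-sort oracle for the suffix array (bytes compare)."""
    b = bytes(bytearray(int(c) for c in text_codes))
    return sorted(range(len(b)), key=lambda i: b[i:])


def brute_seed_score(index, matrix, q_codes, q_start, sa_pos, q_mask=None):
    """Enumerate every prefix length of the gapless seed and take the max."""
    mat = matrix.rank_scores(index.ordering)
    t0 = int(index.sa[sa_pos])
    text = index.text
    delim = index.ordering.delimiter_rank
    if text[t0] == delim:
        return None  # sentinel minimum in the implementation
    best = None
    s = 0
    i = 0
    while q_start + i < len(q_codes) and t0 + i < len(text) and text[t0 + i] != delim:
        c = 0 if (q_mask is not None and q_mask[q_start + i]) else int(
            mat[q_codes[q_start + i], text[t0 + i]]
        )
        s += c
        best = s if best is None else max(best, s)
        i += 1
    return best


def dp_local_affine(q, s, matrix, gap_open=11, gap_extend=1):
    """Textbook three-matrix affine-gap Smith-Waterman oracle (score only).

    Full O(|q|*|s|) matrices, no striping, written independently of the
    package's scoring kernels.  First gap position costs open + extend.
    """
    nq, ns = len(q), len(s)
    NEG = -(10**9)
    H = np.zeros((nq + 1, ns + 1), dtype=np.int64)
    E = np.full((nq + 1, ns + 1), NEG, dtype=np.int64)  # gap in q
    F = np.full((nq + 1, ns + 1), NEG, dtype=np.int64)  # gap in s
    best = 0
    for i in range(1, nq + 1):
        for j in range(1, ns + 1):
            E[i, j] = max(E[i, j - 1] - gap_extend, H[i, j - 1] - gap_open - gap_extend)
            F[i, j] = max(F[i - 1, j] - gap_extend, H[i - 1, j] - gap_open - gap_extend)
            diag = H[i - 1, j - 1] + matrix.score(q[i - 1], s[j - 1])
            H[i, j] = max(0, diag, E[i, j], F[i, j])
            if H[i, j] > best:
                best = int(H[i, j])
    return best
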