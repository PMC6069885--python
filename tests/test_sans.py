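import numpy as np
import pytest

import topaz as tz
from topaz.sans import (
    SCORE_MIN,
    expandable_positions,
    init_frontiers,
    query_suffix_starts,
    seed_score,
)

from conftest import brute_seed_score, random_database


@pytest.fixture(scope="module")
def small_index(blosum62, ordering):
    db = random_database(np.random.default_rng(42), 25, (15, 35))
    return db, tz.build_index(db, ordering, blosum62)


def linear_scan_lower_bound(index, q_codes):
    """Lower-bound oracle: first SA position whose suffix collates >= query."""
    b_text = bytes(bytearray(int(c) for c in index.text))
    b_q = bytes(bytearray(int(c) for c in q_codes))
    for j, start in enumerate(index.sa):
        if b_text[start:] >= b_q:
            return j
    return len(index.sa)


class TestInsertionPoint:
    def test_matches_linear_scan(self, small_index, ordering):
        db, idx = small_index
        rng = np.random.default_rng(1)
        for _ in range(50):
            rec = db[int(rng.integers(0, len(db)))]
            start = int(rng.integers(0, len(rec.sequence) - 7))
            q = ordering.encode(rec.sequence[start:])
            assert tz.insertion_point(idx, q) == linear_scan_lower_bound(idx, q)

    def test_exact_suffix_found_at_leftmost_occurrence(self, small_index, ordering):
        db, idx = small_index
        q = ordering.encode(db[0].sequence)  # full first protein
        k = tz.insertion_point(idx, q)
        assert k == linear_scan_lower_bound(idx, q)

    def test_extremes(self, blosum62, ordering):
        db = tz.database_from_sequences([("w", "WWWWWWWWWW")])
        idx = tz.build_index(db, ordering, blosum62)
        before = ordering.encode("AAAAAAAA")  # A collates before W
        assert tz.insertion_point(idx, before) == 0
        after = ordering.encode("GGGGGGGG")  # G collates last
        assert tz.insertion_point(idx, after) == len(idx.sa)


class TestSeedScore:
    def test_worked_example(self, blosum62, ordering):
        # qs "AC" vs database suffix "AD...": prefix sums {4, 4-3} -> 4
        db = tz.database_from_sequences([("x", "ADKL")])
        idx = tz.build_index(db, ordering, blosum62)
        q = ordering.encode("AC")
        sa_pos = int(np.where(idx.sa == 0)[0][0])
        assert seed_score(idx, blosum62, q, 0, sa_pos) == 4
        # masking position 0 gives prefix sums {0, -3} -> 0
        mask = np.array([True, False])
        assert seed_score(idx, blosum62, q, 0, sa_pos, q_mask=mask) == 0

    def test_identical_suffix_scores_full_diagonal(self, blosum62, ordering):
        db = tz.database_from_sequences([("x", "ACDEFGHIKL")])
        idx = tz.build_index(db, ordering, blosum62)
        q = ordering.encode("ACDEFGHIKL")
        sa_pos = int(np.where(idx.sa == 0)[0][0])
        expected = sum(blosum62.score(c, c) for c in "ACDEFGHIKL")
        assert seed_score(idx, blosum62, q, 0, sa_pos) == expected

    def test_delimiter_initial_suffix_is_sentinel(self, blosum62, ordering):
        db = tz.database_from_sequences([("x", "AC")])
        idx = tz.build_index(db, ordering, blosum62)
        q = ordering.encode("AC")
        sa_pos = int(np.where(idx.sa == 2)[0][0])  # suffix "*"
        assert seed_score(idx, blosum62, q, 0, sa_pos) == int(SCORE_MIN)

    def test_matches_bruteforce_on_random_pairs(self, small_index, blosum62, ordering):
        db, idx = small_index
        rng = np.random.default_rng(5)
        for _ in range(300):
            rec = db[int(rng.integers(0, len(db)))]
            q = ordering.encode(rec.sequence)
            mask = rng.random(len(q)) < 0.2
            start = int(rng.integers(0, len(q) - 7))
            sa_pos = int(rng.integers(0, len(idx.sa)))
            expected = brute_seed_score(idx, blosum62, q, start, sa_pos, mask)
            got = seed_score(idx, blosum62, q, start, sa_pos, q_mask=mask)
            if expected is None:
                assert got == int(SCORE_MIN)
            else:
                assert got == expected


class TestFrontiers:
    def test_frontier_count(self, small_index, blosum62, ordering):
        db, idx = small_index
        seq = db[3].sequence
        q = ordering.encode(seq)
        fr = init_frontiers(idx, blosum62, q, min_suffix=8)
        n_suffixes = len(seq) - 8 + 1
        assert len(fr) <= 2 * n_suffixes
        # interior insertion points give both frontiers
        ups = sum(1 for f in fr if f["direction"] == "upper")
        downs = sum(1 for f in fr if f["direction"] == "lower")
        assert ups + downs == len(fr)

    def test_short_query_yields_no_frontiers(self, small_index, blosum62, ordering):
        _, idx = small_index
        assert init_frontiers(idx, blosum62, ordering.encode("ACDE")) == []
        assert query_suffix_starts(4, 8).size == 0

    def test_frontier_scores_recompute(self, small_index, blosum62, ordering):
        db, idx = small_index
        q = ordering.encode(db[7].sequence)
        for f in init_frontiers(idx, blosum62, q):
            assert f["score"] == seed_score(idx, blosum62, q, f["q_start"], f["position"])


class TestAsymmetricSans:
    def test_self_query_gets_most_votes(self, small_index, blosum62, ordering):
        db, idx = small_index
        q = ordering.encode(db[9].sequence)
        n_suffixes = len(q) - 8 + 1
        vt = tz.asymmetric_sans(idx, blosum62, q, V=4 * n_suffixes)
        assert int(np.argmax(vt.votes)) == 9
        assert vt.votes[9] == vt.votes.max()

    def test_zero_budget(self, small_index, blosum62, ordering):
        db, idx = small_index
        vt = tz.asymmetric_sans(idx, blosum62, ordering.encode(db[0].sequence), V=0)
        assert vt.budget_used == 0 and vt.votes.sum() == 0

    def test_budget_conservation(self, small_index, blosum62, ordering):
        db, idx = small_index
        q = ordering.encode(db[2].sequence)
        for V in (0, 50, 500, 10**7):
            vt = tz.asymmetric_sans(idx, blosum62, q, V=V)
            assert vt.votes.sum() == vt.budget_used
            assert vt.budget_used == min(V, expandable_positions(idx, q))

    def test_monotone_in_budget(self, small_index, blosum62, ordering):
        db, idx = small_index
        q = ordering.encode(db[4].sequence)
        prev = np.zeros(idx.n_proteins, dtype=np.int64)
        for V in (0, 100, 1000, 10000):
            vt = tz.asymmetric_sans(idx, blosum62, q, V=V)
            assert (vt.votes >= prev).all()
            prev = vt.votes

    def test_deterministic(self, small_index, blosum62, ordering):
        db, idx = small_index
        q = ordering.encode(db[5].sequence)
        a = tz.asymmetric_sans(idx, blosum62, q, V=2000)
        b = tz.asymmetric_sans(idx, blosum62, q, V=2000)
        assert np.array_equal(a.votes, b.votes)


class TestSymmetricSans:
    def test_zero_window(self, small_index, ordering):
        db, idx = small_index
        vt = tz.symmetric_sans(idx, ordering.encode(db[0].sequence), W=0)
        assert vt.votes.sum() == 0

    def test_single_suffix_window(self, blosum62, ordering):
        # one query suffix, W=2: exactly positions k-1 and k are voted
        db = random_database(np.random.default_rng(9), 10, (12, 20))
        idx = tz.build_index(db, ordering, blosum62)
        seq = db[0].sequence[:8]
        q = ordering.encode(seq)
        k = tz.insertion_point(idx, q)
        vt = tz.symmetric_sans(idx, q, W=2)
        expected = np.zeros(idx.n_proteins, dtype=np.int64)
        delim = ordering.delimiter_rank
        for p in (k - 1, k):
            if 0 <= p < len(idx.sa) and idx.text[idx.sa[p]] != delim:
                expected[idx.protein_at(int(idx.sa[p]))] += 1
        assert np.array_equal(vt.votes, expected)

    def test_vote_conservation(self, small_index, ordering):
        db, idx = small_index
        q = ordering.encode(db[6].sequence)
        vt = tz.symmetric_sans(idx, q, W=6)
        assert vt.votes.sum() == vt.budget_used


class TestTopCandidates:
    def test_tie_broken_by_ordinal(self):
        votes = np.zeros(5, dtype=np.int64)
        votes[[1, 2, 3]] = [5, 5, 1]
        vt = tz.VoteTable(votes, 11)
        assert tz.top_candidates(vt, 2) == [1, 2]

    def test_n_larger_than_voted(self):
        votes = np.zeros(5, dtype=np.int64)
        votes[[0, 4]] = [2, 7]
        vt = tz.VoteTable(votes, 9)
        assert tz.top_candidates(vt, 50) == [4, 0]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = int(rng.integers(1, 40))
            votes = rng.integers(0, 6, size=n).astype(np.int64)
            vt = tz.VoteTable(votes, int(votes.sum()))
            N = int(rng.integers(1, 10))
            oracle = sorted(
                (i for i in range(n) if votes[i] > 0),
                key=lambda i: (-votes[i], i),
            )[:N]
            assert tz.top_candidates(vt, N) == oracle
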