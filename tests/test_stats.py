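import math

import numpy as np
import pytest

import topaz as tz
from topaz import stats

from conftest import dp_local_affine, random_database


class TestSmithWaterman:
    def test_self_alignment_is_diagonal_sum(self, blosum62):
        r = tz.smith_waterman("ACDE", "ACDE", blosum62)
        assert r.raw_score == 24  # 4 + 9 + 6 + 5
        assert r.identities == 4 and r.mismatches == 0 and r.gap_openings == 0
        assert (r.q_start, r.q_end, r.s_start, r.s_end) == (1, 4, 1, 4)

    def test_no_positive_pair_scores_zero(self, blosum62):
        r = tz.smith_waterman("GGGG", "WWWW", blosum62)
        assert r.raw_score == 0
        assert r.aligned_length == 0 and r.q_start == 0

    def test_matches_dp_oracle_on_random_pairs(self, blosum62):
        from topaz.synthetic import STANDARD_RESIDUES

        rng = np.random.default_rng(8)
        for _ in range(40):
            a = "".join(STANDARD_RESIDUES[i] for i in rng.integers(0, 20, size=rng.integers(5, 60)))
            b = "".join(STANDARD_RESIDUES[i] for i in rng.integers(0, 20, size=rng.integers(5, 60)))
            expected = dp_local_affine(a, b, blosum62)
            assert tz.smith_waterman(a, b, blosum62).raw_score == expected

    def test_score_kernel_agrees_with_traceback_path(self, blosum62, ordering):
        db = random_database(np.random.default_rng(4), 30, (20, 60))
        mat = blosum62.rank_scores(ordering)
        rng = np.random.default_rng(5)
        for _ in range(60):
            a = db[int(rng.integers(0, 30))].sequence
            b = db[int(rng.integers(0, 30))].sequence
            k = int(stats._sw_score_one(ordering.encode(a), ordering.encode(b),
                                        mat, np.int64(11), np.int64(1)))
            assert k == tz.smith_waterman(a, b, blosum62).raw_score

    def test_gapped_alignment_statistics(self, blosum62):
        # force a gap: long identical flanks around an insertion
        q = "MKVLITAAAGHDEW"
        s = "MKVLITAAAWYGHDEW"
        r = tz.smith_waterman(q, s, blosum62)
        assert r.raw_score == dp_local_affine(q, s, blosum62)
        assert r.gap_openings >= 1
        assert r.aligned_length == r.identities + r.mismatches + r.gaps

    def test_empty_sequence_rejected(self, blosum62):
        with pytest.raises(ValueError):
            tz.smith_waterman("", "ACDE", blosum62)


class TestEvalue:
    def test_zero_score_closed_form(self):
        p = tz.KarlinAltschulParams(db_residues=10**6)
        bits, e = tz.evalue(0, 300, p)
        assert e == pytest.approx(300 * 10**6 * p.k * math.e ** 0)  # m*n*K at S=0
        # direct substitution: 2^-bits with bits = -ln(K)/ln 2
        assert e == pytest.approx(300 * 10**6 * 2.0 ** (-bits))

    def test_worked_values(self):
        p = tz.KarlinAltschulParams(lam=0.267, k=0.041, db_residues=10**6)
        bits, e = tz.evalue(100, 300, p)
        expected_bits = (0.267 * 100 - math.log(0.041)) / math.log(2)
        assert bits == pytest.approx(expected_bits)
        assert e == pytest.approx(300 * 10**6 * 2.0 ** (-expected_bits))

    def test_monotone_in_score(self):
        p = tz.KarlinAltschulParams(db_residues=10**6)
        evals = [tz.evalue(s, 200, p)[1] for s in range(0, 200, 10)]
        assert all(a > b for a, b in zip(evals, evals[1:]))

    def test_bitscore_evalue_roundtrip(self):
        p = tz.KarlinAltschulParams(db_residues=123456)
        for s in (13, 57, 211):
            bits, e = tz.evalue(s, 77, p)
            assert e == pytest.approx(77 * 123456 * 2.0 ** (-bits), rel=1e-9)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            tz.KarlinAltschulParams(lam=0.0)


@pytest.fixture(scope="module")
def searchable(blosum62, ordering):
    db = random_database(np.random.default_rng(77), 40, (30, 60))
    idx = tz.build_index(db, ordering, blosum62)
    params = tz.KarlinAltschulParams(db_residues=db.total_residues)
    return db, idx, params


class TestRankHits:
    def test_self_hit_ranks_first(self, searchable, blosum62):
        db, idx, params = searchable
        hits = tz.rank_hits(list(range(len(db))), "q", db[5].sequence,
                            idx, blosum62, params)
        assert hits[0].subject_id == "p5"
        assert hits[0].result.percent_identity == 100.0
        # no other hit can beat a full-length identity
        assert all(h.bitscore <= hits[0].bitscore for h in hits)

    def test_evalue_filter(self, searchable, blosum62):
        db, idx, params = searchable
        hits = tz.rank_hits([0, 1, 2], "q", db[10].sequence, idx, blosum62,
                            params, evalue_max=1e-30)
        assert hits == []

    def test_ordering_matches_full_sort(self, searchable, blosum62):
        db, idx, params = searchable
        hits = tz.rank_hits(list(range(len(db))), "q", db[0].sequence,
                            idx, blosum62, params, evalue_max=1e6 * db.total_residues)
        keys = [(-h.bitscore, h.evalue, h.subject_ordinal) for h in hits]
        assert keys == sorted(keys)

    def test_truncates_to_h(self, searchable, blosum62):
        db, idx, params = searchable
        hits = tz.rank_hits(list(range(len(db))), "q", db[0].sequence,
                            idx, blosum62, params, H=3,
                            evalue_max=1e6 * db.total_residues)
        assert len(hits) == 3
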