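"""Matching engine: bit-parallel rows, search execution, clustering, modes."""

import random

import pytest

from lossmap.alphabet import encode
from lossmap.bitparallel import BitRow, band_row_update
from lossmap.index import build_index
from lossmap.matching import (Occurrence, align_global, all_best_match,
                              approximate_match, cluster_occurrences, dedupe,
                              execute_search, switch_to_in_text)
from lossmap.schemes import (Search, SearchScheme, covers, pigeonhole_scheme,
                             uniform_partition)

from .oracles import (edit_distance, mutate, occurrence_map, random_dna,
                      scalar_dp_columns, sellers_end_positions)


class TestBitParallelRows:
    def test_self_match_reaches_zero(self):
        pat = encode("ACGTACGT")
        row = BitRow.fresh(pat)
        for c in pat:
            row = band_row_update(row, int(c))
        assert row.last == 0

    def test_single_deletion_costs_one(self):
        pat = encode("ACGTACGT")
        row = BitRow.fresh(pat)
        for c in encode("ACGACGT"):  # T deleted
            row = band_row_update(row, int(c))
        assert row.last == 1

    def test_rows_equal_scalar_dp(self, rng):
        """Randomized cross-check of every cell against plain scalar DP."""
        for _ in range(300):
            m = rng.randint(1, 40)
            n = rng.randint(0, 50)
            pat = random_dna(rng, m)
            txt = random_dna(rng, n)
            expected = scalar_dp_columns(pat, txt)
            row = BitRow.fresh(encode(pat))
            assert list(row.values()) == expected[0]
            for j, c in enumerate(encode(txt), 1):
                row = band_row_update(row, int(c))
                assert list(row.values()) == expected[j]
                assert row.last == expected[j][-1]
                assert row.minimum() == min(expected[j])

    def test_after_exact_equals_explicit_spelling(self, rng):
        pat = random_dna(rng, 25)
        codes = encode(pat)
        for j in (0, 5, 25):
            direct = BitRow.after_exact(codes, j)
            spelled = BitRow.fresh(codes)
            for c in codes[:j]:
                spelled = spelled.advance(int(c))
            assert list(direct.values()) == list(spelled.values())

    def test_ambiguous_bases_never_match(self):
        row = BitRow.fresh(encode("ANA"))
        for c in encode("ANA"):
            row = band_row_update(row, int(c))
        assert row.last == 1  # the N column always costs an error


class TestExecuteSearch:
    def test_exact_search_finds_unique_pattern(self, rng):
        text = random_dna(rng, 500)
        idx = build_index([("r", text)])
        pattern = text[200:230]
        scheme = pigeonhole_scheme(0)
        part = uniform_partition(len(pattern), 1)
        out = execute_search(scheme.searches[0], part, pattern, idx, 0)
        assert (200, 230, 0) in out

    def test_planted_substitution_found_at_distance_one(self, rng):
        text = random_dna(rng, 800)
        idx = build_index([("r", text)])
        read = list(text[300:340])
        read[17] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[17]]
        read = "".join(read)
        scheme = pigeonhole_scheme(1)
        part = uniform_partition(len(read), 2)
        hits = set()
        for search in scheme.searches:
            hits |= set(execute_search(search, part, read, idx, 1))
        assert (300, 340, 1) in hits

    def test_in_text_switch_threshold_semantics(self, small_index):
        assert switch_to_in_text(small_index.full_range()) is False
        empty = small_index.extend_left(small_index.full_range(), "A")
        empty = small_index.extend_left(empty, "X")
        assert empty.width == 0
        assert switch_to_in_text(empty, threshold=1) is True


class TestDedupeAndCluster:
    def test_dedupe_collapses_identical_tuples(self):
        a = Occurrence(10, 20, 1)
        assert dedupe([a, Occurrence(10, 20, 1)]) == [a]

    def test_dedupe_keeps_distinct_tuples_and_is_idempotent(self):
        occs = [Occurrence(10, 20, 1), Occurrence(10, 20, 2),
                Occurrence(11, 20, 1)]
        once = dedupe(occs)
        assert len(once) == 3 and dedupe(once) == once

    def test_cluster_tiebreak_keeps_leftmost(self):
        reps = cluster_occurrences([Occurrence(100, 110, 1),
                                    Occurrence(101, 110, 1)])
        assert reps == [Occurrence(100, 110, 1)]

    def test_cluster_keeps_minimal_distance(self):
        reps = cluster_occurrences([Occurrence(100, 110, 2),
                                    Occurrence(100, 111, 1)])
        assert reps == [Occurrence(100, 111, 1)]

    def test_non_overlapping_never_merged(self):
        occs = [Occurrence(0, 10, 2), Occurrence(10, 20, 1)]
        assert cluster_occurrences(occs) == occs

    def test_cluster_covering_guarantee(self, rng):
        """Every suppressed occurrence overlaps a representative with a
        distance no larger than its own."""
        for _ in range(40):
            text = random_dna(rng, 250)
            idx = build_index([("r", text)])
            read = mutate(rng, text[50:90], rng.randint(0, 2))
            k = 2
            full = approximate_match(read, k, idx, cluster=False)
            reps = cluster_occurrences(full)
            assert set(reps) <= set(full)
            for occ in full:
                assert any(r.start < occ.end and occ.start < r.end
                           and r.distance <= occ.distance for r in reps)


class TestApproximateMatch:
    def test_k0_equals_exact_locate(self, rng):
        text = random_dna(rng, 600)
        idx = build_index([("r", text)])
        pattern = text[100:125]
        occs = approximate_match(pattern, 0, idx, cluster=False)
        starts = {o.start for o in occs}
        assert starts == set(idx.locate(idx.match_range(pattern)))
        assert all(o.distance == 0 for o in occs)

    def test_end_positions_match_sellers_oracle(self, rng):
        for _ in range(25):
            n = rng.randint(100, 800)
            text = random_dna(rng, n)
            idx = build_index([("r", text)])
            k = rng.randint(0, 3)
            read = mutate(rng, text[rng.randrange(n - 50):][:40],
                          rng.randint(0, k))
            if len(read) <= k:
                continue
            got = {o.end for o in
                   approximate_match(read, k, idx, cluster=False)}
            assert got == sellers_end_positions(text, read, k)

    def test_partition_invariance(self, rng):
        for _ in range(15):
            text = random_dna(rng, 400)
            idx = build_index([("r", text)])
            read = mutate(rng, text[60:100], 2)
            uni = approximate_match(read, 2, idx, partition="uniform")
            dyn = approximate_match(read, 2, idx, partition="dynamic")
            assert uni == dyn

    def test_covering_scheme_invariance(self, rng):
        alt = SearchScheme(2, (
            Search((0, 1, 2), (0, 0, 2), (0, 1, 2)),
            Search((2, 1, 0), (0, 0, 0), (0, 2, 2)),
            Search((1, 2, 0), (0, 1, 1), (0, 1, 2)),
        ), name="alt-k2")
        assert covers(alt, 2) == (True, None)
        for _ in range(10):
            text = random_dna(rng, 300)
            idx = build_index([("r", text)])
            read = mutate(rng, text[40:80], 2)
            a = approximate_match(read, 2, idx, partition="uniform")
            b = approximate_match(read, 2, idx, schemes=alt,
                                  partition="uniform")
            assert a == b

    def test_rejects_invalid_budgets(self, small_index):
        with pytest.raises(ValueError):
            approximate_match("ACGTACGT", 14, small_index)
        with pytest.raises(ValueError):
            approximate_match("ACG", 3, small_index)
        with pytest.raises(ValueError):
            # 4 parts cannot tile a 3-character pattern
            approximate_match("ACG", 3, small_index,
                              schemes=pigeonhole_scheme(3))


class TestAllBest:
    def test_exact_hit_gives_stratum_zero(self, rng):
        text = random_dna(rng, 500)
        idx = build_index([("r", text)])
        occs, stratum = all_best_match(text[50:80], 3, idx)
        assert stratum == 0
        assert occs and all(o.distance == 0 for o in occs)

    def test_planted_distance_two_stratum(self, rng):
        for _ in range(10):
            text = random_dna(rng, 600)
            idx = build_index([("r", text)])
            read = mutate(rng, text[100:140], 2)
            truth = occurrence_map(text, read, 4)
            occs, stratum = all_best_match(read, 4, idx)
            if truth:
                assert stratum == min(truth.values())
                assert all(o.distance == stratum for o in occs)
            else:
                assert stratum is None and occs == []

    def test_no_hit_within_budget(self):
        idx = build_index(">r\n" + "A" * 100 + "\n")
        occs, stratum = all_best_match("GGGGGGGGGG", 2, idx)
        assert (occs, stratum) == ([], None)


class TestAlignGlobal:
    def test_cigar_lengths_and_cost(self, rng):
        for _ in range(50):
            ref = random_dna(rng, rng.randint(10, 60))
            qry = mutate(rng, ref, rng.randint(0, 3))
            cost, cigar = align_global(encode(qry), encode(ref))
            assert cost == edit_distance(qry, ref)
            read_len = sum(int(n) for n, op in _cigar_ops(cigar)
                           if op in "MI")
            ref_len = sum(int(n) for n, op in _cigar_ops(cigar)
                          if op in "MD")
            assert read_len == len(qry) and ref_len == len(ref)


def _cigar_ops(cigar):
    import re
    return re.findall(r"(\d+)([MID])", cigar)
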