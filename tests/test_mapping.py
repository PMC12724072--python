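"""Read-level mapping: budgets, strands, fragment model, proper pairs."""

import itertools

import pytest

from lossmap.alphabet import reverse_complement
from lossmap.index import build_index
from lossmap.mapping import (FLAG_FIRST, FLAG_PAIRED, FLAG_PROPER,
                             FLAG_REVERSE, FLAG_SECOND, FLAG_SECONDARY,
                             FLAG_UNMAPPED, FragmentModel, ReadRecord,
                             infer_fragment_model, map_pair, map_single,
                             resolve_error_budget)
from lossmap.matching import approximate_match
from lossmap.synthetic import sample_reads

from .oracles import random_dna


class TestErrorBudget:
    def test_zero_rate(self):
        assert resolve_error_budget(0.0, 151) == 0

    def test_illumina_correspondences(self):
        # 2% of a 151 bp read allows 3 errors; 8% of 150 bp allows 12
        assert resolve_error_budget(0.02, 151) == 3
        assert resolve_error_budget(0.08, 150) == 12

    def test_rate_capped_at_ceiling(self):
        assert resolve_error_budget(0.2, 150) == 13

    def test_explicit_k_beyond_ceiling_rejected(self):
        with pytest.raises(ValueError):
            resolve_error_budget(14, 151)

    def test_explicit_k_passthrough(self):
        assert resolve_error_budget(5, 100) == 5


class TestMapSingle:
    def test_exact_forward_read(self, small_genome, small_index):
        name, seq = small_genome[0]
        read = ReadRecord("q1", seq[1000:1080])
        recs = map_single(read, 2, "all-best", small_index)
        prim = recs[0]
        assert prim.is_mapped and not prim.flag & FLAG_SECONDARY
        assert prim.rname == name and prim.pos == 1001
        assert prim.tags["NM"] == 0 and prim.cigar == "80M"

    def test_reverse_complement_read_sets_strand_bit(self, small_genome,
                                                     small_index):
        name, seq = small_genome[1]
        read = ReadRecord("q2", reverse_complement(seq[500:570]))
        prim = map_single(read, 2, "all-best", small_index)[0]
        assert prim.flag & FLAG_REVERSE
        assert prim.rname == name and prim.pos == 501
        # SEQ is emitted reverse-complemented back to reference orientation
        assert prim.seq == seq[500:570]

    def test_unmapped_read(self, small_index):
        read = ReadRecord("q3", "X" * 40)
        recs = map_single(read, 1, "all", small_index)
        assert len(recs) == 1 and recs[0].flag == FLAG_UNMAPPED

    def test_multi_hit_mapq_and_secondary_records(self):
        motif = random_dna(__import__("random").Random(5), 30)
        genome = [("r", motif + "T" * 20 + motif + "C" * 20 + motif)]
        idx = build_index(genome)
        recs = map_single(ReadRecord("q", motif), 0, "all", idx)
        assert len(recs) == 3
        assert recs[0].mapq == 3  # 3 co-optimal placements
        assert all(r.flag & FLAG_SECONDARY for r in recs[1:])

    def test_all_mode_reports_suboptimal_strata(self, rng):
        text = random_dna(rng, 1500)
        idx = build_index([("r", text)])
        read = text[700:760]
        recs_best = map_single(ReadRecord("q", read), 3, "all-best", idx)
        recs_all = map_single(ReadRecord("q", read), 3, "all", idx)
        assert {r.tags["NM"] for r in recs_best} == {0}
        assert len(recs_all) >= len(recs_best)


class TestFragmentModel:
    def test_window_is_six_sigma(self):
        model = FragmentModel(400.0, 30.0)
        assert (model.low, model.high) == (220.0, 580.0)
        assert model.accepts(579) and not model.accepts(581)

    def test_recovers_planted_fragment_mean(self, small_genome, small_index):
        reads, truth = sample_reads(small_genome, 120, read_length=70,
                                    sub_rate=0.005, ins_rate=0.0005,
                                    del_rate=0.0005, paired=(400, 30),
                                    seed=33)
        pairs = [(reads[2 * i], reads[2 * i + 1]) for i in range(120)]
        model = infer_fragment_model(pairs, small_index, 2)
        assert not model.fallback
        se = 30 / (model.n_observations ** 0.5)
        assert abs(model.mean - 400) <= 3 * se + 1  # +1: integer rounding
        assert 15 <= model.sd <= 45

    def test_all_discordant_pairs_fall_back(self, small_index):
        junk = [(ReadRecord("a", "GGGG" * 10), ReadRecord("b", "CCCC" * 10))]
        model = infer_fragment_model(junk * 60, small_index, 1)
        assert model.fallback
        assert (model.mean, model.sd) == (500.0, 100.0)


class TestMapPair:
    def test_planted_concordant_pair(self, small_genome, small_index):
        name, seq = small_genome[0]
        frag = 300
        r1 = ReadRecord("p1", seq[400:470], mate=1)
        r2 = ReadRecord("p1", reverse_complement(seq[400 + frag - 70:400 + frag]),
                        mate=2)
        model = FragmentModel(300.0, 25.0)
        recs = map_pair(r1, r2, 2, "all", model, small_index)
        primaries = [r for r in recs if not r.flag & FLAG_SECONDARY]
        assert len(primaries) == 2
        for rec in primaries:
            assert rec.flag & FLAG_PAIRED and rec.flag & FLAG_PROPER
            assert rec.tags["NM"] == 0
        first = next(r for r in primaries if r.flag & FLAG_FIRST)
        second = next(r for r in primaries if r.flag & FLAG_SECOND)
        assert first.pos == 401 and first.tlen == frag
        assert second.tlen == -frag
        assert first.rnext == "=" and first.pnext == second.pos

    def test_fragment_outside_window_falls_back_to_unpaired(
            self, small_genome, small_index):
        name, seq = small_genome[0]
        r1 = ReadRecord("p2", seq[100:160], mate=1)
        r2 = ReadRecord("p2", reverse_complement(seq[2000:2060]), mate=2)
        model = FragmentModel(300.0, 10.0)  # window [240, 360], frag ~1960
        recs = map_pair(r1, r2, 1, "all-best", model, small_index)
        assert all(not r.flag & FLAG_PROPER for r in recs)
        assert all(r.flag & FLAG_PAIRED for r in recs)
        mapped = [r for r in recs if r.is_mapped]
        assert len(mapped) >= 2

    def test_pairs_match_cross_product_oracle(self, small_genome,
                                              small_index):
        reads, truth = sample_reads(small_genome, 25, read_length=60,
                                    paired=(350, 25), seed=77)
        model = FragmentModel(350.0, 25.0)
        k = 2
        for i in range(25):
            r1, r2 = reads[2 * i], reads[2 * i + 1]
            recs = map_pair(r1, r2, k, "all", model, small_index)
            proper = [r for r in recs if r.flag & FLAG_PROPER]
            # oracle: best total distance over all convergent in-window combos
            occ1 = _strand_occs(r1.sequence, k, small_index)
            occ2 = _strand_occs(r2.sequence, k, small_index)
            best = None
            for o1, o2 in itertools.product(occ1, occ2):
                left, right = (o1, o2) if o1.start <= o2.start else (o2, o1)
                if left.strand != "+" or right.strand != "-":
                    continue
                if small_index.resolve_interval(left.start, right.end) is None:
                    continue
                if not model.accepts(right.end - left.start):
                    continue
                tot = o1.distance + o2.distance
                best = tot if best is None else min(best, tot)
            if best is None:
                assert not proper
            else:
                assert proper
                assert {r.tags["NM"] for r in proper
                        if not r.flag & FLAG_SECONDARY} and \
                    sum(r.tags["NM"] for r in proper
                        if not r.flag & FLAG_SECONDARY) == best


def _strand_occs(seq, k, index):
    from lossmap.matching import Occurrence
    fwd = approximate_match(seq, k, index)
    rev = [Occurrence(o.start, o.end, o.distance, "-")
           for o in approximate_match(reverse_complement(seq), k, index)]
    return fwd + rev
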