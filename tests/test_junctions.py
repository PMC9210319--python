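"""Demultiplexing, congruence, candidate merging and the support filter."""

import numpy as np
import pytest

from gted import (
    build_reference,
    call_junctions,
    demultiplex_pairs,
    expected_junctions,
    extract_flank_windows,
    filter_valid,
    plant_insertions,
)
from gted.junctions import test_congruence as congruence_check
from gted.align import LocalAlignment
from gted.junctions import JunctionCandidate, ValidJunction, cluster_breakpoints
from gted.refdb import ReferenceGenome, TEDatabase, TEFamily
from gted.seqs import random_dna, revcomp
from gted.simulate import ReadPair, generate_read_pairs


def _pair(rid, r2, read_len=75):
    return ReadPair(
        read_id=rid, r1_seq="A" * read_len, r1_qual="?" * read_len,
        r2_seq=r2, r2_qual="?" * len(r2), sample_id="s",
    )


class TestDemultiplex:
    def test_exact_ltr_read_lands_in_its_family_bin(self, te_db):
        copia = te_db["copia"]
        pairs = [
            _pair("a", revcomp(copia.consensus[:75])),  # 5' terminus
            _pair("b", copia.consensus[-75:]),  # 3' terminus
        ]
        res = demultiplex_pairs(pairs, te_db)
        assert set(res.bins["copia"]) == {"a", "b"}
        assert res.bins["copia"]["a"].side == "5p"
        assert res.bins["copia"]["b"].side == "3p"

    def test_random_r2_unassigned_and_partition_invariant(self, te_db):
        rng = np.random.default_rng(0)
        pairs = [_pair(f"r{i}", random_dna(75, rng)) for i in range(5)]
        copia = te_db["copia"]
        pairs.append(_pair("hit", copia.consensus[-75:]))
        res = demultiplex_pairs(pairs, te_db)
        assert set(res.unassigned) == {f"r{i}" for i in range(5)}
        assert sum(len(m) for m in res.bins.values()) + len(res.unassigned) == 6

    def test_score_tie_between_families_goes_unassigned(self):
        rng = np.random.default_rng(1)
        shared = random_dna(150, rng)
        fams = []
        for name, seed in (("famA", 2), ("famB", 3)):
            interior = random_dna(700, rng)
            cons = shared + interior + random_dna(150, rng)
            fams.append(TEFamily(name=name, consensus=cons, ltr5=cons[:150],
                                 ltr3=cons[-150:]))
        db = TEDatabase(families=fams)
        # R2 wholly inside the shared LTR prefix: equal score in both
        res = demultiplex_pairs([_pair("tie", shared[:75])], db, method="exhaustive")
        assert res.unassigned == ["tie"]


class TestCongruence:
    def _galn(self, qs, qe, ts, te, strand="+", read_len=100):
        return LocalAlignment(
            read_id="r", target_name="c", target_start=ts, target_end=te,
            query_start=qs, query_end=qe, strand=strand, score=2 * (qe - qs),
            read_len=read_len,
        )

    def _taln(self, qs, qe, ts, te, strand="+", read_len=100):
        return LocalAlignment(
            read_id="r", target_name="fam", target_start=ts, target_end=te,
            query_start=qs, query_end=qe, strand=strand, score=2 * (qe - qs),
            read_len=read_len,
        )

    def test_clean_split_accepts_with_constructed_breakpoint(self):
        # 100 bp read: 60 bp genome (ending at 5000) + 40 bp TE 5' start
        g = self._galn(0, 60, 4940, 5000)
        t = self._taln(60, 100, 0, 40)
        assert congruence_check(100, g, t, "5p", 1500) == (5000, True)

    def test_unaccounted_tail_beyond_slack_rejects(self):
        g = self._galn(0, 60, 4940, 5000)
        t = self._taln(60, 95, 0, 35)  # 5 bp unexplained tail
        assert congruence_check(100, g, t, "5p", 1500) is None

    def test_nested_te_alignment_rejects(self):
        g = self._galn(0, 100, 4900, 5000)
        t = self._taln(30, 70, 0, 40)
        assert congruence_check(100, g, t, "5p", 1500) is None

    def test_wrong_terminus_for_declared_side_rejects(self):
        g = self._galn(0, 60, 4940, 5000)
        t = self._taln(60, 100, 700, 740)  # interior, not the 5' terminus
        assert congruence_check(100, g, t, "5p", 1500) is None

    def test_micro_homology_overlap_within_cap_accepts(self):
        # genome alignment over-extends 3 bp across the junction
        g = self._galn(0, 63, 4940, 5003)
        t = self._taln(60, 100, 0, 40)
        assert congruence_check(100, g, t, "5p", 1500) == (5000, True)

    def test_te_first_reverse_strand_projection(self):
        # read = rc(te_tail + genomic); genome first in query, strand '-'
        g = self._galn(0, 30, 7000, 7030, strand="-")
        t = self._taln(30, 100, 1430, 1500)
        assert congruence_check(100, g, t, "3p", 1500) == (7000, False)


class TestMergingAndFilter:
    def test_nearby_breakpoints_merge_to_modal_position(self):
        recs = [(1000,), (1002,), (1002,), (1010,)]
        clusters = cluster_breakpoints(recs, merge_window=3)
        assert [sorted(c) for c in clusters] == [
            [(1000,), (1002,), (1002,)], [(1010,)]
        ]

    def test_modal_tie_breaks_to_smaller_coordinate(self):
        from gted.junctions import _make_candidate

        cluster = [(1000, "s", "r1", 5), (1002, "s", "r2", 6)]
        cand = _make_candidate("c", "5p", "copia", True, cluster)
        assert cand.breakpoint == 1000
        assert cand.n_reads == 2

    def test_chain_clustering_matches_exhaustive_single_linkage(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            bps = sorted(int(b) for b in rng.integers(0, 60, size=12))
            clusters = cluster_breakpoints([(b,) for b in bps], merge_window=3)
            # oracle: exhaustive single linkage at <= 3
            groups = [[bps[0]]]
            for b in bps[1:]:
                if any(abs(b - x) <= 3 for x in groups[-1]):
                    groups[-1].append(b)
                else:
                    groups.append([b])
            assert [[r[0] for r in c] for c in clusters] == groups

    @pytest.mark.parametrize(
        "n_reads,n_starts,expected",
        [(12, 4, True), (11, 4, False), (12, 3, False), (13, 5, True)],
    )
    def test_support_thresholds_are_conjunctive(self, n_reads, n_starts, expected):
        starts = list(range(n_starts)) * n_reads
        cand = JunctionCandidate(
            contig="c", breakpoint=100, side="5p", family="copia", te_right=True,
            support=[("s", f"r{i}") for i in range(n_reads)],
            r1_starts=starts[:n_reads],
        )
        got = filter_valid([cand])
        assert bool(got) == expected
        if got:
            assert got[0].n_reads >= 12 and got[0].n_distinct_starts >= 4

    def test_filter_monotone_under_threshold_increase(self):
        rng = np.random.default_rng(8)
        cands = []
        for i in range(200):
            n = int(rng.integers(1, 30))
            starts = [int(s) for s in rng.integers(90, 110, size=n)]
            cands.append(
                JunctionCandidate(
                    contig="c", breakpoint=100 + 10 * i, side="5p", family="roo",
                    te_right=True, support=[("s", f"r{i}_{k}") for k in range(n)],
                    r1_starts=starts,
                )
            )
        base = {c.breakpoint for c in filter_valid(cands, 10, 3)}
        for mr, ms in [(11, 3), (10, 4), (15, 6)]:
            tighter = {c.breakpoint for c in filter_valid(cands, mr, ms)}
            assert tighter <= base

    def test_pooling_across_samples_reaches_threshold(self, te_db, small_ref):
        # 7 + 6 junction reads in two samples: neither alone reaches 12
        geno, _ = plant_insertions(small_ref, te_db, 1, seed=31)
        geno.insertions = geno.insertions[:1]
        mk = lambda sid, ppj, seed: {
            p.read_id: p
            for p in generate_read_pairs(
                small_ref, geno, te_db, pairs_per_junction=ppj, straddle_frac=1.0,
                background_frac=0.0, seed=seed, sample_id=sid,
            )
        }
        samples = {
            "sa": list(mk("sa", 7, 1).values()),
            "sb": list(mk("sb", 6, 2).values()),
        }
        pooled = call_junctions(samples, te_db, small_ref, min_starts=1)
        solo = call_junctions({"sa": samples["sa"]}, te_db, small_ref, min_starts=1)
        truth_keys = {j.key for j in expected_junctions(geno)}
        assert {j.key for j in pooled.junctions} == truth_keys
        assert all(j.n_reads == 13 for j in pooled.junctions)
        assert solo.junctions == []


class TestFlankWindows:
    def _vj(self, bp, te_right, contig="c"):
        return ValidJunction(
            contig=contig, breakpoint=bp, side="5p", family="copia",
            te_right=te_right, n_reads=12, n_distinct_starts=4,
        )

    def test_window_side_follows_te_direction(self):
        genome = ReferenceGenome(contigs={"c": "A" * 10_000})
        vjs = extract_flank_windows(
            [self._vj(5000, True), self._vj(5000, False)], genome
        )
        assert vjs[0].window == (4700, 5000)
        assert vjs[1].window == (5000, 5300)

    def test_truncation_at_contig_bounds(self):
        genome = ReferenceGenome(contigs={"c": "A" * 10_000})
        vjs = extract_flank_windows(
            [self._vj(100, True), self._vj(9900, False)], genome
        )
        assert vjs[0].window == (0, 100)
        assert vjs[1].window == (9900, 10_000)

    def test_paired_junction_windows_sit_on_opposite_sides(self, single_line,
                                                           single_line_calls):
        by_key = {j.key: j for j in single_line_calls.junctions}
        for ins in single_line["genotype"].insertions:
            left = [j for k, j in by_key.items()
                    if k[0] == ins.contig and k[1] == ins.position][0]
            right = [j for k, j in by_key.items()
                     if k[0] == ins.contig and k[1] == ins.position - ins.tsd_len][0]
            assert left.te_right and not right.te_right
            assert left.window[1] <= right.window[0] + ins.tsd_len
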