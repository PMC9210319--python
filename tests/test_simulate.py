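"""Simulator contracts: determinism, geometry, ground truth, fixtures."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from gted import (
    LineSpec,
    build_reference,
    expected_junctions,
    plant_insertions,
    simulate_cohort,
    synthetic_te_database,
    write_fixture,
)
from gted.errors import ConfigError, DataError
from gted.seqs import revcomp
from gted.simulate import generate_read_pairs


class TestBuildReference:
    def test_size_contract(self):
        ref = build_reference(1, 10_000, 42)
        assert list(ref.contigs) == ["contig1"]
        assert len(ref.contigs["contig1"]) == 10_000

    def test_same_seed_identical_different_seed_differs(self):
        a = build_reference(2, 5000, 1)
        b = build_reference(2, 5000, 1)
        c = build_reference(2, 5000, 2)
        assert a.contigs == b.contigs
        assert a.contigs != c.contigs

    @pytest.mark.parametrize("n,length", [(0, 5000), (1, 1999)])
    def test_preconditions(self, n, length):
        with pytest.raises(ConfigError):
            build_reference(n, length, 0)


class TestSyntheticFamilies:
    def test_ltr_invariants_hold(self, te_db):
        for fam in te_db.families:
            assert fam.consensus.startswith(fam.ltr5)
            assert fam.consensus.endswith(fam.ltr3)
            assert set(fam.consensus) <= set("ACGT")

    def test_ltr_copies_diverge_in_every_terminal_window(self, te_db):
        # the R2 anchor window must distinguish the two LTR copies
        for fam in te_db.active:
            w = 75
            head5, head3 = fam.ltr5[:w], fam.ltr3[:w]
            tail5, tail3 = fam.ltr5[-w:], fam.ltr3[-w:]
            assert sum(a != b for a, b in zip(head5, head3)) >= 2
            assert sum(a != b for a, b in zip(tail5, tail3)) >= 2


class TestPlantInsertions:
    def test_zero_insertions_leaves_genome_unchanged(self, te_db, small_ref):
        geno, genome = plant_insertions(small_ref, te_db, 0, seed=1)
        assert geno.insertions == []
        assert genome.contigs == small_ref.contigs

    def test_length_arithmetic_per_insertion(self, te_db, small_ref):
        geno, genome = plant_insertions(small_ref, te_db, 1, seed=2, tsd_len=4)
        added = {c: len(genome.contigs[c]) - len(small_ref.contigs[c])
                 for c in small_ref.contigs}
        expect = {c: 0 for c in small_ref.contigs}
        for ins in geno.insertions:
            expect[ins.contig] += len(te_db[ins.family].consensus) + 4
        assert added == expect

    def test_full_sharing_reproduces_donor_sites(self, te_db, small_ref):
        donor, _ = plant_insertions(small_ref, te_db, 6, seed=3, line_name="D")
        child, _ = plant_insertions(
            small_ref, te_db, 6, shared_with=donor, share_frac=1.0, seed=4,
            line_name="C",
        )
        donor_keys = {(i.contig, i.position, i.family) for i in donor.insertions}
        child_keys = {(i.contig, i.position, i.family) for i in child.insertions}
        assert child_keys == donor_keys

    def test_minimum_spacing_respected(self, te_db, small_ref):
        geno, _ = plant_insertions(small_ref, te_db, 8, seed=5, min_spacing=600)
        by_contig = {}
        for ins in geno.insertions:
            by_contig.setdefault(ins.contig, []).append(ins.position)
        for positions in by_contig.values():
            positions.sort()
            assert all(b - a >= 600 for a, b in zip(positions, positions[1:]))

    def test_impossible_density_raises(self, te_db):
        tiny = build_reference(1, 3000, 9)
        with pytest.raises(DataError, match="eligible"):
            plant_insertions(tiny, te_db, 50, seed=6)

    def test_each_insertion_yields_two_junctions_offset_by_tsd(self, te_db, small_ref):
        geno, _ = plant_insertions(small_ref, te_db, 2, seed=7, tsd_len=4)
        juncs = expected_junctions(geno)
        assert len(juncs) == 2 * len(geno.insertions)
        for ins in geno.insertions:
            mine = [j for j in juncs if j.contig == ins.contig
                    and j.breakpoint in (ins.position, ins.position - 4)
                    and j.family == ins.family]
            assert len(mine) == 2
            sides = {j.side for j in mine}
            assert sides == {"5p", "3p"}


class TestReadPairs:
    def test_zero_pairs_per_junction_empty_stream(self, te_db, small_ref):
        geno, _ = plant_insertions(small_ref, te_db, 1, seed=8)
        pairs = generate_read_pairs(
            small_ref, geno, te_db, pairs_per_junction=0, seed=1
        )
        assert pairs == []

    def test_pair_counting_two_junctions_each(self, te_db, small_ref):
        geno, _ = plant_insertions(small_ref, te_db, 1, seed=8)
        geno.insertions = geno.insertions[:1]
        pairs = generate_read_pairs(
            small_ref, geno, te_db, pairs_per_junction=20, background_frac=0.0,
            seed=2,
        )
        assert len(pairs) == 40

    def test_determinism_and_seed_sensitivity(self, te_db, small_ref):
        geno, _ = plant_insertions(small_ref, te_db, 2, seed=9)
        a = generate_read_pairs(small_ref, geno, te_db, seed=5)
        b = generate_read_pairs(small_ref, geno, te_db, seed=5)
        c = generate_read_pairs(small_ref, geno, te_db, seed=6)
        key = lambda ps: [(p.read_id, p.r1_seq, p.r2_seq) for p in ps]
        assert key(a) == key(b)
        assert key(a) != key(c)

    def test_r2_matches_the_family_terminus(self, te_db, small_ref):
        geno, _ = plant_insertions(small_ref, te_db, 1, seed=10)
        pairs = generate_read_pairs(
            small_ref, geno, te_db, pairs_per_junction=3, background_frac=0.0,
            seed=3,
        )
        for p in pairs:
            _, key, _ = p.read_id.split("|")
            fam = te_db[key.rsplit(":", 1)[1]]
            side = key.split(":")[2]
            if side == "5p":
                assert p.r2_seq == revcomp(fam.consensus[:75])
            else:
                assert p.r2_seq == fam.consensus[-75:]

    def test_straddle_reads_have_distinct_genomic_starts(self, te_db, small_ref):
        geno, _ = plant_insertions(small_ref, te_db, 1, seed=12)
        ins = geno.insertions[0]
        geno.insertions = [ins]
        pairs = generate_read_pairs(
            small_ref, geno, te_db, pairs_per_junction=20, background_frac=0.0,
            seed=4,
        )
        ref = small_ref.contigs[ins.contig]
        left_prefix_lens = set()
        for p in pairs:
            side_key = f"{ins.contig}:{ins.position}:"
            if side_key not in p.read_id:
                continue
            # length of the genomic prefix of a left-junction read
            for g in range(20, 76):
                if p.r1_seq[:g] == ref[ins.position - g : ins.position] and g < 75:
                    left_prefix_lens.add(g)
        assert len(left_prefix_lens) >= 4

    def test_read_longer_than_fragment_rejected(self, te_db, small_ref):
        geno, _ = plant_insertions(small_ref, te_db, 1, seed=13)
        with pytest.raises(ConfigError, match="fragment"):
            generate_read_pairs(
                small_ref, geno, te_db, read_len=400, frag_len_mean=300, seed=1
            )


class TestFixtures:
    def _cohort(self, te_db, seed=21):
        ref = build_reference(2, 20_000, seed=19)
        return simulate_cohort(
            ref, te_db,
            [LineSpec("A", n_per_family=2), LineSpec("B", n_per_family=2)],
            pairs_per_junction=5, seed=seed,
        )

    def test_fixture_layout_and_manifest(self, te_db, tmp_path):
        cohort = self._cohort(te_db)
        write_fixture(cohort, tmp_path)
        assert len(cohort.manifest) == 6
        for sid in cohort.manifest["sample_id"]:
            assert (tmp_path / f"{sid}_R1.fastq").exists()
            assert (tmp_path / f"{sid}_R2.fastq").exists()
        for line in ("A", "B"):
            bed = (tmp_path / f"truth_{line}.bed").read_text().strip().splitlines()
            assert len(bed) == 2 * len(cohort.truth.genotypes[line].insertions)
        assert (tmp_path / "manifest.tsv").exists()
        assert (tmp_path / "reference.fasta").exists()

    def test_rerun_with_same_seed_is_byte_identical(self, te_db, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_fixture(self._cohort(te_db), d1)
        write_fixture(self._cohort(te_db), d2)
        for f1 in sorted(d1.iterdir()):
            h1 = hashlib.sha256(f1.read_bytes()).hexdigest()
            h2 = hashlib.sha256((d2 / f1.name).read_bytes()).hexdigest()
            assert h1 == h2, f1.name

    def test_replicates_below_one_rejected(self, te_db):
        ref = build_reference(1, 20_000, seed=20)
        with pytest.raises(ConfigError, match="replicates"):
            simulate_cohort(ref, te_db, [LineSpec("A", replicates=0)], seed=1)
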