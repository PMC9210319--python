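"""Subsampling, window counting, normalization and binarization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gted import binarize, count_window_reads, normalize, subsample_pairs
from gted.align import AlignmentSet, LocalAlignment
from gted.errors import ConfigError, DataError
from gted.junctions import ValidJunction
from gted.profile import CountMatrix, NormalizedMatrix
from gted.refdb import ReferenceGenome
from gted.simulate import ReadPair


def _pairs(n):
    return [
        ReadPair(read_id=f"r{i:03d}", r1_seq="ACGT" * 20, r1_qual="?" * 80,
                 r2_seq="ACGT" * 20, r2_qual="?" * 80, sample_id="s")
        for i in range(n)
    ]


class TestSubsample:
    def test_n_at_least_total_keeps_everything(self):
        pairs = _pairs(10)
        assert subsample_pairs(pairs, 10, seed=1) == pairs
        assert subsample_pairs(pairs, 99, seed=1) == pairs

    def test_deterministic_and_order_independent_membership(self):
        pairs = _pairs(10)
        a = subsample_pairs(pairs, 5, seed=3)
        b = subsample_pairs(pairs, 5, seed=3)
        assert [p.read_id for p in a] == [p.read_id for p in b]
        shuffled = list(reversed(pairs))
        c = subsample_pairs(shuffled, 5, seed=3)
        assert {p.read_id for p in c} == {p.read_id for p in a}

    def test_invalid_size_rejected(self):
        with pytest.raises(ConfigError):
            subsample_pairs(_pairs(3), 0)

    def test_inclusion_frequency_is_uniform(self):
        pairs = _pairs(10)
        hits = {p.read_id: 0 for p in pairs}
        for trial in range(1000):
            for p in subsample_pairs(pairs, 5, seed=trial):
                hits[p.read_id] += 1
        for rid, n in hits.items():
            assert abs(n / 1000 - 0.5) < 0.05, rid


def _aln(rid, start, contig="c", strand="+"):
    if strand == "+":
        ts, te = start, start + 75
    else:
        ts, te = start - 74, start + 1
    return LocalAlignment(
        read_id=rid, target_name=contig, target_start=ts, target_end=te,
        query_start=0, query_end=75, strand=strand, score=150, read_len=75,
    )


def _vj(bp, te_right, contig="c", family="copia", window=None):
    j = ValidJunction(
        contig=contig, breakpoint=bp, side="5p", family=family, te_right=te_right,
        n_reads=12, n_distinct_starts=4,
    )
    j.window = window or ((bp - 300, bp) if te_right else (bp, bp + 300))
    return j


class TestWindowCounting:
    def test_no_alignments_gives_zero_matrix(self):
        genome = ReferenceGenome(contigs={"c": "A" * 10_000})
        aset = AlignmentSet()
        cm = count_window_reads({"s1": aset}, {"s1": {}}, [_vj(5000, True)], genome)
        assert cm.counts.shape == (1, 1)
        assert cm.counts.iloc[0, 0] == 0 and cm.totals["s1"] == 0

    def test_counts_match_brute_force_interval_membership(self):
        rng = np.random.default_rng(0)
        genome = ReferenceGenome(contigs={"c": "A" * 50_000})
        windows = [_vj(int(b), bool(r))
                   for b, r in zip(rng.integers(1000, 49_000, 8),
                                   rng.integers(0, 2, 8))]
        aset = AlignmentSet()
        fam = {}
        starts = {}
        for i in range(400):
            start = int(rng.integers(0, 49_900))
            strand = "+" if rng.random() < 0.5 else "-"
            rid = f"r{i}"
            a = _aln(rid, start, strand=strand)
            aset.add(a)
            fam[rid] = "copia"
            starts[rid] = a.genomic_start
        cm = count_window_reads({"s": aset}, {"s": fam}, windows, genome)
        for j in windows:
            ws, we = j.window
            brute = sum(1 for rid, s in starts.items() if ws <= s < we)
            assert cm.counts.loc[j.junction_id, "s"] == brute

    def test_half_open_boundary(self):
        genome = ReferenceGenome(contigs={"c": "A" * 10_000})
        j = _vj(5000, True)  # window [4700, 5000)
        aset = AlignmentSet()
        for rid, start in [("at_start", 4700), ("before", 4699), ("at_end", 5000),
                           ("last_in", 4999)]:
            aset.add(_aln(rid, start))
        fam = {rid: "copia" for rid, _ in aset}
        cm = count_window_reads({"s": aset}, {"s": fam}, [j], genome)
        assert cm.counts.iloc[0, 0] == 2  # at_start and last_in only

    def test_unknown_contig_rejected(self):
        genome = ReferenceGenome(contigs={"c": "A" * 10_000})
        with pytest.raises(DataError, match="unknown contig"):
            count_window_reads({}, {}, [_vj(500, True, contig="cX")], genome)

    def test_read_counted_in_every_containing_window(self):
        genome = ReferenceGenome(contigs={"c": "A" * 10_000})
        j1 = _vj(5000, True, window=(4700, 5000))
        j2 = _vj(4996, False, window=(4996, 5296))
        aset = AlignmentSet()
        aset.add(_aln("both", 4998))
        cm = count_window_reads(
            {"s": aset}, {"s": {"both": "copia"}}, [j1, j2], genome
        )
        assert cm.counts["s"].tolist() == [1, 1]


class TestNormalize:
    def _cm(self, counts, totals):
        df = pd.DataFrame(counts)
        return CountMatrix(counts=df, totals=pd.Series(totals))

    def test_cpm_unit_definition(self):
        cm = self._cm({"a": [10], "b": [10]}, {"a": 1_000_000, "b": 2_000_000})
        nm = normalize(cm)
        assert nm.values["a"].iloc[0] == 10.0
        assert nm.values["b"].iloc[0] == 5.0

    def test_zero_column_stays_zero(self):
        cm = self._cm({"a": [0, 0]}, {"a": 500_000})
        assert (normalize(cm).values["a"] == 0).all()

    def test_zero_total_names_sample(self):
        cm = self._cm({"bad": [1]}, {"bad": 0})
        with pytest.raises(DataError, match="bad"):
            normalize(cm)

    def test_unknown_strategy_rejected(self):
        cm = self._cm({"a": [1]}, {"a": 10})
        with pytest.raises(ConfigError):
            normalize(cm, strategy="quantile")


def _nm(rows):
    df = pd.DataFrame(rows, dtype=float)
    df.index = [f"c:{i}:5p:copia" for i in range(len(df))]
    return NormalizedMatrix(values=df, totals=pd.Series(
        {c: 1.0 for c in df.columns}))


def literal_dummy_zero_z(row):
    """Oracle: explicit augmented-vector z-score computation."""
    S = len(row)
    aug = np.concatenate([row, np.zeros(S)])
    mu, sigma = aug.mean(), aug.std()
    if sigma == 0:
        return np.zeros(S)
    return (row - mu) / sigma


class TestBinarize:
    def test_all_equal_positive_row_is_all_present(self):
        # the pathology the dummy zeros fix: plain z would call all absent
        bm = binarize(_nm({"s1": [5.0], "s2": [5.0], "s3": [5.0]}))
        assert bm.presence.iloc[0].all()
        plain = (np.array([5.0, 5, 5]) - 5.0)  # plain z numerator: all 0
        assert not (plain > 0).any()

    def test_all_zero_row_is_all_absent(self):
        bm = binarize(_nm({"s1": [0.0], "s2": [0.0], "s3": [0.0]}))
        assert not bm.presence.iloc[0].any()

    def test_single_positive_among_zeros(self):
        bm = binarize(_nm({"s1": [10.0], "s2": [0.0], "s3": [0.0]}))
        assert bm.presence.iloc[0].tolist() == [True, False, False]

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_closed_form_and_literal_z(self, trial):
        rng = np.random.default_rng(trial)
        S = int(rng.integers(2, 9))
        rows = rng.choice([0.0, 0.0, 1.0, 5.0, 20.0], size=(12, S)) * rng.random(
            (12, S)
        )
        nm = _nm({f"s{i}": rows[:, i] for i in range(S)})
        bm = binarize(nm)
        x = nm.values.to_numpy()
        closed = x > x.sum(axis=1, keepdims=True) / (2 * S)
        assert (bm.presence.to_numpy() == closed).all()
        for r in range(x.shape[0]):
            z = literal_dummy_zero_z(x[r])
            assert np.allclose(bm.zscores.to_numpy()[r], z)
            assert ((z > 0) == bm.presence.to_numpy()[r]).all()

    @given(
        st.lists(st.floats(0, 1000, allow_nan=False), min_size=2, max_size=6),
        st.floats(0.01, 100),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_scale_invariance(self, row, c):
        nm1 = _nm({f"s{i}": [v] for i, v in enumerate(row)})
        nm2 = _nm({f"s{i}": [v * c] for i, v in enumerate(row)})
        assert binarize(nm1).presence.equals(binarize(nm2).presence)


class TestReplicateConsistency:
    def test_equal_depth_replicates_have_identical_binary_profiles(
        self, te_db, small_ref
    ):
        """Noise-free replicates subsampled to one depth binarize alike."""
        from gted import call_junctions, plant_insertions
        from gted.pipeline import profile_samples
        from gted.simulate import generate_read_pairs

        geno, _ = plant_insertions(small_ref, te_db, 3, seed=41, line_name="L")
        samples = {}
        for rep, seed in (("L_1", 1), ("L_2", 2)):
            pairs = generate_read_pairs(
                small_ref, geno, te_db, pairs_per_junction=20, seed=seed,
                sample_id=rep,
            )
            samples[rep] = subsample_pairs(pairs, 600, seed=9)
        callres = call_junctions(samples, te_db, small_ref)
        bm, _ = profile_samples(callres, small_ref)
        assert bm.presence["L_1"].equals(bm.presence["L_2"])
        assert bm.presence["L_1"].any()
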