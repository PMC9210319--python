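"""Shared fixtures: synthetic TE database, references, and cohorts.

The expensive simulated cohorts are session-scoped and shared between
the clustering, identification and stability tests; their parameters
are the desk-scale study conditions (5 active families, triplicate
samples, 20 pairs per junction) and are not tuned per test.
"""

import numpy as np
import pytest

from gted import (
    LineSpec,
    build_reference,
    call_junctions,
    expected_junctions,
    plant_insertions,
    simulate_cohort,
    synthetic_te_database,
)
from gted.pipeline import profile_samples
from gted.simulate import generate_read_pairs


@pytest.fixture(scope="session")
def te_db():
    return synthetic_te_database(seed=7)


@pytest.fixture(scope="session")
def small_ref():
    return build_reference(2, 30_000, seed=11)


@pytest.fixture(scope="session")
def single_line(te_db, small_ref):
    """One line, 5 families x 10 insertions, noise-free 20 pairs/junction."""
    genotype, line_genome = plant_insertions(
        small_ref, te_db, 10, seed=3, line_name="A"
    )
    pairs = generate_read_pairs(
        small_ref, genotype, te_db, pairs_per_junction=20, seed=5, sample_id="A_1"
    )
    return {
        "genotype": genotype,
        "line_genome": line_genome,
        "pairs": pairs,
        "truth": expected_junctions(genotype),
    }


@pytest.fixture(scope="session")
def single_line_calls(single_line, te_db, small_ref):
    return call_junctions({"A_1": single_line["pairs"]}, te_db, small_ref)


@pytest.fixture(scope="session")
def cohort56(te_db):
    """Five known lines (one subline pair at 50% sharing), one novel line,
    one background-only sample set, 2% read error, triplicates."""
    ref = build_reference(4, 100_000, seed=11)
    lines = [
        LineSpec("A"),
        LineSpec("B"),
        LineSpec("C"),
        LineSpec("D"),
        LineSpec("E", share_with="D", share_frac=0.5),
        LineSpec("F"),  # novel genotype, kept out of the signature db
        LineSpec("foreign", n_per_family=0, replicates=3, background_pairs=500),
    ]
    cohort = simulate_cohort(
        ref,
        te_db,
        lines,
        pairs_per_junction=20,
        error_rate=0.02,
        depth_jitter=0.1,
        seed=42,
    )
    callres = call_junctions(cohort.samples, te_db, ref)
    bm, zero_samples = profile_samples(callres, ref)
    return {
        "ref": ref,
        "cohort": cohort,
        "callres": callres,
        "bm": bm,
        "zero_samples": zero_samples,
        "known_lines": list("ABCDE"),
    }


@pytest.fixture(scope="session")
def passage_cohort(te_db):
    """Six 'passages' x 3 replicates of a single genotype (1% error)."""
    ref = build_reference(2, 60_000, seed=23)
    lines = [LineSpec("S2Rplus", n_per_family=6, replicates=3)]
    base = simulate_cohort(
        ref, te_db, lines, pairs_per_junction=20, error_rate=0.01, seed=77
    )
    genotype = base.truth.genotypes["S2Rplus"]
    rng = np.random.default_rng(78)
    samples = {}
    batch = {}
    for passage in range(1, 7):
        for rep in range(1, 4):
            sid = f"P{passage * 10}_{rep}"
            samples[sid] = generate_read_pairs(
                ref,
                genotype,
                te_db,
                pairs_per_junction=20,
                error_rate=0.01,
                seed=int(rng.integers(0, 2**31 - 1)),
                sample_id=sid,
            )
            batch[sid] = f"P{passage * 10}"
    callres = call_junctions(samples, te_db, ref)
    bm, _ = profile_samples(callres, ref)
    return {"ref": ref, "bm": bm, "batch": batch, "callres": callres}
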