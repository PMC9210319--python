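"""Per-sample junction profiles: counting, normalization, binarization.

A junction's signal in one sample is the number of retained R1 reads
(uniquely mapped, demultiplexed to the junction's family) whose
strand-aware genomic start falls in the junction's flank window.  Counts
are depth-normalized (counts per million mapped reads by default) and
then binarized per junction with the dummy-zero z-score rule: for S real
samples, append S zeros before computing z-scores, and call a sample
"present" iff its z-score is strictly positive.  The padding prevents
the pathology of plain z-scoring where a junction present in all
samples would mark half of them absent.  Algebraically the rule reduces
to: present  ⇔  x_i > (row sum) / (2 S).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .align import AlignmentSet
from .errors import ConfigError, DataError
from .junctions import ValidJunction
from .refdb import ReferenceGenome
from .simulate import ReadPair

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "BinaryProfileMatrix",
    "subsample_pairs",
    "count_window_reads",
    "normalize",
    "binarize",
]


@dataclass
class CountMatrix:
    counts: pd.DataFrame  # junctions x samples, int
    totals: pd.Series  # mapped-read totals per sample

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.totals.index):
            raise DataError("count matrix columns and totals disagree")


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame
    totals: pd.Series
    strategy: str = "cpm"


@dataclass
class BinaryProfileMatrix:
    presence: pd.DataFrame  # bool
    zscores: pd.DataFrame  # provenance: augmented-vector z per cell

    def keys_for(self, sample: str) -> set[tuple[str, int, str, str]]:
        """Junction keys called present in one sample column."""
        out = set()
        for jid in self.presence.index[self.presence[sample]]:
            contig, bp, side, family = jid.rsplit(":", 3)
            out.add((contig, int(bp), side, family))
        return out


# ---------------------------------------------------------------------------
# Subsampling


def subsample_pairs(pairs: list[ReadPair], n: int, seed: int = 0) -> list[ReadPair]:
    """Uniform sample of min(n, total) pairs, without replacement.

    Membership is decided on the sorted read ids, so the same pairs are
    chosen regardless of input order; input order is preserved in the
    output.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ConfigError("subsample size must be >= 1")
    if n >= len(pairs):
        return list(pairs)
    ids = sorted(p.read_id for p in pairs)
    rng = np.random.default_rng(seed)
    chosen = set(
        ids[i] for i in rng.choice(len(ids), size=n, replace=False)
    )
    return [p for p in pairs if p.read_id in chosen]


# ---------------------------------------------------------------------------
# Window counting


def count_window_reads(
    genome_alns: dict[str, AlignmentSet],
    read_family: dict[str, dict[str, str]],
    junctions: list[ValidJunction],
    genome: ReferenceGenome,
) -> CountMatrix:
    """Count retained family-matched R1 starts per flank window per sample.

    A read is assigned to every window containing its strand-aware start
    (windows of distinct junctions may abut or overlap near a TSD).  The
    per-sample total is the number of retained, family-binned R1
    alignments — the denominator for CPM normalization.
    """
    for j in junctions:
        if j.contig not in genome.contigs:
            raise DataError(f"window references unknown contig {j.contig!r}")
        if j.window is None:
            raise DataError(f"junction {j.junction_id} has no flank window")

    samples = list(genome_alns)
    jids = [j.junction_id for j in junctions]
    counts = np.zeros((len(junctions), len(samples)), dtype=np.int64)

    # per (contig, family): windows sorted by start for bounded backscan
    by_group: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    max_width = 1
    for row, j in enumerate(junctions):
        ws, we = j.window
        max_width = max(max_width, we - ws)
        by_group.setdefault((j.contig, j.family), []).append((ws, we, row))
    for group in by_group.values():
        group.sort()

    for col, sid in enumerate(samples):
        fam_map = read_family.get(sid, {})
        for read_id, alns in genome_alns[sid]:
            fam = fam_map.get(read_id)
            if fam is None:
                continue
            best = max(alns, key=lambda a: a.score)
            group = by_group.get((best.target_name, fam))
            if not group:
                continue
            s = best.genomic_start
            # windows with ws <= s < we; ws within max_width of s
            hi = bisect.bisect_right(group, (s, np.inf, np.inf))
            i = hi - 1
            while i >= 0 and group[i][0] > s - max_width:
                ws, we, row = group[i]
                if ws <= s < we:
                    counts[row, col] += 1
                i -= 1

    totals = pd.Series(
        {
            sid: sum(
                1
                for rid in genome_alns[sid].read_ids()
                if rid in read_family.get(sid, {})
            )
            for sid in samples
        },
        dtype=np.int64,
    )
    df = pd.DataFrame(counts, index=jids, columns=samples)
    return CountMatrix(counts=df, totals=totals)


# ---------------------------------------------------------------------------
# Normalization


def normalize(cm: CountMatrix, strategy: str = "cpm") -> NormalizedMatrix:
    """Depth-normalize counts.

    ``cpm``: counts per million mapped reads (per-sample totals);
    ``total-junction-reads``: per million reads inside any window;
    ``none``: raw counts as floats.
    """
    if strategy == "cpm":
        denom = cm.totals.astype(float)
    elif strategy == "total-junction-reads":
        denom = cm.counts.sum(axis=0).astype(float)
    elif strategy == "none":
        return NormalizedMatrix(
            values=cm.counts.astype(float), totals=cm.totals, strategy=strategy
        )
    else:
        raise ConfigError(f"unknown normalization strategy {strategy!r}")
    zero = denom[denom == 0]
    if len(zero):
        raise DataError(f"zero mapped-read total for sample(s) {list(zero.index)}")
    values = cm.counts.astype(float) * 1e6 / denom
    return NormalizedMatrix(values=values, totals=cm.totals, strategy=strategy)


# ---------------------------------------------------------------------------
# Dummy-zero z-score binarization


def binarize(nm: NormalizedMatrix) -> BinaryProfileMatrix:
    """Present iff the dummy-zero-augmented z-score is strictly positive.

    Per junction row with S samples the augmented vector holds the S
    values plus S zeros; z_i = (x_i - mu) / sigma with the population
    sigma over all 2S entries (the sigma choice cannot change the sign
    of z, hence not the call).  An all-zero row (sigma = 0) is absent
    everywhere, as is any exact z = 0.
    """
    x = nm.values.to_numpy(dtype=float)
    n_rows, S = x.shape
    if S == 0:
        raise DataError("no samples to binarize")
    row_sum = x.sum(axis=1, keepdims=True)
    mu = row_sum / (2 * S)
    var = (((x - mu) ** 2).sum(axis=1, keepdims=True) + S * mu**2) / (2 * S)
    sigma = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, (x - mu) / sigma, 0.0)
    presence = z > 0
    return BinaryProfileMatrix(
        presence=pd.DataFrame(
            presence, index=nm.values.index, columns=nm.values.columns
        ),
        zscores=pd.DataFrame(z, index=nm.values.index, columns=nm.values.columns),
    )


# ---------------------------------------------------------------------------
# IO


def write_matrix_tsv(
    df: pd.DataFrame, path: str | Path, header: str | None = None, as_int: bool = False
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        out = df.astype(int) if as_int else df
        out.to_csv(fh, sep="\t", index_label="junction_id")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="junction_id")
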