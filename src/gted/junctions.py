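"""Demultiplexing, breakpoint detection and the valid-junction filter.

A junction is the genomic coordinate where unique genomic context
transitions into TE sequence.  Detection works on read pairs from the
enrichment library:

1. R2 is aligned to the active TE consensi; the pair is binned by the
   best-scoring family (ties between families, or no qualifying
   alignment, go to UNASSIGNED).  The LTR the R2 hit names the element
   terminus (5'/3') the fragment spans.
2. The binned R1 is aligned to the N-masked genome; only reads with a
   uniquely best genomic hit survive.  R1 is also aligned to the TE
   consensi.
3. A read whose genome and TE local alignments are congruent — jointly
   accounting for the whole read within a small slack — yields a
   breakpoint, obtained by projecting the TE-alignment query boundary
   through the genome alignment (stable under end trimming and
   junction micro-homology).
4. Support is pooled over every sample in the run; breakpoints within a
   small merge window collapse to their modal position.  A valid
   junction needs at least ``min_reads`` supporting reads with at least
   ``min_starts`` distinct R1 genomic start positions, and receives a
   flank window of up to ``flank`` bp of genomic sequence immediately
   outside the element.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

from .align import (
    AlignmentSet,
    LocalAlignment,
    Scoring,
    DEFAULT_SCORING,
    TargetIndex,
    align_reads,
    filter_unique_best,
    local_align,
)
from .errors import DataError
from .refdb import ReferenceGenome, TEDatabase
from .simulate import ReadPair

__all__ = [
    "UNASSIGNED",
    "R2Assignment",
    "DemuxResult",
    "JunctionCandidate",
    "ValidJunction",
    "demultiplex_pairs",
    "test_congruence",
    "collect_candidates",
    "filter_valid",
    "extract_flank_windows",
    "call_junctions",
    "JunctionCallResult",
    "junctions_to_bed",
    "junctions_to_tsv",
]

UNASSIGNED = "UNASSIGNED"

# Split alignments (genome or TE segment of a junction-spanning R1) cover
# only part of the read, so the junction stage aligns at a lower score
# floor than the 0.6 used for fully-TE-internal R2 demultiplexing.
JUNCTION_MIN_SCORE_FRAC = 0.3
DEFAULT_MERGE_WINDOW = 3
DEFAULT_MIN_READS = 12
DEFAULT_MIN_STARTS = 4
DEFAULT_FLANK = 300
TERMINAL_TOL = 6
# Junction micro-homology plus chance extension of the genome alignment
# into the element can overlap the two query intervals by well over the
# slack; the breakpoint projection is immune to it (far-end anchored), so
# the cap only needs to reject chimera-scale overlaps.
MAX_OVERLAP = 25


@dataclass(frozen=True)
class R2Assignment:
    family: str
    side: str  # '5p'/'3p': which LTR the R2 anchored in
    score: int


@dataclass
class DemuxResult:
    """Partition of one sample's pairs into family bins + UNASSIGNED."""

    bins: dict[str, dict[str, R2Assignment]]
    unassigned: list[str]
    n_pairs: int

    def family_of(self, read_id: str) -> str | None:
        for fam, members in self.bins.items():
            if read_id in members:
                return fam
        return None

    @property
    def counts(self) -> dict[str, int]:
        out = {fam: len(members) for fam, members in self.bins.items()}
        out[UNASSIGNED] = len(self.unassigned)
        return out


@dataclass
class JunctionCandidate:
    contig: str
    breakpoint: int
    side: str
    family: str
    te_right: bool
    support: list[tuple[str, str]]  # (sample_id, read_id)
    r1_starts: list[int]

    @property
    def n_reads(self) -> int:
        return len(self.support)

    @property
    def n_distinct_starts(self) -> int:
        return len(set(self.r1_starts))

    @property
    def te_orientation(self) -> str:
        if self.side == "5p":
            return "+" if self.te_right else "-"
        return "-" if self.te_right else "+"


@dataclass
class ValidJunction:
    contig: str
    breakpoint: int
    side: str
    family: str
    te_right: bool
    n_reads: int
    n_distinct_starts: int
    window: tuple[int, int] | None = None  # [start, end) genomic flank

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.breakpoint, self.side, self.family)

    @property
    def junction_id(self) -> str:
        return f"{self.contig}:{self.breakpoint}:{self.side}:{self.family}"

    @property
    def te_orientation(self) -> str:
        if self.side == "5p":
            return "+" if self.te_right else "-"
        return "-" if self.te_right else "+"


# ---------------------------------------------------------------------------
# Demultiplexing


def _ltr_side(fam, aln: LocalAlignment) -> str:
    """Which LTR an R2-to-consensus alignment anchors in."""
    l5 = len(fam.ltr5)
    l3_start = len(fam.consensus) - len(fam.ltr3)
    ov5 = max(0, min(aln.target_end, l5) - aln.target_start)
    ov3 = max(0, aln.target_end - max(aln.target_start, l3_start))
    return "5p" if ov5 >= ov3 else "3p"


def demultiplex_pairs(
    pairs: list[ReadPair],
    db: TEDatabase,
    te_index: TargetIndex | None = None,
    *,
    scoring: Scoring = DEFAULT_SCORING,
    min_score_frac: float = 0.6,
    method: str = "seeded",
) -> DemuxResult:
    """Assign each pair to the family of its R2's best consensus hit.

    A score tie between two families, or no alignment reaching the score
    floor, sends the pair to UNASSIGNED.  Bin sizes plus UNASSIGNED
    always sum to the input count.
    """
    active = {f.name: f for f in db.active}
    if te_index is None:
        te_index = TargetIndex({n: f.consensus for n, f in active.items()})
    bins: dict[str, dict[str, R2Assignment]] = {n: {} for n in active}
    unassigned: list[str] = []
    for pair in pairs:
        alns = local_align(
            pair.r2_seq,
            te_index,
            scoring,
            min_score_frac=min_score_frac,
            method=method,
            read_id=pair.read_id,
        )
        if not alns:
            unassigned.append(pair.read_id)
            continue
        best = alns[0]
        if (
            len(alns) > 1
            and alns[1].score == best.score
            and alns[1].target_name != best.target_name
        ):
            unassigned.append(pair.read_id)
            continue
        fam = active[best.target_name]
        bins[fam.name][pair.read_id] = R2Assignment(
            family=fam.name, side=_ltr_side(fam, best), score=best.score
        )
    return DemuxResult(bins=bins, unassigned=unassigned, n_pairs=len(pairs))


# ---------------------------------------------------------------------------
# Congruence


def test_congruence(
    read_len: int,
    genome_aln: LocalAlignment,
    te_aln: LocalAlignment,
    side: str,
    fam_len: int,
    *,
    slack: int = 2,
    terminal_tol: int = TERMINAL_TOL,
    max_overlap: int = MAX_OVERLAP,
) -> tuple[int, bool] | None:
    """Breakpoint of a split R1, or None if the alignments are incongruent.

    Accepts when the genome- and TE-aligned query intervals are
    non-nested and jointly account for the read: unexplained bases
    (gap between the intervals plus uncovered read ends, overlap
    credited) must not exceed ``slack``.  Micro-homology at the junction
    shows up as overlap and is tolerated up to ``max_overlap``.  The TE
    alignment must reach the consensus terminus named by ``side`` (the
    R2 bin), anchoring the projection.

    Returns (breakpoint, te_right): the first genomic base outside the
    element and whether the element lies genomically rightward.
    """
    qg0, qg1 = genome_aln.query_start, genome_aln.query_end
    qt0, qt1 = te_aln.query_start, te_aln.query_end
    if (qg0 <= qt0 and qt1 <= qg1) or (qt0 <= qg0 and qg1 <= qt1):
        return None  # nested: no transition
    len_g = qg1 - qg0
    len_t = qt1 - qt0
    unaccounted = read_len - len_g - len_t
    if unaccounted > slack:
        return None
    if -unaccounted > max_overlap:
        return None
    if side == "5p":
        if te_aln.target_start > terminal_tol:
            return None
    else:
        if te_aln.target_end < fam_len - terminal_tol:
            return None
    # Project the TE-alignment boundary through the genome alignment from
    # its far (junction-distal) end: the junction-proximal end can
    # over-extend across the breakpoint via micro-homology, sometimes with
    # a spurious gap, while the distal end lies in clean genomic sequence.
    genome_first = qg0 < qt0
    if genome_first:
        q_boundary = qt0
        if genome_aln.strand == "+":
            bp = genome_aln.target_start + (q_boundary - qg0)
            te_right = True
        else:
            bp = genome_aln.target_end - (q_boundary - qg0)
            te_right = False
    else:
        q_boundary = qt1
        if genome_aln.strand == "+":
            bp = genome_aln.target_end - (qg1 - q_boundary)
            te_right = False
        else:
            bp = genome_aln.target_start + (qg1 - q_boundary)
            te_right = True
    return int(bp), te_right


# ---------------------------------------------------------------------------
# Candidate collection (pooled across samples)


def collect_candidates(
    demux: dict[str, DemuxResult],
    genome_alns: dict[str, AlignmentSet],
    r1_te_alns: dict[str, AlignmentSet],
    db: TEDatabase,
    *,
    slack: int = 2,
    merge_window: int = DEFAULT_MERGE_WINDOW,
) -> list[JunctionCandidate]:
    """Pool congruent split reads from every sample into candidates.

    Breakpoints within ``merge_window`` of each other (same contig, side,
    family, TE direction) collapse into one candidate at the modal
    position (ties broken toward the smaller coordinate).
    """
    raw: dict[tuple, list[tuple[int, str, str, int]]] = {}
    for sid, dres in demux.items():
        g_set = genome_alns[sid]
        t_set = r1_te_alns[sid]
        for fam_name, members in dres.bins.items():
            fam = db[fam_name]
            for read_id, assign in members.items():
                if read_id not in g_set or read_id not in t_set:
                    continue
                g_aln = g_set.best(read_id)
                # try every family-matched TE alignment, best first: the
                # top hit can be a co-optimal alignment to the homologous
                # other-LTR copy, which the terminus check rejects
                res = None
                for te_aln in sorted(
                    (a for a in t_set[read_id] if a.target_name == fam_name),
                    key=lambda a: -a.score,
                ):
                    res = test_congruence(
                        g_aln.read_len,
                        g_aln,
                        te_aln,
                        assign.side,
                        len(fam),
                        slack=slack,
                    )
                    if res is not None:
                        break
                if res is None:
                    continue
                bp, te_right = res
                key = (g_aln.target_name, assign.side, fam_name, te_right)
                raw.setdefault(key, []).append(
                    (bp, sid, read_id, g_aln.genomic_start)
                )

    candidates: list[JunctionCandidate] = []
    for (contig, side, fam_name, te_right), recs in sorted(raw.items()):
        for cluster in cluster_breakpoints(recs, merge_window):
            candidates.append(
                _make_candidate(contig, side, fam_name, te_right, cluster)
            )
    candidates.sort(key=lambda c: (c.contig, c.breakpoint, c.side, c.family))
    return candidates


def cluster_breakpoints(
    records: list[tuple], merge_window: int = DEFAULT_MERGE_WINDOW
) -> list[list[tuple]]:
    """Single-linkage grouping of records keyed by leading breakpoint.

    Consecutive sorted breakpoints more than ``merge_window`` apart start
    a new group.
    """
    clusters: list[list[tuple]] = []
    cluster: list[tuple] = []
    for rec in sorted(records):
        if cluster and rec[0] - cluster[-1][0] > merge_window:
            clusters.append(cluster)
            cluster = []
        cluster.append(rec)
    if cluster:
        clusters.append(cluster)
    return clusters


def _make_candidate(
    contig: str,
    side: str,
    fam_name: str,
    te_right: bool,
    cluster: list[tuple[int, str, str, int]],
) -> JunctionCandidate:
    counts = Counter(bp for bp, *_ in cluster)
    top = max(counts.values())
    modal = min(bp for bp, c in counts.items() if c == top)
    return JunctionCandidate(
        contig=contig,
        breakpoint=modal,
        side=side,
        family=fam_name,
        te_right=te_right,
        support=[(sid, rid) for _, sid, rid, _ in cluster],
        r1_starts=[start for *_, start in cluster],
    )


# ---------------------------------------------------------------------------
# Valid-junction filter and flank windows


def filter_valid(
    candidates: list[JunctionCandidate],
    min_reads: int = DEFAULT_MIN_READS,
    min_starts: int = DEFAULT_MIN_STARTS,
) -> list[ValidJunction]:
    """Keep candidates with >= min_reads reads and >= min_starts starts."""
    out = []
    for c in candidates:
        if c.n_reads >= min_reads and c.n_distinct_starts >= min_starts:
            out.append(
                ValidJunction(
                    contig=c.contig,
                    breakpoint=c.breakpoint,
                    side=c.side,
                    family=c.family,
                    te_right=c.te_right,
                    n_reads=c.n_reads,
                    n_distinct_starts=c.n_distinct_starts,
                )
            )
    return out


def extract_flank_windows(
    junctions: list[ValidJunction],
    genome: ReferenceGenome,
    width: int = DEFAULT_FLANK,
) -> list[ValidJunction]:
    """Attach the <= ``width`` bp genomic window outside each junction.

    TE rightward of the breakpoint -> window on the left,
    [breakpoint - width, breakpoint); TE leftward -> window on the right,
    [breakpoint, breakpoint + width); truncated at contig bounds.
    """
    out = []
    for j in junctions:
        if j.contig not in genome.contigs:
            raise DataError(f"junction contig {j.contig!r} not in genome")
        clen = len(genome.contigs[j.contig])
        if j.te_right:
            win = (max(0, j.breakpoint - width), j.breakpoint)
        else:
            win = (j.breakpoint, min(clen, j.breakpoint + width))
        out.append(replace(j, window=win))
    return out


# ---------------------------------------------------------------------------
# High-level driver


@dataclass
class JunctionCallResult:
    """Everything downstream profiling needs from junction calling."""

    junctions: list[ValidJunction]
    candidates: list[JunctionCandidate]
    demux: dict[str, DemuxResult]
    genome_alns: dict[str, AlignmentSet]  # retained unique-best R1 hits
    read_family: dict[str, dict[str, str]]
    totals: dict[str, int] = field(default_factory=dict)


def call_junctions(
    samples: dict[str, list[ReadPair]],
    db: TEDatabase,
    genome: ReferenceGenome,
    *,
    scoring: Scoring = DEFAULT_SCORING,
    min_reads: int = DEFAULT_MIN_READS,
    min_starts: int = DEFAULT_MIN_STARTS,
    slack: int = 2,
    merge_window: int = DEFAULT_MERGE_WINDOW,
    flank: int = DEFAULT_FLANK,
    demux_min_score_frac: float = 0.6,
    split_min_score_frac: float = JUNCTION_MIN_SCORE_FRAC,
) -> JunctionCallResult:
    """Run demultiplex -> align -> congruence -> pooled filter -> windows."""
    te_index = TargetIndex({f.name: f.consensus for f in db.active})
    genome_index = TargetIndex(genome.contigs)

    demux: dict[str, DemuxResult] = {}
    genome_alns: dict[str, AlignmentSet] = {}
    r1_te_alns: dict[str, AlignmentSet] = {}
    read_family: dict[str, dict[str, str]] = {}
    totals: dict[str, int] = {}

    for sid, pairs in samples.items():
        dres = demultiplex_pairs(
            pairs, db, te_index, scoring=scoring, min_score_frac=demux_min_score_frac
        )
        demux[sid] = dres
        binned_ids = {rid for members in dres.bins.values() for rid in members}
        binned_r1 = [(p.read_id, p.r1_seq) for p in pairs if p.read_id in binned_ids]
        g_all = align_reads(
            binned_r1,
            genome_index,
            scoring,
            min_score_frac=split_min_score_frac,
            method="seeded",
            target_db="genome",
        )
        g_ret = filter_unique_best(g_all)
        genome_alns[sid] = g_ret
        r1_te_alns[sid] = align_reads(
            binned_r1,
            te_index,
            scoring,
            min_score_frac=split_min_score_frac,
            method="seeded",
            target_db="te",
        )
        fam_map = {
            rid: fam for fam, members in dres.bins.items() for rid in members
        }
        read_family[sid] = fam_map
        totals[sid] = sum(1 for rid in g_ret.read_ids() if rid in fam_map)

    candidates = collect_candidates(
        demux, genome_alns, r1_te_alns, db, slack=slack, merge_window=merge_window
    )
    valid = filter_valid(candidates, min_reads=min_reads, min_starts=min_starts)
    valid = extract_flank_windows(valid, genome, width=flank)
    return JunctionCallResult(
        junctions=valid,
        candidates=candidates,
        demux=demux,
        genome_alns=genome_alns,
        read_family=read_family,
        totals=totals,
    )


# ---------------------------------------------------------------------------
# Writers


def junctions_to_bed(
    junctions: list[ValidJunction], path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for j in junctions:
            ws, we = j.window if j.window else (j.breakpoint, j.breakpoint + 1)
            fh.write(
                f"{j.contig}\t{ws}\t{we}\t{j.family}:{j.side}\t{j.n_reads}\t"
                f"{j.te_orientation}\n"
            )


def junctions_to_tsv(
    junctions: list[ValidJunction], path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write(
            "contig\tbreakpoint\tside\tfamily\tte_orientation\tn_reads\t"
            "n_distinct_starts\twindow_start\twindow_end\n"
        )
        for j in junctions:
            ws, we = j.window if j.window else ("", "")
            fh.write(
                f"{j.contig}\t{j.breakpoint}\t{j.side}\t{j.family}\t"
                f"{j.te_orientation}\t{j.n_reads}\t{j.n_distinct_starts}\t"
                f"{ws}\t{we}\n"
            )
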