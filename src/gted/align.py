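"""Local alignment of reads to TE consensi and to the (masked) genome.

The contract mirrors ``bowtie2 --local -k 2``: for each read we report
the best local alignment plus the score of the best alignment at a
*distinct* locus (another target, another strand, or the same target with
a start more than one read length away).  :func:`filter_unique_best`
then drops every read whose best hit is tied — the "uniquely best match"
rule.

Two search strategies share one scoring engine (affine-gap local DP,
see ``_kernels``):

``exhaustive``
    full DP against every target, both strands.  Exact for arbitrary
    inputs; the default for small target sets (<= ~8 kb total).
``seeded``
    exact k-mer seeds (default k=15) looked up in a sorted index, hit
    clusters expanded into windows, DP run per window.  Used for
    desk-scale genomes; finds any alignment containing one exact k-mer.

Real-scale users align externally and load SAM via :func:`ingest_sam`;
:func:`export_sam` writes the built-in aligner's output in the same
dialect (AS = score, XS = second-best score).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pysam

from ._kernels import local_align_ends, local_dp_matrix, second_best_distinct
from .errors import ConfigError, DataError
from .seqs import encode, kmer_codes, revcomp_encoded

__all__ = [
    "Scoring",
    "LocalAlignment",
    "AlignmentSet",
    "TargetIndex",
    "local_align",
    "filter_unique_best",
    "ingest_sam",
    "export_sam",
]

MIN_READ_LEN = 20
_EXHAUSTIVE_LIMIT = 8000


@dataclass(frozen=True)
class Scoring:
    """Local-alignment scoring; a gap of length k costs open + (k-1)*extend."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


DEFAULT_SCORING = Scoring()


@dataclass
class LocalAlignment:
    """One local alignment; query coordinates are on the original read.

    ``target_start < target_end`` and ``query_start < query_end`` are
    0-based half-open.  For strand '-' the reverse complement of the read
    aligned to the forward target; query coordinates are mapped back to
    the read as sequenced.
    """

    read_id: str
    target_name: str
    target_start: int
    target_end: int
    query_start: int
    query_end: int
    strand: str
    score: int
    second_best_score: int | None = None
    read_len: int = 0

    def __post_init__(self) -> None:
        if not (self.target_start < self.target_end):
            raise DataError("target_start must be < target_end")
        if not (self.query_start < self.query_end):
            raise DataError("query_start must be < query_end")
        if self.second_best_score is not None and self.score < self.second_best_score:
            raise DataError("score must be >= second_best_score")

    @property
    def genomic_start(self) -> int:
        """Strand-aware 5' end of the alignment on the target."""
        return self.target_start if self.strand == "+" else self.target_end - 1


class AlignmentSet:
    """Alignments grouped by read id, insertion-ordered."""

    def __init__(self, target_db: str = "") -> None:
        self.target_db = target_db
        self._by_read: dict[str, list[LocalAlignment]] = {}
        self.n_unmapped = 0

    def add(self, aln: LocalAlignment) -> None:
        self._by_read.setdefault(aln.read_id, []).append(aln)

    def best(self, read_id: str) -> LocalAlignment | None:
        alns = self._by_read.get(read_id)
        if not alns:
            return None
        return max(alns, key=lambda a: a.score)

    def __getitem__(self, read_id: str) -> list[LocalAlignment]:
        return self._by_read[read_id]

    def __contains__(self, read_id: str) -> bool:
        return read_id in self._by_read

    def __iter__(self):
        return iter(self._by_read.items())

    def __len__(self) -> int:
        return len(self._by_read)

    def read_ids(self) -> list[str]:
        return list(self._by_read)


# ---------------------------------------------------------------------------
# Target index


class TargetIndex:
    """Named targets plus a sorted exact k-mer seed index.

    Targets are concatenated with k N spacers; seed positions are stored
    in concatenated coordinates and mapped back per hit.
    """

    def __init__(self, targets: dict[str, str], k: int = 15) -> None:
        if not targets:
            raise DataError("empty target database")
        self.k = k
        self.names = list(targets)
        self.sequences = {n: s.upper() for n, s in targets.items()}
        spacer = np.full(k, 4, dtype=np.uint8)
        parts: list[np.ndarray] = []
        offsets: list[int] = []
        pos = 0
        for name in self.names:
            offsets.append(pos)
            arr = encode(self.sequences[name])
            parts.append(arr)
            pos += arr.shape[0]
            parts.append(spacer)
            pos += k
        self._concat = np.concatenate(parts)
        self._offsets = np.array(offsets, dtype=np.int64)
        self._lengths = np.array(
            [len(self.sequences[n]) for n in self.names], dtype=np.int64
        )
        codes, valid = kmer_codes(self._concat, k)
        positions = np.nonzero(valid)[0]
        codes = codes[positions]
        order = np.argsort(codes, kind="stable")
        self._codes_sorted = codes[order]
        self._pos_sorted = positions[order]

    @property
    def total_length(self) -> int:
        return int(self._lengths.sum())

    def locate(self, concat_pos: int) -> tuple[int, int]:
        """Map a concatenated coordinate to (target_idx, local_pos)."""
        idx = int(np.searchsorted(self._offsets, concat_pos, side="right")) - 1
        return idx, int(concat_pos - self._offsets[idx])

    def seed_hits(
        self, q: np.ndarray, max_hits_per_seed: int = 64
    ) -> tuple[np.ndarray, np.ndarray]:
        """Seed hits as (diagonals, hit positions), concatenated coords."""
        codes, valid = kmer_codes(q, self.k)
        qpos = np.nonzero(valid)[0]
        codes = codes[qpos]
        empty = np.empty(0, dtype=np.int64)
        if codes.size == 0:
            return empty, empty
        lo = np.searchsorted(self._codes_sorted, codes, side="left")
        hi = np.searchsorted(self._codes_sorted, codes, side="right")
        diags: list[np.ndarray] = []
        tpos: list[np.ndarray] = []
        for i in range(codes.size):
            n_hits = hi[i] - lo[i]
            if n_hits == 0 or n_hits > max_hits_per_seed:
                continue
            hits = self._pos_sorted[lo[i] : hi[i]]
            diags.append(hits - qpos[i])
            tpos.append(hits)
        if not diags:
            return empty, empty
        return np.concatenate(diags), np.concatenate(tpos)

    def candidate_windows(
        self, q: np.ndarray, band: int = 16, pad: int = 12, max_windows: int = 30
    ) -> list[tuple[int, int, int]]:
        """Cluster seed diagonals into DP windows.

        Returns (target_idx, start, end) windows in local target
        coordinates, merged when overlapping.
        """
        m = q.shape[0]
        diags, tpos = self.seed_hits(q)
        if diags.size == 0:
            return []
        order0 = np.argsort(diags, kind="stable")
        diags = diags[order0]
        tpos = tpos[order0]
        # split clusters where consecutive diagonals differ by > band
        breaks = np.nonzero(np.diff(diags) > band)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks + 1, [diags.size]))
        # largest clusters first
        order = np.argsort(ends - starts, kind="stable")[::-1][:max_windows]
        raw: list[tuple[int, int, int]] = []
        for ci in order:
            d0 = int(diags[starts[ci]])
            d1 = int(diags[ends[ci] - 1])
            # target identity from an actual hit position (diagonals can
            # fall outside the target when the query overhangs its start)
            tidx, _ = self.locate(int(tpos[starts[ci]]))
            off = int(self._offsets[tidx])
            tlen = int(self._lengths[tidx])
            w0 = max(0, d0 - off - pad)
            w1 = min(tlen, d1 - off + m + pad)
            if w1 > w0:
                raw.append((tidx, w0, w1))
        # merge overlapping windows on the same target
        raw.sort()
        merged: list[tuple[int, int, int]] = []
        for tidx, w0, w1 in raw:
            if merged and merged[-1][0] == tidx and w0 <= merged[-1][2]:
                merged[-1] = (tidx, merged[-1][1], max(merged[-1][2], w1))
            else:
                merged.append((tidx, w0, w1))
        return merged

    def encoded(self, idx: int) -> np.ndarray:
        off = int(self._offsets[idx])
        return self._concat[off : off + int(self._lengths[idx])]


# ---------------------------------------------------------------------------
# Alignment search


def _query_coords(qs: int, qe: int, strand: str, read_len: int) -> tuple[int, int]:
    if strand == "+":
        return qs, qe
    return read_len - qe, read_len - qs


def local_align(
    read: str,
    targets: TargetIndex | dict[str, str],
    scoring: Scoring = DEFAULT_SCORING,
    *,
    min_score: int | None = None,
    min_score_frac: float = 0.6,
    method: str = "auto",
    read_id: str = "",
) -> list[LocalAlignment]:
    """Best (and second-best distinct-locus) local alignments of ``read``.

    Returns ``[]`` when no alignment reaches ``min_score`` (default
    ``min_score_frac * len(read) * match``); otherwise one or two
    alignments, the first carrying ``second_best_score`` when a distinct
    locus aligned as well.
    """
    if len(read) < MIN_READ_LEN:
        raise DataError(f"read shorter than {MIN_READ_LEN} bp")
    if not isinstance(targets, TargetIndex):
        targets = TargetIndex(targets)
    if method == "auto":
        method = "exhaustive" if targets.total_length <= _EXHAUSTIVE_LIMIT else "seeded"
    if min_score is None:
        min_score = int(round(min_score_frac * len(read) * scoring.match))

    m = len(read)
    q_fwd = encode(read)
    q_rev = revcomp_encoded(q_fwd)
    sc = (scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend)

    # candidate tuples: (score, tname, strand, t_start, t_end, q_start, q_end)
    cands: list[tuple[int, str, str, int, int, int, int]] = []

    if method == "exhaustive":
        for tidx, name in enumerate(targets.names):
            t = targets.encoded(tidx)
            if t.shape[0] == 0:
                continue
            for strand, q in (("+", q_fwd), ("-", q_rev)):
                H = local_dp_matrix(q, t, *sc)
                best = int(H.max())
                if best <= 0:
                    continue
                flat = int(np.argmax(H))
                bi, bj = divmod(flat, H.shape[1])
                s, qs, qe, ts, te = local_align_ends(q, t, *sc)
                oqs, oqe = _query_coords(qs, qe, strand, m)
                cands.append((s, name, strand, ts, te, oqs, oqe))
                s2 = second_best_distinct(H, bj, m)
                if s2 > 0:
                    # coordinates of the runner-up are only needed if it
                    # survives selection; recover them lazily below via a
                    # masked re-run.  Store end column as a placeholder.
                    cands.append(
                        _runner_up_alignment(q, t, H, bj, m, sc, name, strand)
                    )
        cands = [c for c in cands if c is not None]
    elif method == "seeded":
        for strand, q in (("+", q_fwd), ("-", q_rev)):
            for tidx, w0, w1 in targets.candidate_windows(q):
                t = targets.encoded(tidx)[w0:w1]
                s, qs, qe, ts, te = local_align_ends(q, t, *sc)
                if s <= 0:
                    continue
                oqs, oqe = _query_coords(qs, qe, strand, m)
                cands.append(
                    (s, targets.names[tidx], strand, w0 + ts, w0 + te, oqs, oqe)
                )
    else:
        raise ConfigError(f"unknown alignment method {method!r}")

    if not cands:
        return []
    cands.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    best = cands[0]
    if best[0] < min_score:
        return []
    second = None
    for c in cands[1:]:
        if _distinct_locus(best, c, m):
            second = c
            break
    out = [
        LocalAlignment(
            read_id=read_id,
            target_name=best[1],
            target_start=best[3],
            target_end=best[4],
            query_start=best[5],
            query_end=best[6],
            strand=best[2],
            score=best[0],
            second_best_score=second[0] if second else None,
            read_len=m,
        )
    ]
    if second is not None and second[0] >= min_score:
        out.append(
            LocalAlignment(
                read_id=read_id,
                target_name=second[1],
                target_start=second[3],
                target_end=second[4],
                query_start=second[5],
                query_end=second[6],
                strand=second[2],
                score=second[0],
                read_len=m,
            )
        )
    return out


def _distinct_locus(a, b, read_len: int) -> bool:
    if a[1] != b[1] or a[2] != b[2]:
        return True
    return abs(a[3] - b[3]) > read_len


def _runner_up_alignment(q, t, H, bj, m, sc, name, strand):
    """Locate the best alignment ending > read_len columns away from bj."""
    n = H.shape[1] - 1
    mask_lo = max(0, bj - m)
    mask_hi = min(n, bj + m)
    Hm = H.copy()
    Hm[:, mask_lo : mask_hi + 1] = 0
    best = int(Hm.max())
    if best <= 0:
        return None
    flat = int(np.argmax(Hm))
    bi2, bj2 = divmod(flat, Hm.shape[1])
    # recover the start with the reversed-prefix trick
    qr = q[:bi2][::-1].copy()
    tr = t[:bj2][::-1].copy()
    Hr = local_dp_matrix(qr, tr, *sc)
    flat_r = int(np.argmax(Hr))
    ri, rj = divmod(flat_r, Hr.shape[1])
    qs, qe, ts, te = bi2 - ri, bi2, bj2 - rj, bj2
    if qe <= qs or te <= ts:
        return None
    oqs, oqe = _query_coords(qs, qe, strand, m)
    return (best, name, strand, ts, te, oqs, oqe)


def align_reads(
    reads: dict[str, str] | list[tuple[str, str]],
    targets: TargetIndex | dict[str, str],
    scoring: Scoring = DEFAULT_SCORING,
    *,
    min_score: int | None = None,
    min_score_frac: float = 0.6,
    method: str = "auto",
    target_db: str = "",
) -> AlignmentSet:
    """Align many reads; convenience wrapper returning an AlignmentSet."""
    if not isinstance(targets, TargetIndex):
        targets = TargetIndex(targets)
    items = reads.items() if isinstance(reads, dict) else reads
    aset = AlignmentSet(target_db=target_db)
    for rid, seq in items:
        for aln in local_align(
            seq,
            targets,
            scoring,
            min_score=min_score,
            min_score_frac=min_score_frac,
            method=method,
            read_id=rid,
        ):
            aset.add(aln)
    return aset


# ---------------------------------------------------------------------------
# Unique-best filter


def filter_unique_best(alns: AlignmentSet) -> AlignmentSet:
    """Keep only reads whose best score strictly beats the runner-up.

    A tie (equal best and second-best score) is not a unique mapping and
    the read is dropped.  The retained entry is the single best
    alignment.  Idempotent.
    """
    out = AlignmentSet(target_db=alns.target_db)
    for read_id, read_alns in alns:
        best = max(read_alns, key=lambda a: a.score)
        second = best.second_best_score
        for a in read_alns:
            if a is not best and a.score > (second if second is not None else -1):
                second = a.score
        if second is None or best.score > second:
            out.add(replace(best, second_best_score=second))
    return out


# ---------------------------------------------------------------------------
# SAM interoperability


def _cigar(aln: LocalAlignment) -> list[tuple[int, int]]:
    """Soft-clipped CIGAR reconciling query and target span lengths.

    The alignment path is not stored, so gaps are represented as a single
    trailing I or D block; spans round-trip exactly.
    """
    if aln.strand == "+":
        left, right = aln.query_start, aln.read_len - aln.query_end
    else:  # stored sequence is the reverse complement
        left = aln.read_len - aln.query_end
        right = aln.query_start
    q_span = aln.query_end - aln.query_start
    t_span = aln.target_end - aln.target_start
    ops: list[tuple[int, int]] = []
    if left:
        ops.append((4, left))  # S
    core = min(q_span, t_span)
    ops.append((0, core))  # M
    if q_span > t_span:
        ops.append((1, q_span - t_span))  # I
    elif t_span > q_span:
        ops.append((2, t_span - q_span))  # D
    if right:
        ops.append((4, right))
    return ops


def export_sam(
    alns: AlignmentSet, target_lengths: dict[str, int], path: str | Path
) -> None:
    header = pysam.AlignmentHeader.from_references(
        list(target_lengths), list(target_lengths.values())
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for read_id, read_alns in alns:
            ordered = sorted(read_alns, key=lambda a: -a.score)
            for rank, aln in enumerate(ordered):
                rec = pysam.AlignedSegment(header)
                rec.query_name = read_id
                rec.flag = (16 if aln.strand == "-" else 0) | (256 if rank else 0)
                rec.reference_name = aln.target_name
                rec.reference_start = aln.target_start
                rec.mapping_quality = 60 if rank == 0 else 0
                rec.cigartuples = _cigar(aln)
                rec.query_sequence = None
                tags = [("AS", aln.score)]
                if aln.second_best_score is not None:
                    tags.append(("XS", aln.second_best_score))
                tags.append(("ZL", aln.read_len))
                rec.set_tags(tags)
                fh.write(rec)


def ingest_sam(
    path: str | Path, target_lengths: dict[str, int] | None = None
) -> AlignmentSet:
    """Fold SAM records into an AlignmentSet.

    Primary and secondary records become LocalAlignments; the XS tag (or
    the best secondary score) supplies ``second_best_score``.  Unmapped
    records are skipped and counted.
    """
    aset = AlignmentSet(target_db=str(path))
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        known = set(target_lengths) if target_lengths is not None else None
        for rec in fh:
            if rec.is_unmapped:
                aset.n_unmapped += 1
                continue
            tname = rec.reference_name
            if known is not None and tname not in known:
                raise DataError(f"unknown target {tname!r} in {path}")
            read_len = rec.infer_read_length()
            if rec.has_tag("ZL"):
                read_len = int(rec.get_tag("ZL"))
            qs = rec.query_alignment_start
            qe = rec.query_alignment_end
            if rec.is_reverse:
                qs, qe = read_len - qe, read_len - qs
            aset.add(
                LocalAlignment(
                    read_id=rec.query_name,
                    target_name=tname,
                    target_start=rec.reference_start,
                    target_end=rec.reference_end,
                    query_start=qs,
                    query_end=qe,
                    strand="-" if rec.is_reverse else "+",
                    score=int(rec.get_tag("AS")) if rec.has_tag("AS") else 0,
                    second_best_score=(
                        int(rec.get_tag("XS")) if rec.has_tag("XS") else None
                    ),
                    read_len=read_len,
                )
            )
    return aset
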