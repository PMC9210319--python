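"""TE family definitions and the reference genome.

A :class:`TEDatabase` holds the consensus sequence of each LTR
retrotransposon family used for enrichment, with the two terminal repeats
(LTRs) annotated so that downstream code can tell which end of an element
an R2 read anchors in.  A :class:`ReferenceGenome` is a plain map of
contig name to sequence; :func:`mask_reference` replaces every exact
occurrence of TE consensus sequence (>= ``min_match_len`` bp, either
strand) with N so that reads drawn from TE interiors cannot acquire a
unique genomic mapping.

On-disk layout: consensi as standard FASTA (header = family name) plus a
TOML sidecar with per-family LTR coordinates (1-based inclusive) and the
active flag.  Real-scale users who masked their genome with an external
tool can load the pre-masked FASTA directly.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, DataError
from .seqs import check_alphabet, encode, kmer_codes, revcomp

__all__ = [
    "TEFamily",
    "TEDatabase",
    "ReferenceGenome",
    "load_te_database",
    "write_te_database",
    "load_genome",
    "write_genome",
    "mask_reference",
]


@dataclass(frozen=True)
class TEFamily:
    """One LTR retrotransposon family.

    ``ltr5``/``ltr3`` are the 5' and 3' long terminal repeats; they must be
    a prefix/suffix of ``consensus`` (ambiguity codes resolved to N may
    introduce a bounded mismatch fraction).  ``active`` families define
    demultiplexing bins; inactive families (e.g. one whose primers failed)
    are retained for masking but excluded from analysis.
    """

    name: str
    consensus: str
    ltr5: str
    ltr3: str
    active: bool = True

    def __post_init__(self) -> None:
        if not self.consensus:
            raise DataError(f"family {self.name!r}: empty consensus")
        check_alphabet(self.consensus, f"family {self.name!r} consensus")
        for label, ltr in (("ltr5", self.ltr5), ("ltr3", self.ltr3)):
            if not ltr:
                raise DataError(f"family {self.name!r}: empty {label}")
        if not _matches_with_n(self.consensus[: len(self.ltr5)], self.ltr5):
            raise DataError(
                f"family {self.name!r}: ltr5 is not a prefix of the consensus"
            )
        if not _matches_with_n(self.consensus[-len(self.ltr3) :], self.ltr3):
            raise DataError(
                f"family {self.name!r}: ltr3 is not a suffix of the consensus"
            )

    def __len__(self) -> int:
        return len(self.consensus)


def _matches_with_n(a: str, b: str, max_mismatch_frac: float = 0.0) -> bool:
    """Equality where N matches anything, allowing a mismatch fraction."""
    if len(a) != len(b):
        return False
    mism = sum(
        1 for x, y in zip(a, b) if x != y and x != "N" and y != "N"
    )
    return mism <= max_mismatch_frac * len(a)


@dataclass
class TEDatabase:
    families: list[TEFamily]
    version: str = "1"

    def __post_init__(self) -> None:
        names = [f.name for f in self.families]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise DataError(f"duplicate family names: {sorted(dupes)}")
        if not self.families:
            raise DataError("no families")
        if not any(f.active for f in self.families):
            raise DataError("no active families")

    @property
    def active(self) -> list[TEFamily]:
        return [f for f in self.families if f.active]

    def __getitem__(self, name: str) -> TEFamily:
        for f in self.families:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.families)


@dataclass
class ReferenceGenome:
    contigs: dict[str, str]
    masked: bool = False

    def __post_init__(self) -> None:
        if not self.contigs:
            raise DataError("reference genome has no contigs")
        for name, seq in self.contigs.items():
            check_alphabet(seq, f"contig {name!r}")

    def __len__(self) -> int:
        return sum(len(s) for s in self.contigs.values())


# ---------------------------------------------------------------------------
# IO


def load_te_database(fasta_path: str | Path, config_path: str | Path) -> TEDatabase:
    """Load TE families from a FASTA + TOML sidecar.

    The sidecar maps family name to ``ltr5_end``/``ltr3_start`` (1-based
    inclusive coordinates on the consensus) and an optional ``active``
    flag.
    """
    fasta_path = Path(fasta_path)
    config_path = Path(config_path)
    with open(config_path, "rb") as fh:
        cfg = tomllib.load(fh)
    fam_cfg = cfg.get("families", {})
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise DataError(f"no families in {fasta_path}")
    families = []
    seen: set[str] = set()
    for rec in records:
        name = rec.id
        if name in seen:
            raise DataError(f"duplicate family names: ['{name}']")
        seen.add(name)
        if name not in fam_cfg:
            raise ConfigError(f"family {name!r}: no LTR annotation in {config_path}")
        entry = fam_cfg[name]
        seq = str(rec.seq).upper()
        try:
            ltr5_end = int(entry["ltr5_end"])
            ltr3_start = int(entry["ltr3_start"])
        except KeyError as exc:
            raise ConfigError(f"family {name!r}: missing LTR key {exc}") from exc
        if not (0 < ltr5_end < ltr3_start <= len(seq)):
            raise ConfigError(
                f"family {name!r}: LTR coordinates out of range for "
                f"consensus of length {len(seq)}"
            )
        families.append(
            TEFamily(
                name=name,
                consensus=seq,
                ltr5=seq[:ltr5_end],
                ltr3=seq[ltr3_start - 1 :],
                active=bool(entry.get("active", True)),
            )
        )
    return TEDatabase(families=families, version=str(cfg.get("version", "1")))


def write_te_database(
    db: TEDatabase, fasta_path: str | Path, config_path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(f.consensus), id=f.name, description="") for f in db.families
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    lines = [f'version = "{db.version}"', ""]
    for f in db.families:
        lines += [
            f"[families.{_toml_key(f.name)}]",
            f"ltr5_end = {len(f.ltr5)}",
            f"ltr3_start = {len(f.consensus) - len(f.ltr3) + 1}",
            f"active = {'true' if f.active else 'false'}",
            "",
        ]
    Path(config_path).write_text("\n".join(lines))


def _toml_key(name: str) -> str:
    return name if name.isidentifier() else f'"{name}"'


def load_genome(path: str | Path, masked: bool = False) -> ReferenceGenome:
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    return ReferenceGenome(contigs=contigs, masked=masked)


def write_genome(genome: ReferenceGenome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Masking

_SEED_K = 24


def mask_reference(
    genome: ReferenceGenome,
    db: TEDatabase,
    min_match_len: int = 100,
) -> tuple[ReferenceGenome, list[tuple[str, int, int, str]]]:
    """N-mask every exact TE-consensus match of >= ``min_match_len`` bp.

    Both strands are searched.  Returns the masked genome plus a report of
    masked intervals as (contig, start, end, family) in 0-based half-open
    coordinates.  Exact matching is sufficient for synthetic genomes where
    planted copies equal the consensus; externally pre-masked FASTAs are
    the route for diverged real-genome copies.
    """
    if min_match_len < 20:
        raise ConfigError("min_match_len < 20 would mask randomly matching k-mers")
    k = min(_SEED_K, min_match_len)

    # seed table: k-mer code -> list of (family, strand-oriented consensus, pos)
    seeds: dict[int, list[tuple[str, str, int]]] = {}
    for fam in db.families:
        for oriented in (fam.consensus, revcomp(fam.consensus)):
            codes, valid = kmer_codes(encode(oriented), k)
            for pos in np.nonzero(valid)[0]:
                seeds.setdefault(int(codes[pos]), []).append((fam.name, oriented, int(pos)))

    report: list[tuple[str, int, int, str]] = []
    new_contigs: dict[str, str] = {}
    for cname, cseq in genome.contigs.items():
        codes, valid = kmer_codes(encode(cseq), k)
        intervals: list[tuple[int, int, str]] = []
        covered_until = -1
        for gpos in np.nonzero(valid)[0]:
            gpos = int(gpos)
            if gpos + k <= covered_until:
                continue
            hits = seeds.get(int(codes[gpos]))
            if not hits:
                continue
            for fam_name, oriented, cpos in hits:
                s, e = _extend_exact(cseq, gpos, oriented, cpos, k)
                if e - s >= min_match_len:
                    intervals.append((s, e, fam_name))
                    covered_until = max(covered_until, e)
        merged = _merge_intervals(intervals)
        seq = cseq
        for s, e, fam_name in merged:
            seq = seq[:s] + "N" * (e - s) + seq[e:]
            report.append((cname, s, e, fam_name))
        new_contigs[cname] = seq
    report.sort()
    return ReferenceGenome(contigs=new_contigs, masked=True), report


def _extend_exact(
    genome_seq: str, gpos: int, cons: str, cpos: int, k: int
) -> tuple[int, int]:
    """Maximally extend an exact k-mer match in both directions."""
    s_g, s_c = gpos, cpos
    while s_g > 0 and s_c > 0 and genome_seq[s_g - 1] == cons[s_c - 1] != "N":
        s_g -= 1
        s_c -= 1
    e_g, e_c = gpos + k, cpos + k
    while (
        e_g < len(genome_seq)
        and e_c < len(cons)
        and genome_seq[e_g] == cons[e_c] != "N"
    ):
        e_g += 1
        e_c += 1
    return s_g, e_g


def _merge_intervals(
    intervals: list[tuple[int, int, str]]
) -> list[tuple[int, int, str]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [intervals[0]]
    for s, e, fam in intervals[1:]:
        ps, pe, pfam = out[-1]
        if s <= pe:
            out[-1] = (ps, max(pe, e), pfam)
        else:
            out.append((s, e, fam))
    return out


def write_mask_report(report: list[tuple[str, int, int, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tfamily\n")
        for row in report:
            fh.write("\t".join(map(str, row)) + "\n")
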