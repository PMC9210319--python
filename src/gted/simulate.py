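"""Synthetic cell lines and protocol-faithful paired-end reads.

The generator emulates the geometry of a targeted TE-enrichment library:
every sequenced fragment spans one terminus of one planted LTR
retrotransposon insertion.  Read 2 anchors inside the LTR adjacent to
that terminus (it identifies the family and the element end); Read 1
starts in the flanking genomic DNA at a fragmentation-randomised offset
and reads toward the element, so a configurable fraction of R1 reads
straddle the genome→TE breakpoint and carry the junction signal while
the rest land wholly inside the flank and only contribute to window
counts.  A small off-target background (reads drawn anywhere in the
genome) exercises the unassigned path of demultiplexing.

Insertions create a target-site duplication (TSD), so the two genomic
breakpoints of one insertion differ by ``tsd_len``: the left junction
sits at the insertion position ``p`` and the right junction at
``p - tsd_len``.

Related sublines are modelled by copying a fraction of another line's
insertion set; replicates of one line differ only by read seed and depth
jitter.  Everything is deterministic given the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .refdb import ReferenceGenome, TEDatabase, TEFamily, write_genome, write_te_database
from .seqs import random_dna, revcomp

__all__ = [
    "PlantedInsertion",
    "CellLineGenotype",
    "ExpectedJunction",
    "SimTruth",
    "ReadPair",
    "LineSpec",
    "Cohort",
    "synthetic_te_database",
    "build_reference",
    "plant_insertions",
    "expected_junctions",
    "generate_read_pairs",
    "generate_background_pairs",
    "simulate_cohort",
    "write_fixture",
]

FAMILY_NAMES = ["297", "copia", "mdg1", "roo", "1731"]
INACTIVE_FAMILY = "mdg3"

DEFAULT_READ_LEN = 75
DEFAULT_FLANK = 300


@dataclass(frozen=True)
class PlantedInsertion:
    contig: str
    position: int  # 0-based; element inserted before this base
    family: str
    orientation: str  # '+' or '-'
    tsd_len: int = 4


@dataclass
class CellLineGenotype:
    line_name: str
    insertions: list[PlantedInsertion]
    base_genome_seed: int = 0

    def __post_init__(self) -> None:
        keys = [(i.contig, i.position, i.family) for i in self.insertions]
        if len(keys) != len(set(keys)):
            raise DataError(f"line {self.line_name!r}: duplicate insertions")


@dataclass(frozen=True)
class ExpectedJunction:
    """One of the two genomic breakpoints of a planted insertion.

    ``side`` names the element terminus ('5p'/'3p'); ``te_right`` is True
    when the element lies genomically rightward of the breakpoint.
    """

    contig: str
    breakpoint: int
    side: str
    family: str
    te_right: bool

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.breakpoint, self.side, self.family)


@dataclass
class SimTruth:
    genotypes: dict[str, CellLineGenotype]
    junctions: dict[str, list[ExpectedJunction]]  # per line

    def keys_for(self, line: str) -> set[tuple[str, int, str, str]]:
        return {j.key for j in self.junctions[line]}


@dataclass
class ReadPair:
    read_id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str
    sample_id: str

    def __post_init__(self) -> None:
        if not self.r1_seq or not self.r2_seq:
            raise DataError("empty read in pair")


# ---------------------------------------------------------------------------
# Synthetic TE database


def _synthetic_family(name: str, rng: np.random.Generator, active: bool) -> TEFamily:
    """Random consensus with LTR termini.

    Real LTR retrotransposons carry identical terminal repeats; here the
    3' LTR copy carries one substitution every 25 bp so that the LTR of
    origin of an R2 read is computable from its best alignment — a
    synthetic-construction convenience, documented as such.
    """
    ltr_len, interior_len = 250, 1000
    ltr5 = random_dna(ltr_len, rng)
    interior = random_dna(interior_len, rng)
    ltr3_arr = list(ltr5)
    bases = "ACGT"
    for pos in range(12, ltr_len, 25):
        old = ltr3_arr[pos]
        ltr3_arr[pos] = bases[(bases.index(old) + 1 + int(rng.integers(0, 3))) % 4]
    ltr3 = "".join(ltr3_arr)
    consensus = ltr5 + interior + ltr3
    return TEFamily(
        name=name, consensus=consensus, ltr5=ltr5, ltr3=ltr3, active=active
    )


def synthetic_te_database(seed: int = 7, include_inactive: bool = True) -> TEDatabase:
    """The five diagnostic families (plus one disabled) as synthetic consensi."""
    ss = np.random.SeedSequence(seed)
    names = FAMILY_NAMES + ([INACTIVE_FAMILY] if include_inactive else [])
    children = ss.spawn(len(names))
    families = [
        _synthetic_family(name, np.random.default_rng(child), name != INACTIVE_FAMILY)
        for name, child in zip(names, children)
    ]
    return TEDatabase(families=families, version=f"synthetic-{seed}")


# ---------------------------------------------------------------------------
# Reference and genotypes


def build_reference(n_contigs: int, contig_len: int, seed: int) -> ReferenceGenome:
    if n_contigs < 1:
        raise ConfigError("n_contigs must be >= 1")
    if contig_len < 2000:
        raise ConfigError("contig_len must be >= 2000")
    rng = np.random.default_rng(seed)
    contigs = {
        f"contig{i + 1}": random_dna(contig_len, rng) for i in range(n_contigs)
    }
    return ReferenceGenome(contigs=contigs, masked=False)


def plant_insertions(
    genome: ReferenceGenome,
    db: TEDatabase,
    n_per_family: int,
    *,
    shared_with: CellLineGenotype | None = None,
    share_frac: float = 0.0,
    seed: int = 0,
    tsd_len: int = 4,
    min_spacing: int = 2 * DEFAULT_FLANK,
    margin: int = 400,
    exclude: dict[str, list[int]] | None = None,
    line_name: str = "line",
) -> tuple[CellLineGenotype, ReferenceGenome]:
    """Draw a genotype and return it with the corresponding line genome.

    Sites are uniform over non-N positions at least ``margin`` from the
    contig ends and ``min_spacing`` from every other site (including
    ``exclude``, e.g. other lines' sites, so flank windows of distinct
    insertions never overlap across a cohort).  With ``shared_with``,
    ``floor(share_frac * n_per_family)`` sites per family are copied from
    that genotype, modelling related sublines.
    """
    if not (0 <= tsd_len <= 10):
        raise ConfigError("tsd_len must be in 0..10")
    rng = np.random.default_rng(seed)
    occupied: dict[str, list[int]] = {c: [] for c in genome.contigs}
    if exclude:
        for c, positions in exclude.items():
            occupied.setdefault(c, []).extend(positions)

    insertions: list[PlantedInsertion] = []
    n_shared = int(np.floor(share_frac * n_per_family)) if shared_with else 0
    for fam in db.active:
        if shared_with is not None and n_shared:
            donor = sorted(
                (i for i in shared_with.insertions if i.family == fam.name),
                key=lambda i: (i.contig, i.position),
            )[:n_shared]
            insertions.extend(donor)
            for ins in donor:
                occupied[ins.contig].append(ins.position)
        for _ in range(n_per_family - (n_shared if shared_with else 0)):
            pos, contig = _draw_site(genome, rng, occupied, margin, min_spacing)
            occupied[contig].append(pos)
            insertions.append(
                PlantedInsertion(
                    contig=contig,
                    position=pos,
                    family=fam.name,
                    orientation="+" if rng.integers(0, 2) == 0 else "-",
                    tsd_len=tsd_len,
                )
            )
    genotype = CellLineGenotype(line_name=line_name, insertions=insertions)
    return genotype, _apply_insertions(genome, genotype, db)


def _draw_site(
    genome: ReferenceGenome,
    rng: np.random.Generator,
    occupied: dict[str, list[int]],
    margin: int,
    min_spacing: int,
    max_attempts: int = 2000,
) -> tuple[int, str]:
    names = list(genome.contigs)
    lengths = np.array([len(genome.contigs[n]) for n in names], dtype=float)
    weights = lengths / lengths.sum()
    for _ in range(max_attempts):
        contig = names[int(rng.choice(len(names), p=weights))]
        seq = genome.contigs[contig]
        if len(seq) <= 2 * margin:
            continue
        pos = int(rng.integers(margin, len(seq) - margin))
        if seq[pos] == "N" or seq[pos - 1] == "N":
            continue
        if any(abs(pos - q) < min_spacing for q in occupied[contig]):
            continue
        return pos, contig
    raise DataError("not enough eligible positions for requested insertions")


def _apply_insertions(
    genome: ReferenceGenome, genotype: CellLineGenotype, db: TEDatabase
) -> ReferenceGenome:
    contigs = dict(genome.contigs)
    by_contig: dict[str, list[PlantedInsertion]] = {}
    for ins in genotype.insertions:
        by_contig.setdefault(ins.contig, []).append(ins)
    for cname, inss in by_contig.items():
        ref = genome.contigs[cname]
        pieces: list[str] = []
        prev = 0
        for ins in sorted(inss, key=lambda i: i.position):
            te = db[ins.family].consensus
            if ins.orientation == "-":
                te = revcomp(te)
            tsd = ref[max(0, ins.position - ins.tsd_len) : ins.position]
            pieces += [ref[prev : ins.position], te, tsd]
            prev = ins.position
        pieces.append(ref[prev:])
        contigs[cname] = "".join(pieces)
    return ReferenceGenome(contigs=contigs, masked=False)


def expected_junctions(genotype: CellLineGenotype) -> list[ExpectedJunction]:
    """The two breakpoints each insertion contributes (TSD-corrected)."""
    out: list[ExpectedJunction] = []
    for ins in genotype.insertions:
        left_side = "5p" if ins.orientation == "+" else "3p"
        right_side = "3p" if ins.orientation == "+" else "5p"
        out.append(
            ExpectedJunction(ins.contig, ins.position, left_side, ins.family, True)
        )
        out.append(
            ExpectedJunction(
                ins.contig, ins.position - ins.tsd_len, right_side, ins.family, False
            )
        )
    return out


# ---------------------------------------------------------------------------
# Reads


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    bases = "ACGT"
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = bases[(bases.index(arr[i]) + 1 + int(rng.integers(0, 3))) % 4]
    return "".join(arr)


def _r2_for_side(fam: TEFamily, side: str, read_len: int) -> str:
    """R2 anchored in the LTR adjacent to the element terminus.

    The nested primer sits ~``read_len`` inside the LTR and reads outward
    toward the terminus, so the read covers the terminal ``read_len``
    bases of the consensus on the appropriate strand.
    """
    if side == "5p":
        return revcomp(fam.consensus[:read_len])
    return fam.consensus[-read_len:]


def generate_read_pairs(
    reference: ReferenceGenome,
    genotype: CellLineGenotype,
    db: TEDatabase,
    *,
    pairs_per_junction: int = 20,
    read_len: int = DEFAULT_READ_LEN,
    frag_len_mean: int = 300,
    frag_len_sd: int = 60,
    straddle_frac: float = 0.8,
    error_rate: float = 0.0,
    background_frac: float = 0.05,
    seed: int = 0,
    sample_id: str = "sample",
) -> list[ReadPair]:
    """Emit ``pairs_per_junction`` pairs for each junction of each insertion.

    ``round(straddle_frac * pairs_per_junction)`` R1 reads per junction
    straddle the breakpoint, with genomic offsets sampled without
    replacement from ``read_len/3 .. 2*read_len/3`` (distinct start
    positions by construction); the rest start ``read_len .. 300`` bp
    into the flank.  Fragment length only bounds the geometry: the
    quantitative enrichment efficiency of the nested PCR is not
    modelled.
    """
    if read_len > frag_len_mean:
        raise ConfigError("read_len exceeds mean fragment length")
    if pairs_per_junction < 0:
        raise ConfigError("pairs_per_junction must be >= 0")
    rng = np.random.default_rng(seed)
    qual = "?"  # Q30-equivalent, constant: trimming is out of scope
    g_lo, g_hi = max(25, read_len // 3), 2 * read_len // 3
    pairs: list[ReadPair] = []
    n_straddle = int(round(straddle_frac * pairs_per_junction))

    for ins in genotype.insertions:
        fam = db[ins.family]
        te_full = fam.consensus if ins.orientation == "+" else revcomp(fam.consensus)
        ref = reference.contigs[ins.contig]
        p, t = ins.position, ins.tsd_len
        for junc in expected_junctions(
            CellLineGenotype(genotype.line_name, [ins])
        ):
            if pairs_per_junction == 0:
                continue
            offsets = _draw_offsets(
                rng, n_straddle, pairs_per_junction, g_lo, g_hi, read_len
            )
            for i, (g, straddles) in enumerate(offsets):
                if junc.te_right:  # left junction: flank left of breakpoint
                    if straddles:
                        r1 = ref[p - g : p] + te_full[: read_len - g]
                    else:
                        r1 = ref[p - g : p - g + read_len]
                else:  # right junction: flank right of breakpoint p - t
                    b = p - t
                    if straddles:
                        core = te_full[len(te_full) - (read_len - g) :] + ref[b : b + g]
                        r1 = revcomp(core)
                    else:
                        r1 = revcomp(ref[b + g - read_len : b + g])
                r2 = _r2_for_side(fam, junc.side, read_len)
                rid = (
                    f"{sample_id}|{junc.contig}:{junc.breakpoint}:{junc.side}"
                    f":{junc.family}|{i}"
                )
                pairs.append(
                    ReadPair(
                        read_id=rid,
                        r1_seq=_mutate(r1, error_rate, rng),
                        r1_qual=qual * read_len,
                        r2_seq=_mutate(r2, error_rate, rng),
                        r2_qual=qual * read_len,
                        sample_id=sample_id,
                    )
                )
    n_bg = int(round(background_frac * len(pairs)))
    pairs.extend(
        generate_background_pairs(
            reference,
            n_bg,
            read_len=read_len,
            seed=int(rng.integers(0, 2**31 - 1)),
            sample_id=sample_id,
            error_rate=error_rate,
        )
    )
    return pairs


def _draw_offsets(
    rng: np.random.Generator,
    n_straddle: int,
    total: int,
    g_lo: int,
    g_hi: int,
    read_len: int,
    flank_cap: int = DEFAULT_FLANK,
) -> list[tuple[int, bool]]:
    n_straddle = min(n_straddle, total)
    choices = np.arange(g_lo, g_hi + 1)
    if choices.size >= n_straddle:
        gs = rng.choice(choices, size=n_straddle, replace=False)
    else:
        gs = rng.choice(choices, size=n_straddle, replace=True)
    out = [(int(g), True) for g in gs]
    n_window = total - n_straddle
    if n_window > 0:
        ws = rng.integers(read_len, flank_cap + 1, size=n_window)
        out += [(int(w), False) for w in ws]
    return out


def generate_background_pairs(
    reference: ReferenceGenome,
    n: int,
    *,
    read_len: int = DEFAULT_READ_LEN,
    seed: int = 0,
    sample_id: str = "sample",
    error_rate: float = 0.0,
) -> list[ReadPair]:
    """Off-target pairs: both mates random genomic sequence (no TE)."""
    rng = np.random.default_rng(seed)
    names = list(reference.contigs)
    qual = "?" * read_len
    out: list[ReadPair] = []
    for i in range(n):
        r = []
        for _ in range(2):
            cname = names[int(rng.integers(0, len(names)))]
            seq = reference.contigs[cname]
            pos = int(rng.integers(0, len(seq) - read_len))
            r.append(seq[pos : pos + read_len])
        out.append(
            ReadPair(
                read_id=f"{sample_id}|bg|{i}",
                r1_seq=_mutate(r[0], error_rate, rng),
                r1_qual=qual,
                r2_seq=_mutate(r[1], error_rate, rng),
                r2_qual=qual,
                sample_id=sample_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cohorts and fixtures


@dataclass
class LineSpec:
    """One synthetic cell line: sizing and optional subline relation."""

    name: str
    n_per_family: int = 10
    replicates: int = 3
    share_with: str | None = None
    share_frac: float = 0.0
    background_pairs: int | None = None  # for n_per_family == 0 ("foreign")


@dataclass
class Cohort:
    reference: ReferenceGenome
    db: TEDatabase
    truth: SimTruth
    samples: dict[str, list[ReadPair]]
    manifest: pd.DataFrame  # sample_id, line, replicate, n_pairs
    params: dict = field(default_factory=dict)


def simulate_cohort(
    reference: ReferenceGenome,
    db: TEDatabase,
    lines: list[LineSpec],
    *,
    pairs_per_junction: int = 20,
    read_len: int = DEFAULT_READ_LEN,
    error_rate: float = 0.0,
    background_frac: float = 0.05,
    depth_jitter: float = 0.0,
    tsd_len: int = 4,
    seed: int = 0,
) -> Cohort:
    """Simulate a multi-line cohort with replicate samples.

    Replicates of a line share the genotype and differ only by read seed
    and (optionally) depth jitter.  Insertion sites are spaced across the
    whole cohort so flank windows of distinct junctions never collide.
    """
    for spec in lines:
        if spec.replicates < 1:
            raise ConfigError(f"line {spec.name!r}: replicates must be >= 1")
    ss = np.random.SeedSequence(seed)
    geno_seeds, read_seed_root = ss.spawn(2)
    geno_children = geno_seeds.spawn(len(lines))
    read_rng = np.random.default_rng(read_seed_root)

    genotypes: dict[str, CellLineGenotype] = {}
    occupied: dict[str, list[int]] = {c: [] for c in reference.contigs}
    for spec, child in zip(lines, geno_children):
        shared = genotypes.get(spec.share_with) if spec.share_with else None
        if spec.share_with and shared is None:
            raise ConfigError(
                f"line {spec.name!r} shares with unknown line {spec.share_with!r}"
            )
        genotype, _ = plant_insertions(
            reference,
            db,
            spec.n_per_family,
            shared_with=shared,
            share_frac=spec.share_frac,
            seed=int(np.random.default_rng(child).integers(0, 2**31 - 1)),
            tsd_len=tsd_len,
            exclude={c: list(v) for c, v in occupied.items()},
            line_name=spec.name,
        )
        genotypes[spec.name] = genotype
        for ins in genotype.insertions:
            if ins.position not in occupied[ins.contig]:
                occupied[ins.contig].append(ins.position)

    samples: dict[str, list[ReadPair]] = {}
    rows = []
    for spec in lines:
        genotype = genotypes[spec.name]
        for rep in range(1, spec.replicates + 1):
            sid = f"{spec.name}_{rep}"
            sample_seed = int(read_rng.integers(0, 2**31 - 1))
            if depth_jitter > 0:
                scale = 1.0 + float(read_rng.uniform(-depth_jitter, depth_jitter))
            else:
                scale = 1.0
            if spec.n_per_family == 0:
                n_bg = spec.background_pairs or 500
                pairs = generate_background_pairs(
                    reference,
                    int(round(n_bg * scale)),
                    read_len=read_len,
                    seed=sample_seed,
                    sample_id=sid,
                    error_rate=error_rate,
                )
            else:
                ppj = max(1, int(round(pairs_per_junction * scale)))
                pairs = generate_read_pairs(
                    reference,
                    genotype,
                    db,
                    pairs_per_junction=ppj,
                    read_len=read_len,
                    error_rate=error_rate,
                    background_frac=background_frac,
                    seed=sample_seed,
                    sample_id=sid,
                )
            samples[sid] = pairs
            rows.append(
                {
                    "sample_id": sid,
                    "line": spec.name,
                    "replicate": rep,
                    "n_pairs": len(pairs),
                }
            )

    truth = SimTruth(
        genotypes=genotypes,
        junctions={n: expected_junctions(g) for n, g in genotypes.items()},
    )
    params = {
        "pairs_per_junction": pairs_per_junction,
        "read_len": read_len,
        "error_rate": error_rate,
        "background_frac": background_frac,
        "depth_jitter": depth_jitter,
        "tsd_len": tsd_len,
        "seed": seed,
        "lines": [vars(s) for s in lines],
    }
    return Cohort(
        reference=reference,
        db=db,
        truth=truth,
        samples=samples,
        manifest=pd.DataFrame(rows),
        params=params,
    )


def _write_fastq(pairs: list[ReadPair], r1_path: Path, r2_path: Path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}\n{p.r1_seq}\n+\n{p.r1_qual}\n")
            f2.write(f"@{p.read_id}\n{p.r2_seq}\n+\n{p.r2_qual}\n")


def write_fixture(cohort: Cohort, outdir: str | Path, flank: int = DEFAULT_FLANK) -> dict:
    """Write a cohort to disk: FASTQ pairs, truth BEDs, manifest, params.

    Also writes the reference FASTA and the TE database (FASTA + TOML) so
    the directory is a complete, self-describing pipeline input.  Output
    is byte-identical for identical cohorts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for sid in cohort.manifest["sample_id"]:
        r1 = outdir / f"{sid}_R1.fastq"
        r2 = outdir / f"{sid}_R2.fastq"
        _write_fastq(cohort.samples[sid], r1, r2)
        paths[sid] = f"{r1.name},{r2.name}"
    for line, juncs in cohort.truth.junctions.items():
        with open(outdir / f"truth_{line}.bed", "w") as fh:
            for j in sorted(juncs, key=lambda j: (j.contig, j.breakpoint)):
                if j.te_right:
                    ws, we = max(0, j.breakpoint - flank), j.breakpoint
                else:
                    ws, we = j.breakpoint, j.breakpoint + flank
                fh.write(
                    f"{j.contig}\t{ws}\t{we}\t{j.family}:{j.side}\t.\t"
                    f"{'+' if j.te_right else '-'}\n"
                )
    manifest = cohort.manifest.copy()
    manifest["fastq"] = [paths[s] for s in manifest["sample_id"]]
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    write_genome(cohort.reference, outdir / "reference.fasta")
    write_te_database(cohort.db, outdir / "te_families.fasta", outdir / "te_families.toml")
    with open(outdir / "params.json", "w") as fh:
        json.dump(cohort.params, fh, indent=2, sort_keys=True)
    return paths
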