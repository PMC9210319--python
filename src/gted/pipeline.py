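"""End-to-end orchestration: reads in, signatures and calls out.

One :func:`run_pipeline` call executes subsample -> demultiplex ->
align -> junction call -> flank windows -> count -> normalize ->
binarize -> cluster (-> identify when a signature database is given)
and writes every intermediate plus a provenance record.  Samples with
zero mapped TE-associated reads (e.g. a non-target species) cannot be
depth-normalized; they are carried as all-absent profiles and always
identify as NO_ID.

Re-running with an identical configuration produces byte-identical
outputs; each text output names the sha256 checksum of the
configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .align import export_sam
from .classify import (
    SignatureDB,
    build_signature_db,
    cluster_profiles,
    export_heatmap,
    identify,
    to_newick,
    write_identification_tsv,
)
from .errors import ConfigError, DataError
from .junctions import JunctionCallResult, call_junctions, junctions_to_bed, junctions_to_tsv
from .profile import (
    BinaryProfileMatrix,
    binarize,
    count_window_reads,
    normalize,
    subsample_pairs,
    write_matrix_tsv,
)
from .refdb import load_genome, load_te_database, mask_reference, write_genome, write_mask_report
from .simulate import ReadPair

logger = logging.getLogger("gted")

__all__ = ["RunConfig", "run_pipeline", "load_read_pairs", "read_manifest"]


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    input_dir: str
    output_dir: str
    te_fasta: str = "te_families.fasta"
    te_config: str = "te_families.toml"
    genome_fasta: str = "reference.fasta"
    manifest: str = "manifest.tsv"
    genome_premasked: bool = False
    mask_min_match_len: int = 100
    signature_db: str | None = None
    subsample_n: int = 10_000_000
    min_reads: int = 12
    min_starts: int = 4
    flank: int = 300
    slack: int = 2
    merge_window: int = 3
    tau: float = 0.6
    min_junctions: int = 50
    distance: str = "euclidean"
    linkage: str = "complete"
    normalization: str = "cpm"
    seed: int = 0
    write_sam: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.tau <= 1):
            raise ConfigError("tau must be in (0, 1]")
        for name in ("min_reads", "min_starts", "flank", "merge_window",
                     "min_junctions", "subsample_n"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.slack < 0:
            raise ConfigError("slack must be >= 0")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        doc.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**doc)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def checksum(self) -> str:
        # output_dir excluded: where results land must not change what
        # they contain (runs into different directories stay bit-identical)
        doc = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "fastq"}
    if not required <= set(df.columns):
        raise ConfigError(f"manifest must have columns {sorted(required)}")
    return df


def load_read_pairs(r1_path: Path, r2_path: Path, sample_id: str) -> list[ReadPair]:
    pairs = []
    with open(r1_path) as f1, open(r2_path) as f2:
        while True:
            h1 = f1.readline()
            if not h1:
                break
            s1, _, q1 = f1.readline(), f1.readline(), f1.readline()
            h2, s2, _, q2 = (f2.readline() for _ in range(4))
            rid1 = h1[1:].split()[0].strip()
            rid2 = h2[1:].split()[0].strip()
            if rid1 != rid2:
                raise DataError(
                    f"sample {sample_id}: read id mismatch {rid1!r} vs {rid2!r}"
                )
            pairs.append(
                ReadPair(
                    read_id=rid1,
                    r1_seq=s1.strip().upper(),
                    r1_qual=q1.strip(),
                    r2_seq=s2.strip().upper(),
                    r2_qual=q2.strip(),
                    sample_id=sample_id,
                )
            )
    return pairs


def profile_samples(
    callres: JunctionCallResult, genome, normalization: str = "cpm"
) -> tuple[BinaryProfileMatrix, list[str]]:
    """Count, normalize and binarize; zero-total samples become all-absent.

    Returns the binary matrix over all samples (in input order) and the
    list of zero-total sample ids.
    """
    cm = count_window_reads(
        callres.genome_alns, callres.read_family, callres.junctions, genome
    )
    zero = [s for s in cm.totals.index if cm.totals[s] == 0]
    if zero:
        logger.warning("samples with no mapped TE-associated reads: %s", zero)
    keep = [s for s in cm.totals.index if s not in zero]
    if not keep:
        raise DataError("no sample has mapped TE-associated reads")
    from .profile import CountMatrix

    nm = normalize(
        CountMatrix(counts=cm.counts[keep], totals=cm.totals[keep]),
        strategy=normalization,
    )
    bm = binarize(nm)
    presence = bm.presence
    zscores = bm.zscores
    for s in zero:
        presence = presence.assign(**{s: False})
        zscores = zscores.assign(**{s: 0.0})
    order = list(cm.totals.index)
    return (
        BinaryProfileMatrix(presence=presence[order], zscores=zscores[order]),
        zero,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict of outputs."""
    indir = Path(cfg.input_dir)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"config={cfg.checksum()}"

    stage = "load"
    try:
        db = load_te_database(indir / cfg.te_fasta, indir / cfg.te_config)
        genome = load_genome(indir / cfg.genome_fasta, masked=cfg.genome_premasked)
        if not cfg.genome_premasked:
            stage = "mask"
            genome, mask_report = mask_reference(
                genome, db, min_match_len=cfg.mask_min_match_len
            )
            write_mask_report(mask_report, outdir / "mask_report.tsv")
            write_genome(genome, outdir / "reference.masked.fasta")
        manifest = read_manifest(indir / cfg.manifest)

        stage = "subsample"
        samples: dict[str, list[ReadPair]] = {}
        for _, row in manifest.iterrows():
            sid = row["sample_id"]
            r1_name, r2_name = row["fastq"].split(",")
            pairs = load_read_pairs(indir / r1_name, indir / r2_name, sid)
            if len(pairs) > cfg.subsample_n:
                pairs = subsample_pairs(pairs, cfg.subsample_n, seed=cfg.seed)
            else:
                logger.info(
                    "sample %s: %d pairs <= subsample_n=%d, keeping all",
                    sid, len(pairs), cfg.subsample_n,
                )
            samples[sid] = pairs

        stage = "junctions"
        callres = call_junctions(
            samples,
            db,
            genome,
            min_reads=cfg.min_reads,
            min_starts=cfg.min_starts,
            slack=cfg.slack,
            merge_window=cfg.merge_window,
            flank=cfg.flank,
        )
        junctions_to_bed(callres.junctions, outdir / "junctions.bed", header=tag)
        junctions_to_tsv(callres.junctions, outdir / "junctions.tsv", header=tag)
        demux_rows = []
        for sid in samples:
            for fam, n in sorted(callres.demux[sid].counts.items()):
                demux_rows.append({"sample_id": sid, "family": fam, "n_pairs": n})
        with open(outdir / "demux_counts.tsv", "w") as fh:
            fh.write(f"# {tag}\n")
            pd.DataFrame(demux_rows).to_csv(fh, sep="\t", index=False)
        if cfg.write_sam:
            samdir = outdir / "alignments"
            samdir.mkdir(exist_ok=True)
            tlens = {n: len(s) for n, s in genome.contigs.items()}
            for sid in samples:
                export_sam(callres.genome_alns[sid], tlens, samdir / f"{sid}.r1.sam")

        stage = "profile"
        cm = count_window_reads(
            callres.genome_alns, callres.read_family, callres.junctions, genome
        )
        write_matrix_tsv(cm.counts, outdir / "counts.tsv", header=tag, as_int=True)
        bm, zero_samples = profile_samples(callres, genome, cfg.normalization)
        write_matrix_tsv(
            bm.presence.astype(int), outdir / "binary.tsv", header=tag, as_int=True
        )
        write_matrix_tsv(bm.zscores.round(6), outdir / "zscores.tsv", header=tag)
        with open(outdir / "profile_meta.json", "w") as fh:
            json.dump(
                {
                    "config": cfg.checksum(),
                    "totals": {s: int(v) for s, v in cm.totals.items()},
                    "normalization": cfg.normalization,
                    "zero_total_samples": zero_samples,
                    "n_junctions": len(callres.junctions),
                },
                fh,
                indent=2,
                sort_keys=True,
            )

        stage = "cluster"
        dendro = None
        if bm.presence.shape[1] >= 2:
            dendro = cluster_profiles(bm, distance=cfg.distance, linkage=cfg.linkage)
            (outdir / "dendrogram.newick").write_text(to_newick(dendro) + "\n")
            export_heatmap(
                bm, dendro, outdir / "heatmap.png", outdir / "binary.ordered.tsv",
                header=tag,
            )

        stage = "identify"
        id_results = []
        if cfg.signature_db:
            sig = SignatureDB.from_json(cfg.signature_db)
            for sid in bm.presence.columns:
                id_results.append(
                    identify(
                        bm.keys_for(sid),
                        sig,
                        sample_id=sid,
                        tau=cfg.tau,
                        min_junctions=cfg.min_junctions,
                        merge_window=cfg.merge_window,
                    )
                )
            write_identification_tsv(
                id_results, outdir / "identification.tsv", header=tag
            )
    except Exception as exc:
        raise type(exc)(f"[stage={stage}] {exc}") from exc

    stage_outputs = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        and p.name != "provenance.json"
    )
    provenance = {
        "config": {k: v for k, v in asdict(cfg).items() if k != "output_dir"},
        "config_checksum": cfg.checksum(),
        "version": __version__,
        "inputs": {
            name: _sha256(indir / getattr(cfg, name))
            for name in ("te_fasta", "te_config", "genome_fasta", "manifest")
        },
        "outputs": stage_outputs,
        "n_valid_junctions": len(callres.junctions),
        "samples": list(samples),
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return {
        "junctions": callres.junctions,
        "binary": bm,
        "dendrogram": dendro,
        "identification": id_results,
        "outdir": outdir,
        "provenance": provenance,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
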