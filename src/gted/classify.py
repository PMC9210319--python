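"""Clustering of binary profiles and identification against signatures.

Samples are hierarchically clustered on their 0/1 junction profiles
(Euclidean distance with complete linkage by default, matching the
defaults of the heatmap routine commonly used for this kind of figure;
Jaccard distance and average/Ward linkage are available).  Known lines
are stored as consensus junction-key sets (present in at least 2 of 3
replicates); a query profile is identified by its best Jaccard
similarity to the stored signatures, with two explicit No-ID outcomes:
too few junctions detected (e.g. a non-target species whose TEs the
enrichment cannot amplify) and insufficient similarity to any stored
line (a previously uncharacterized genotype).  The similarity threshold
and the junction-count floor are explicit parameters of this package —
the original identification was by dendrogram inspection — and are
reported in every result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigError, DataError
from .profile import BinaryProfileMatrix

__all__ = [
    "Dendrogram",
    "SignatureDB",
    "IdentificationResult",
    "cluster_profiles",
    "to_newick",
    "export_heatmap",
    "build_signature_db",
    "identify",
    "jaccard_keys",
    "batch_association_test",
]

JunctionKey = tuple[str, int, str, str]  # contig, breakpoint, side, family

DEFAULT_TAU = 0.6
DEFAULT_MIN_JUNCTIONS = 50
DEFAULT_MERGE_WINDOW = 3

NO_ID = "NO_ID"


@dataclass
class Dendrogram:
    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def cut(self, k: int) -> dict[str, int]:
        """Flat cluster labels from cutting the tree into k clusters."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def cophenetic(self) -> pd.DataFrame:
        d = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(d, index=self.labels, columns=self.labels)

    def clades(self) -> list[frozenset[str]]:
        """Leaf-label set of every internal node."""
        tree = hierarchy.to_tree(self.linkage)
        out: list[frozenset[str]] = []

        def walk(node) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([self.labels[node.id]])
            left = walk(node.get_left())
            right = walk(node.get_right())
            s = left | right
            out.append(s)
            return s

        walk(tree)
        return out

    def is_clade(self, labels: set[str]) -> bool:
        return frozenset(labels) in set(self.clades()) or len(labels) == 1


@dataclass
class SignatureDB:
    """Consensus present-junction sets of known cell lines."""

    entries: dict[str, set[JunctionKey]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.entries)) != len(self.entries):
            raise DataError("duplicate line names in signature database")
        for line, keys in self.entries.items():
            if not keys:
                raise DataError(f"empty signature for line {line!r}")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "schema": "gted-signature-db/1",
            "metadata": self.metadata,
            "entries": {
                line: sorted([list(k) for k in keys])
                for line, keys in self.entries.items()
            },
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureDB":
        doc = json.loads(Path(path).read_text())
        if doc.get("schema") != "gted-signature-db/1":
            raise DataError(f"unrecognized signature-db schema in {path}")
        entries = {
            line: {(c, int(b), s, f) for c, b, s, f in keys}
            for line, keys in doc["entries"].items()
        }
        return cls(entries=entries, metadata=doc.get("metadata", {}))

    def to_bed(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for line, keys in self.entries.items():
            with open(outdir / f"signature_{line}.bed", "w") as fh:
                for contig, bp, side, fam in sorted(keys):
                    fh.write(f"{contig}\t{bp}\t{bp + 1}\t{fam}:{side}\t.\t.\n")


@dataclass
class IdentificationResult:
    sample_id: str
    call: str  # line name or NO_ID
    nearest: str
    similarity: float
    n_junctions_detected: int
    reasons: list[str] = field(default_factory=list)
    tau: float = DEFAULT_TAU
    min_junctions: int = DEFAULT_MIN_JUNCTIONS


# ---------------------------------------------------------------------------
# Clustering


def cluster_profiles(
    bm: BinaryProfileMatrix | pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "complete",
) -> Dendrogram:
    """Agglomerative clustering of sample columns of a binary matrix."""
    presence = bm.presence if isinstance(bm, BinaryProfileMatrix) else bm
    labels = list(presence.columns)
    if len(labels) < 2:
        raise DataError("need at least 2 samples to cluster")
    X = presence.T.to_numpy(dtype=float)
    if distance == "euclidean":
        d = pdist(X, metric="euclidean")
    elif distance == "jaccard":
        d = pdist(X.astype(bool), metric="jaccard")
        d = np.nan_to_num(d, nan=0.0)  # two all-zero profiles are identical
    else:
        raise ConfigError(f"unknown distance {distance!r}")
    if linkage not in ("complete", "average", "ward"):
        raise ConfigError(f"unknown linkage {linkage!r}")
    Z = hierarchy.linkage(d, method=linkage)
    return Dendrogram(linkage=Z, labels=labels)


def to_newick(d: Dendrogram) -> str:
    """Newick string with branch lengths from merge heights."""
    tree = hierarchy.to_tree(d.linkage)

    def fmt(node, parent_dist: float) -> str:
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{_escape(d.labels[node.id])}:{length:.6g}"
        left = fmt(node.get_left(), node.dist)
        right = fmt(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    if tree.is_leaf():
        return f"{_escape(d.labels[tree.id])}:0;"
    left = fmt(tree.get_left(), tree.dist)
    right = fmt(tree.get_right(), tree.dist)
    return f"({left},{right});"


def _escape(label: str) -> str:
    if any(ch in label for ch in " (),:;'\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def export_heatmap(
    bm: BinaryProfileMatrix,
    d: Dendrogram,
    png_path: str | Path,
    tsv_path: str | Path | None = None,
    header: str | None = None,
) -> pd.DataFrame:
    """Dendrogram-ordered presence heatmap (PNG) plus the ordered matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = d.leaf_order()
    mat = bm.presence[order]
    # order rows by first sample in which the junction is present
    first = mat.to_numpy().argmax(axis=1) + (~mat.to_numpy().any(axis=1)) * len(order)
    mat = mat.iloc[np.argsort(first, kind="stable")]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.45 * len(order)), 6), constrained_layout=True
    )
    ax.imshow(mat.to_numpy(), aspect="auto", interpolation="nearest", cmap="Greys")
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{mat.shape[0]} junctions")
    fig.savefig(png_path, dpi=120, metadata={"Software": "gted"})
    plt.close(fig)
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            mat.astype(int).to_csv(fh, sep="\t", index_label="junction_id")
    return mat


# ---------------------------------------------------------------------------
# Signature database


def _parse_jid(jid: str) -> JunctionKey:
    contig, bp, side, family = jid.rsplit(":", 3)
    return (contig, int(bp), side, family)


def build_signature_db(
    bm: BinaryProfileMatrix,
    sample_to_line: dict[str, str],
    min_rep_frac: float = 2 / 3,
    metadata: dict | None = None,
) -> SignatureDB:
    """Consensus signature per line: keys present in >= min_rep_frac of reps."""
    missing = [s for s in sample_to_line if s not in bm.presence.columns]
    if missing:
        raise DataError(f"manifest samples missing from matrix: {missing}")
    by_line: dict[str, list[str]] = {}
    for sample, line in sample_to_line.items():
        by_line.setdefault(line, []).append(sample)
    entries: dict[str, set[JunctionKey]] = {}
    for line, samples in by_line.items():
        need = max(1, int(np.ceil(min_rep_frac * len(samples) - 1e-9)))
        hits = bm.presence[samples].sum(axis=1)
        keys = {_parse_jid(jid) for jid in hits.index[hits >= need]}
        if keys:
            entries[line] = keys
    return SignatureDB(entries=entries, metadata=metadata or {})


# ---------------------------------------------------------------------------
# Identification


def _match_count(a: list[int], b: list[int], window: int) -> int:
    """Greedy one-to-one matching of two sorted coordinate lists."""
    i = j = n = 0
    while i < len(a) and j < len(b):
        if abs(a[i] - b[j]) <= window:
            n += 1
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return n


def jaccard_keys(
    a: set[JunctionKey], b: set[JunctionKey], merge_window: int = DEFAULT_MERGE_WINDOW
) -> float:
    """Jaccard similarity with +/- merge_window breakpoint tolerance."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    groups: dict[tuple[str, str, str], tuple[list[int], list[int]]] = {}
    for contig, bp, side, fam in a:
        groups.setdefault((contig, side, fam), ([], []))[0].append(bp)
    for contig, bp, side, fam in b:
        groups.setdefault((contig, side, fam), ([], []))[1].append(bp)
    inter = sum(
        _match_count(sorted(av), sorted(bv), merge_window)
        for av, bv in groups.values()
    )
    union = len(a) + len(b) - inter
    return inter / union


def identify(
    query_keys: set[JunctionKey],
    db: SignatureDB,
    *,
    sample_id: str = "query",
    tau: float = DEFAULT_TAU,
    min_junctions: int = DEFAULT_MIN_JUNCTIONS,
    merge_window: int = DEFAULT_MERGE_WINDOW,
) -> IdentificationResult:
    """Call the best-matching line or NO_ID with an explicit reason.

    NO_ID reasons: TOO_FEW_JUNCTIONS (profile below the junction-count
    floor, e.g. a non-target species), BELOW_SIMILARITY (best Jaccard
    similarity under tau), AMBIGUOUS (similarity tie at or above tau).
    """
    if not db.entries:
        raise DataError("empty signature database")
    n_detected = len(query_keys)
    if n_detected < min_junctions:
        return IdentificationResult(
            sample_id=sample_id,
            call=NO_ID,
            nearest="",
            similarity=0.0,
            n_junctions_detected=n_detected,
            reasons=["TOO_FEW_JUNCTIONS"],
            tau=tau,
            min_junctions=min_junctions,
        )
    sims = {
        line: jaccard_keys(query_keys, keys, merge_window)
        for line, keys in db.entries.items()
    }
    best_sim = max(sims.values())
    best_lines = sorted(line for line, s in sims.items() if s == best_sim)
    nearest = best_lines[0]
    if best_sim < tau:
        call, reasons = NO_ID, ["BELOW_SIMILARITY"]
    elif len(best_lines) > 1:
        call, reasons = NO_ID, ["AMBIGUOUS"]
    else:
        call, reasons = nearest, []
    return IdentificationResult(
        sample_id=sample_id,
        call=call,
        nearest=nearest,
        similarity=best_sim,
        n_junctions_detected=n_detected,
        reasons=reasons,
        tau=tau,
        min_junctions=min_junctions,
    )


def write_identification_tsv(
    results: list[IdentificationResult], path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write(
            "sample_id\tcall\tnearest\tsimilarity\tn_junctions\treasons\ttau\t"
            "min_junctions\n"
        )
        for r in results:
            fh.write(
                f"{r.sample_id}\t{r.call}\t{r.nearest}\t{r.similarity:.4f}\t"
                f"{r.n_junctions_detected}\t{','.join(r.reasons) or '.'}\t"
                f"{r.tau}\t{r.min_junctions}\n"
            )


# ---------------------------------------------------------------------------
# Batch-label association (passage-stability analog)


def batch_association_test(
    d: Dendrogram,
    batch_labels: dict[str, str],
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test for association between tree and batch labels.

    Statistic: mean between-batch minus mean within-batch cophenetic
    distance (positive when same-batch samples sit closer in the tree).
    The p-value is the fraction of label permutations with a statistic
    at least as large, with the +1 correction.  p > 0.05 means profiles
    do not cluster by batch (the desired outcome for passages of one
    line).
    """
    labels = [batch_labels[s] for s in d.labels]
    coph = d.cophenetic().to_numpy()
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    dist = coph[iu]

    def stat(lab: np.ndarray) -> float:
        same = (lab[iu[0]] == lab[iu[1]])
        if same.all() or (~same).all():
            return 0.0
        return float(dist[~same].mean() - dist[same].mean())

    lab = np.asarray(labels)
    observed = stat(lab)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(lab)
        if stat(perm) >= observed:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return observed, p
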