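"""Domain types, file I/O, per-class quantile normalization, configuration.

The on-disk dialects are deliberately minimal tab-separated formats so that
exports from interaction databases, marker-gene tables (GMT) and pathway
topology dumps can be consumed without any network access:

* expression  ``gene_id<TAB>sample1<TAB>...`` (header row of sample ids)
* labels      ``sample_id<TAB>fiber_type`` (no header)
* catalog     ``gene_id<TAB>rna_class[<TAB>symbol]`` (no header)
* interactions ``mirna_id<TAB>target_id<TAB>target_class<TAB>evidence<TAB>source_db``
* clusters    standard GMT; optional sidecar ``cluster<TAB>subgroup``
* pathways    nodes ``pathway_id<TAB>title<TAB>node_id`` and
              edges ``pathway_id<TAB>src<TAB>dst<TAB>relation``
* networks    sectioned node/edge TSV or Cytoscape-style JSON elements
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cernet")

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")
EVIDENCE_LEVELS = ("validated", "predicted")
ORIGINS = ("query", "selected", "stitched")

#: fiber-type labels used when fixtures cycle sample annotations
FIBER_TYPES = ("1", "2A", "2A/2X", "2X", "2X/2B", "2B")


def setup_logging(level: int = logging.INFO) -> None:
    """Attach a structured stderr handler to the package logger (idempotent)."""
    if any(getattr(h, "_cernet", False) for h in logger.handlers):
        return
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s :: %(message)s")
    )
    handler._cernet = True  # type: ignore[attr-defined]
    logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class Config:
    """Pipeline thresholds and caps; every field maps to a CLI flag.

    rho_min_pos:    minimum Spearman rho for mRNA-lncRNA retention (inclusive)
    rho_max_neg:    retention bound for miRNA pairs (strictly below)
    n_perm:         permutations for the empirical p-value
    damping:        PageRank damping factor
    wpg_floor:      lower clamp for the PageRank edge weight wpg
    k_total:        node-centric candidate-set size
    k_per_class:    balanced per-RNA-class quota inside k_total
    custom_cap:     hard node cap for custom networks
    query_cap:      maximum size of a user query list
    view_circuit_cap: circuits attached to a pathway view
    """

    rho_min_pos: float = 0.45
    rho_max_neg: float = -0.35
    n_perm: int = 1000
    damping: float = 0.85
    wpg_floor: float = 1e-6
    k_total: int = 30
    k_per_class: int = 10
    custom_cap: int = 150
    query_cap: int = 30
    view_circuit_cap: int = 25

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Parse a ``key=value`` config file; unknown keys are a hard error."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            default = getattr(cls(), key)
            kwargs[key] = type(default)(value)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CatalogEntry:
    rna_class: str
    symbol: str


class GeneCatalog:
    """Mapping of gene identifier -> RNA class and display symbol.

    Identifiers are opaque strings (symbols or Ensembl-style ids); no
    namespace translation is attempted.
    """

    def __init__(self, entries: Mapping[str, CatalogEntry]):
        for gid, entry in entries.items():
            if entry.rna_class not in RNA_CLASSES:
                raise ValueError(
                    f"gene {gid!r}: rna_class {entry.rna_class!r} not in {RNA_CLASSES}"
                )
        self.entries: dict[str, CatalogEntry] = dict(entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def rna_class(self, gene_id: str) -> str:
        return self.entries[gene_id].rna_class

    def symbol(self, gene_id: str) -> str:
        return self.entries[gene_id].symbol

    def ids_of_class(self, rna_class: str) -> list[str]:
        if rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown rna_class {rna_class!r}")
        return [g for g, e in self.entries.items() if e.rna_class == rna_class]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample fiber-type labels."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    sample_labels: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene id(s): {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample id(s): {dupes}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.values.equals(other.values)
            and self.sample_labels == other.sample_labels
        )


@dataclass(frozen=True)
class InteractionRecord:
    """One directed miRNA -> target relation from an interaction database."""

    mirna_id: str
    target_id: str
    target_class: str  # mRNA | lncRNA
    evidence: str  # validated | predicted
    source_db: str

    def __post_init__(self) -> None:
        if self.evidence not in EVIDENCE_LEVELS:
            raise ValueError(
                f"evidence must be one of {EVIDENCE_LEVELS}, got {self.evidence!r}"
            )
        if self.target_class not in ("mRNA", "lncRNA"):
            raise ValueError(f"target_class must be mRNA or lncRNA, got {self.target_class!r}")


@dataclass
class ClusterSet:
    """Named marker-gene sets (e.g. snRNA-seq nucleus-type clusters)."""

    clusters: dict[str, list[str]]
    subgroup: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.clusters.items():
            if not genes:
                raise ValueError(f"cluster {name!r} is empty")
        if self.subgroup is not None:
            missing = set(self.clusters) - set(self.subgroup)
            if missing:
                raise ValueError(f"subgroup labels missing for clusters: {sorted(missing)}")


@dataclass
class PathwayTopology:
    pathway_id: str
    title: str
    node_ids: list[str]
    edges: list[tuple[str, str, str]]  # (src, dst, relation)
    extended_nodes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        nodes = set(self.node_ids)
        for src, dst, _rel in self.edges:
            if src not in nodes or dst not in nodes:
                raise ValueError(
                    f"pathway {self.pathway_id}: edge ({src},{dst}) endpoint not a node"
                )
        if not self.extended_nodes <= nodes:
            raise ValueError(f"pathway {self.pathway_id}: extended_nodes not a node subset")


@dataclass(frozen=True)
class NetworkNode:
    id: str
    rna_class: str
    score: float
    origin: str


@dataclass(frozen=True)
class NetworkEdge:
    source: str
    target: str
    w: float
    wpg: float
    evidence: str
    source_db: str
    correlation: float


@dataclass
class NetworkDocument:
    """Flat, export-ready description of a (sub)network."""

    nodes: list[NetworkNode]
    edges: list[NetworkEdge]

    def __post_init__(self) -> None:
        ids = {n.id for n in self.nodes}
        for e in self.edges:
            if e.source not in ids or e.target not in ids:
                raise ValueError(f"edge ({e.source},{e.target}) endpoint missing from nodes")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, labels_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a sample -> fiber-type label table.

    Duplicate gene ids and non-numeric cells are hard errors; label rows for
    unknown samples are ignored with a warning, and unlabeled samples are
    annotated ``"NA"``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate gene id(s) in {path}: {dupes}")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"non-numeric expression value at gene {gene!r}, sample {col!r}")
        if converted.isna().any():
            gene = df.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise ValueError(f"missing expression value at gene {gene!r}, sample {col!r}")
    # numpy's parser is correctly rounded (pd.to_numeric's fast path is not),
    # so values survive a write -> read round trip bit-exactly
    values = pd.DataFrame(
        df.to_numpy(dtype=str).astype(float),
        index=df.index.astype(str),
        columns=df.columns.astype(str),
    )

    labels_df = pd.read_csv(labels_path, sep="\t", header=None, dtype=str)
    labels: dict[str, str] = {}
    known = set(values.columns)
    for sample, fiber in zip(labels_df[0], labels_df[1]):
        if sample not in known:
            logger.warning("label for unknown sample %r ignored", sample)
            continue
        labels[sample] = fiber
    for sample in values.columns:
        if sample not in labels:
            logger.warning("sample %r has no fiber-type label; using 'NA'", sample)
            labels[sample] = "NA"
    return ExpressionMatrix(values=values, sample_labels=labels)


def read_catalog(path: str | Path) -> GeneCatalog:
    """Read ``gene_id<TAB>rna_class[<TAB>symbol]``; symbol defaults to the id."""
    entries: dict[str, CatalogEntry] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
        gid, rna_class = parts[0], parts[1]
        symbol = parts[2] if len(parts) > 2 and parts[2] else gid
        if gid in entries:
            raise ValueError(f"{path}:{lineno}: duplicate gene id {gid!r}")
        if rna_class not in RNA_CLASSES:
            raise ValueError(f"{path}:{lineno}: unknown rna_class {rna_class!r}")
        entries[gid] = CatalogEntry(rna_class=rna_class, symbol=symbol)
    return GeneCatalog(entries)


def read_interactions(
    path: str | Path,
    catalog: GeneCatalog,
    return_dropped: bool = False,
) -> list[InteractionRecord] | tuple[list[InteractionRecord], int]:
    """Read and validate an interaction TSV against the catalog.

    Rows whose miRNA or target are absent from the catalog, or whose declared
    target class contradicts it, are dropped and counted.  Rows reported by
    multiple databases are merged into one record per (mirna, target,
    evidence) with source names concatenated by ``;`` (sorted).
    """
    kept: dict[tuple[str, str, str], tuple[InteractionRecord, set[str]]] = {}
    dropped = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
        mirna, target, target_class, evidence, source_db = parts
        if evidence not in EVIDENCE_LEVELS:
            raise ValueError(
                f"{path}:{lineno}: evidence {evidence!r} not in {EVIDENCE_LEVELS}"
            )
        if (
            mirna not in catalog
            or catalog.rna_class(mirna) != "miRNA"
            or target not in catalog
            or catalog.rna_class(target) != target_class
        ):
            dropped += 1
            continue
        key = (mirna, target, evidence)
        if key in kept:
            kept[key][1].add(source_db)
        else:
            kept[key] = (
                InteractionRecord(mirna, target, target_class, evidence, source_db),
                {source_db},
            )
    records = [
        dataclasses.replace(rec, source_db=";".join(sorted(sources)))
        for rec, sources in kept.values()
    ]
    if dropped:
        logger.warning("dropped %d interaction rows contradicting the catalog", dropped)
    if return_dropped:
        return records, dropped
    return records


def read_clusters(
    path: str | Path, subgroups_path: str | Path | None = None
) -> ClusterSet:
    """Read a GMT file, optionally with a ``cluster<TAB>subgroup`` sidecar."""
    clusters: dict[str, list[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        name, _desc, *genes = parts
        genes = [g for g in genes if g]
        if name in clusters:
            raise ValueError(f"{path}:{lineno}: duplicate cluster {name!r}")
        clusters[name] = genes
    subgroup = None
    if subgroups_path is not None:
        subgroup = {}
        for raw in Path(subgroups_path).read_text().splitlines():
            if not raw.strip():
                continue
            name, label = raw.rstrip("\n").split("\t")[:2]
            subgroup[name] = label
    return ClusterSet(clusters=clusters, subgroup=subgroup)


def read_pathways(nodes_path: str | Path, edges_path: str | Path) -> list[PathwayTopology]:
    """Read the two-file pathway topology dialect into topology objects."""
    nodes: dict[str, dict] = {}
    for raw in Path(nodes_path).read_text().splitlines():
        if not raw.strip():
            continue
        pid, title, node_id = raw.rstrip("\n").split("\t")[:3]
        entry = nodes.setdefault(pid, {"title": title, "node_ids": []})
        entry["node_ids"].append(node_id)
    edges: dict[str, list[tuple[str, str, str]]] = {}
    for raw in Path(edges_path).read_text().splitlines():
        if not raw.strip():
            continue
        pid, src, dst, relation = raw.rstrip("\n").split("\t")[:4]
        edges.setdefault(pid, []).append((src, dst, relation))
    return [
        PathwayTopology(
            pathway_id=pid,
            title=entry["title"],
            node_ids=entry["node_ids"],
            edges=edges.get(pid, []),
        )
        for pid, entry in sorted(nodes.items())
    ]


# ---------------------------------------------------------------------------
# Writers (fixture emission + network export)
# ---------------------------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, path: str | Path, labels_path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    with open(labels_path, "w") as fh:
        for sample in matrix.sample_ids:
            fh.write(f"{sample}\t{matrix.sample_labels[sample]}\n")


def write_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, entry in catalog.entries.items():
            fh.write(f"{gid}\t{entry.rna_class}\t{entry.symbol}\n")


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.mirna_id}\t{rec.target_id}\t{rec.target_class}"
                f"\t{rec.evidence}\t{rec.source_db}\n"
            )


def write_clusters(
    clusters: ClusterSet, path: str | Path, subgroups_path: str | Path | None = None
) -> None:
    with open(path, "w") as fh:
        for name, genes in clusters.clusters.items():
            fh.write("\t".join([name, "."] + list(genes)) + "\n")
    if subgroups_path is not None and clusters.subgroup is not None:
        with open(subgroups_path, "w") as fh:
            for name, label in clusters.subgroup.items():
                fh.write(f"{name}\t{label}\n")


def write_pathways(
    pathways: Sequence[PathwayTopology], nodes_path: str | Path, edges_path: str | Path
) -> None:
    with open(nodes_path, "w") as fh:
        for p in pathways:
            for node in p.node_ids:
                fh.write(f"{p.pathway_id}\t{p.title}\t{node}\n")
    with open(edges_path, "w") as fh:
        for p in pathways:
            for src, dst, rel in p.edges:
                fh.write(f"{p.pathway_id}\t{src}\t{dst}\t{rel}\n")


_NODE_COLS = ("id", "rna_class", "score", "origin")
_EDGE_COLS = ("source", "target", "w", "wpg", "evidence", "source_db", "correlation")


def write_network(net: NetworkDocument, path: str | Path, format: str = "json") -> None:
    """Export a network as sectioned TSV or Cytoscape-style JSON elements.

    The TSV layout is a single file with ``#nodes`` and ``#edges`` sections so
    the document round-trips losslessly through :func:`read_network`.  Float
    fields are serialized with ``repr`` and therefore survive byte-stable.
    """
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("#nodes\t" + "\t".join(_NODE_COLS) + "\n")
            for n in net.nodes:
                fh.write(f"node\t{n.id}\t{n.rna_class}\t{n.score!r}\t{n.origin}\n")
            fh.write("#edges\t" + "\t".join(_EDGE_COLS) + "\n")
            for e in net.edges:
                fh.write(
                    f"edge\t{e.source}\t{e.target}\t{e.w!r}\t{e.wpg!r}"
                    f"\t{e.evidence}\t{e.source_db}\t{e.correlation!r}\n"
                )
    elif format == "json":
        doc = {
            "elements": {
                "nodes": [{"data": dataclasses.asdict(n)} for n in net.nodes],
                "edges": [{"data": dataclasses.asdict(e)} for e in net.edges],
            }
        }
        Path(path).write_text(json.dumps(doc, indent=1))
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "json") -> NetworkDocument:
    if format == "tsv":
        nodes, edges = [], []
        for raw in Path(path).read_text().splitlines():
            if raw.startswith("#") or not raw.strip():
                continue
            parts = raw.split("\t")
            if parts[0] == "node":
                nodes.append(
                    NetworkNode(id=parts[1], rna_class=parts[2], score=float(parts[3]), origin=parts[4])
                )
            elif parts[0] == "edge":
                edges.append(
                    NetworkEdge(
                        source=parts[1], target=parts[2], w=float(parts[3]),
                        wpg=float(parts[4]), evidence=parts[5], source_db=parts[6],
                        correlation=float(parts[7]),
                    )
                )
        return NetworkDocument(nodes=nodes, edges=edges)
    if format == "json":
        doc = json.loads(Path(path).read_text())
        return NetworkDocument(
            nodes=[NetworkNode(**el["data"]) for el in doc["elements"]["nodes"]],
            edges=[NetworkEdge(**el["data"]) for el in doc["elements"]["edges"]],
        )
    raise ValueError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def _quantile_normalize_block(block: np.ndarray) -> np.ndarray:
    """Classic quantile normalization of a genes x samples block.

    Each column is replaced by the rank-ordered reference distribution (the
    mean across samples of the column-wise sorted values).  Tied values in a
    column receive the mean of the reference quantiles they span.
    """
    n_genes, _ = block.shape
    reference = np.sort(block, axis=0).mean(axis=1)
    out = np.empty_like(block, dtype=float)
    for j in range(block.shape[1]):
        col = block[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n_genes)
        assigned[order] = reference
        # average the assigned reference values over tied groups
        ser = pd.Series(assigned)
        out[:, j] = ser.groupby(pd.Series(col)).transform("mean").to_numpy()
    return out


def normalize_quantile(matrix: ExpressionMatrix, catalog: GeneCatalog) -> ExpressionMatrix:
    """Quantile-normalize each RNA-class stratum independently.

    Coding and non-coding genes live on different dynamic ranges, so each
    class (mRNA, lncRNA, miRNA) is normalized on its own: after the call,
    within a stratum every sample shares the same sorted value vector.
    Strata with a single gene are returned unchanged with a warning.
    """
    missing = [g for g in matrix.gene_ids if g not in catalog]
    if missing:
        raise ValueError(f"genes absent from catalog: {missing[:5]}")
    values = matrix.values.copy()
    for rna_class in RNA_CLASSES:
        genes = [g for g in matrix.gene_ids if catalog.rna_class(g) == rna_class]
        if not genes:
            continue
        if len(genes) == 1:
            logger.warning(
                "stratum %s has a single gene; quantile normalization skipped", rna_class
            )
            continue
        block = values.loc[genes].to_numpy(dtype=float)
        values.loc[genes] = _quantile_normalize_block(block)
    return ExpressionMatrix(values=values, sample_labels=dict(matrix.sample_labels))
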