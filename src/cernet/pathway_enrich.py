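"""Pathway extension with non-coding regulators and hypergeometric enrichment.

Canonical pathway topologies only contain protein-coding genes.  Each
topology can be *extended* with the miRNAs whose correlation-gated
interactions target a pathway mRNA, and with the lncRNAs that appear in a
functional circuit with such a miRNA — giving a regulator-aware view of the
pathway.  Enrichment of a user query is tested per pathway with the
upper-tail hypergeometric probability and corrected across pathways with
the Benjamini-Hochberg step-up procedure.

Enrichment is computed on the original (coding) pathway membership: the
extension affects display only, since counting regulators as members would
conflate gene-set membership with regulatory reach.  A flag overrides this.
The default universe is the union of coding genes across the loaded
pathways, overridable with a user-supplied background.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.multitest import fdrcorrection

from .circuits import Circuit, GatedRelation
from .model_io import (
    NetworkDocument,
    NetworkEdge,
    NetworkNode,
    PathwayTopology,
    logger,
)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    title: str
    overlap: int
    pathway_size: int
    extended_size: int
    universe_size: int
    query_size: int
    p: float
    p_adj: float


def extend_pathway(
    topology: PathwayTopology,
    circuits: list[Circuit],
    gated_interactions: list[GatedRelation],
) -> PathwayTopology:
    """Extend one topology with gated miRNA regulators and their sponge lncRNAs.

    A miRNA is added (edge miRNA->mRNA, relation ``mirna-target``) when a
    gated interaction links it to a pathway mRNA; a lncRNA is added (edge
    lncRNA-miRNA, relation ``cerna-sponge``) when it shares a circuit with an
    added miRNA.  Original nodes and edges are preserved untouched.
    """
    pathway_genes = set(topology.node_ids)
    new_nodes: list[str] = []
    new_edges: list[tuple[str, str, str]] = []
    added_mirnas: set[str] = set()
    for rel in sorted(gated_interactions, key=lambda r: (r.mirna_id, r.target_id)):
        if rel.target_class == "mRNA" and rel.target_id in pathway_genes:
            if rel.mirna_id not in pathway_genes and rel.mirna_id not in added_mirnas:
                new_nodes.append(rel.mirna_id)
            added_mirnas.add(rel.mirna_id)
            new_edges.append((rel.mirna_id, rel.target_id, "mirna-target"))
    added_lncrnas: set[str] = set()
    for c in sorted(circuits, key=lambda c: c.key):
        if c.mirna_id in added_mirnas:
            if (
                c.lncrna_id not in pathway_genes
                and c.lncrna_id not in added_lncrnas
                and c.lncrna_id not in added_mirnas
            ):
                new_nodes.append(c.lncrna_id)
            if c.lncrna_id not in added_lncrnas:
                added_lncrnas.add(c.lncrna_id)
            edge = (c.lncrna_id, c.mirna_id, "cerna-sponge")
            if edge not in new_edges:
                new_edges.append(edge)
    return PathwayTopology(
        pathway_id=topology.pathway_id,
        title=topology.title,
        node_ids=list(topology.node_ids) + new_nodes,
        edges=list(topology.edges) + new_edges,
        extended_nodes=set(topology.extended_nodes) | set(new_nodes),
    )


def hypergeom_upper(k: int, universe: int, pathway: int, query: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N=universe, K=pathway, n=query)."""
    if not (0 <= k <= min(pathway, query)):
        raise ValueError(f"overlap k={k} inconsistent with pathway={pathway}, query={query}")
    if pathway > universe or query > universe:
        raise ValueError("pathway and query sizes cannot exceed the universe")
    return float(stats.hypergeom.sf(k - 1, universe, pathway, query))


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    if not pvalues:
        return []
    if any(not (0.0 < p <= 1.0) for p in pvalues):
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted = fdrcorrection(pvalues, alpha=0.05, method="indep")
    return [float(p) for p in adjusted]


def enrich(
    query: list[str],
    pathways: list[PathwayTopology],
    universe: set[str] | None = None,
    catalog=None,
    use_extended: bool = False,
) -> tuple[list[EnrichmentResult], list[str]]:
    """Hypergeometric enrichment of a query list over a pathway collection.

    Returns the per-pathway result table, sorted by (p_adj, p, pathway_id),
    plus the query members that were excluded from testing (non-coding ids
    and genes outside the universe — reported, never silently swallowed).
    """
    def _members(p: PathwayTopology) -> set[str]:
        if use_extended:
            return set(p.node_ids)
        return set(p.node_ids) - set(p.extended_nodes)

    if universe is None:
        universe = set()
        for p in pathways:
            universe |= _members(p)
    excluded = []
    effective = []
    for g in query:
        noncoding = catalog is not None and g in catalog and catalog.rna_class(g) != "mRNA"
        if g in universe and not noncoding:
            effective.append(g)
        else:
            excluded.append(g)
    if excluded:
        logger.info("query members excluded from enrichment: %s", excluded)
    query_set = set(effective)
    if not query_set:
        raise ValueError("no query gene lies in the enrichment universe")

    rows = []
    for p in pathways:
        members = _members(p) & universe
        overlap = len(members & query_set)
        pval = hypergeom_upper(overlap, len(universe), len(members), len(query_set))
        rows.append((p, members, overlap, pval))
    adjusted = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(
            pathway_id=p.pathway_id,
            title=p.title,
            overlap=overlap,
            pathway_size=len(members),
            extended_size=len(p.node_ids),
            universe_size=len(universe),
            query_size=len(query_set),
            p=pval,
            p_adj=p_adj,
        )
        for (p, members, overlap, pval), p_adj in zip(rows, adjusted)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p, r.pathway_id))
    return results, excluded


def write_enrichment(results: list[EnrichmentResult], path) -> None:
    cols = (
        "pathway_id\ttitle\toverlap\tpathway_size\textended_size"
        "\tuniverse_size\tquery_size\tp\tp_adj"
    )
    with open(path, "w") as fh:
        fh.write(cols + "\n")
        for r in results:
            fh.write(
                f"{r.pathway_id}\t{r.title}\t{r.overlap}\t{r.pathway_size}"
                f"\t{r.extended_size}\t{r.universe_size}\t{r.query_size}"
                f"\t{r.p!r}\t{r.p_adj!r}\n"
            )


def pathway_view(
    topology: PathwayTopology,
    query: list[str],
    circuits: list[Circuit],
    catalog=None,
    max_circuits: int = 25,
) -> NetworkDocument:
    """Displayable pathway document: query overlap marked, circuits attached.

    Pathway nodes overlapping the query get origin ``query``; circuits whose
    mRNA is a pathway node are attached (validated first, then by ascending
    mRNA-lncRNA p-value), capped at ``max_circuits``; their off-pathway
    members get origin ``stitched``.
    """
    query_set = set(query)
    pathway_nodes = set(topology.node_ids)

    def _class_of(node: str) -> str:
        if catalog is not None and node in catalog:
            return catalog.rna_class(node)
        return "mRNA" if node not in topology.extended_nodes else "lncRNA"

    nodes: dict[str, NetworkNode] = {}
    for node in topology.node_ids:
        origin = "query" if node in query_set else "selected"
        nodes[node] = NetworkNode(id=node, rna_class=_class_of(node), score=0.0, origin=origin)
    edges: list[NetworkEdge] = [
        NetworkEdge(
            source=src, target=dst, w=1.0, wpg=0.0,
            evidence="validated", source_db=rel, correlation=0.0,
        )
        for src, dst, rel in topology.edges
    ]

    attachable = sorted(
        (c for c in circuits if c.mrna_id in pathway_nodes),
        key=lambda c: (c.evidence != "validated", c.edge_cl.p_emp, c.key),
    )[:max_circuits]
    for c in attachable:
        for member, rna_class in (
            (c.lncrna_id, "lncRNA"),
            (c.mirna_id, "miRNA"),
        ):
            if member not in nodes:
                nodes[member] = NetworkNode(
                    id=member, rna_class=rna_class, score=0.0, origin="stitched"
                )
        for a, b, w, rho, ev, src_db in (
            (c.mirna_id, c.mrna_id, c.edge_mm.p_emp, c.edge_mm.rho, c.edge_mm.evidence, c.edge_mm.source_db),
            (c.mirna_id, c.lncrna_id, c.edge_ml.p_emp, c.edge_ml.rho, c.edge_ml.evidence, c.edge_ml.source_db),
            (c.mrna_id, c.lncrna_id, c.edge_cl.p_emp, c.edge_cl.rho, "predicted", ""),
        ):
            edges.append(
                NetworkEdge(
                    source=a, target=b, w=w, wpg=0.0,
                    evidence=ev, source_db=src_db, correlation=rho,
                )
            )
    # deduplicate edges while keeping first occurrence
    seen = set()
    unique_edges = []
    for e in edges:
        key = (min(e.source, e.target), max(e.source, e.target), e.source_db)
        if key not in seen:
            seen.add(key)
            unique_edges.append(e)
    return NetworkDocument(nodes=list(nodes.values()), edges=unique_edges)
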