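"""Connected, size-bounded subnetwork extraction from the master network.

The master network is far too large to display whole, so two extraction
procedures produce small connected views:

* **node-centric** — around one query node: induce the two-step
  neighborhood, select a PageRank-balanced candidate set (10 mRNAs,
  10 miRNAs, 10 lncRNAs when available, 30 total), collect the functional
  circuits touching those candidates (validated first) until no candidate
  is left isolated, then stitch the remaining components together along
  w-weighted shortest paths of the master network;
* **custom** — from a user list of up to 30 nodes: induce the subgraph on
  the query, connect its components along minimum-spanning-tree paths
  between their top-PageRank representatives, and cap the result at 150
  nodes.

Both tag every node with its provenance: ``query`` (asked for), ``selected``
(balanced candidate or circuit member), ``stitched`` (added to connect
components or to complete a circuit through a stitched edge).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .circuits import Circuit
from .master_network import MasterNetwork, _edge_key
from .model_io import Config, NetworkDocument, NetworkEdge, NetworkNode, logger


@dataclass
class Subnetwork:
    graph: nx.Graph
    circuit_ids: set[str] = field(default_factory=set)

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    def to_document(self) -> NetworkDocument:
        nodes = [
            NetworkNode(
                id=n,
                rna_class=d["rna_class"],
                score=d.get("score", 0.0),
                origin=d["origin"],
            )
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        edges = [
            NetworkEdge(
                source=a, target=b,
                w=d.get("w", 1.0), wpg=d.get("wpg", 0.0),
                evidence=d.get("evidence", "predicted"),
                source_db=d.get("source_db", ""),
                correlation=d.get("rho", 0.0),
            )
            for a, b, d in sorted(
                (( *_ordered(a, b), d) for a, b, d in self.graph.edges(data=True)),
                key=lambda t: (t[0], t[1]),
            )
        ]
        return NetworkDocument(nodes=nodes, edges=edges)


def _ordered(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _top_pagerank(nodes, pagerank) -> str:
    """Highest-PageRank node; lexicographic tie-break."""
    return min(nodes, key=lambda n: (-pagerank.get(n, 0.0), n))


def _add_node(sub: nx.Graph, master: nx.Graph, pagerank, node: str, origin: str, **extra) -> None:
    if node in sub:
        return
    sub.add_node(
        node,
        rna_class=master.nodes[node]["rna_class"],
        origin=origin,
        score=pagerank.get(node, 0.0),
        **extra,
    )


def _add_master_edge(sub: nx.Graph, master: nx.Graph, a: str, b: str) -> None:
    sub.add_edge(a, b, **master.edges[a, b])


# ---------------------------------------------------------------------------
# Step 1: two-step neighborhood
# ---------------------------------------------------------------------------

def two_step_neighborhood(net: MasterNetwork, center: str) -> nx.Graph:
    """Induced subgraph of all nodes within unweighted hop distance 2."""
    if center not in net.graph:
        raise KeyError(f"node {center!r} is not in the master network")
    reach = nx.single_source_shortest_path_length(net.graph, center, cutoff=2)
    return net.graph.subgraph(reach).copy()


# ---------------------------------------------------------------------------
# Step 2: PageRank-balanced candidate selection
# ---------------------------------------------------------------------------

def select_balanced_top(
    subgraph: nx.Graph,
    pagerank: dict[str, float],
    k_total: int = 30,
    k_per_class: int = 10,
) -> set[str]:
    """Top nodes by PageRank with an even split across RNA classes.

    Per class the ``k_per_class`` highest-scoring nodes are taken; classes
    with fewer members leave a shortfall that is backfilled with the
    globally next-highest-PageRank remaining nodes, so the result always has
    ``min(k_total, |subgraph|)`` nodes.  Ties break lexicographically.
    """
    def _rank_key(n: str):
        return (-pagerank.get(n, 0.0), n)

    by_class: dict[str, list[str]] = {}
    for n, d in subgraph.nodes(data=True):
        by_class.setdefault(d["rna_class"], []).append(n)
    chosen: set[str] = set()
    for rna_class in sorted(by_class):
        ranked = sorted(by_class[rna_class], key=_rank_key)
        chosen.update(ranked[:k_per_class])
    target = min(k_total, subgraph.number_of_nodes())
    if len(chosen) < target:
        rest = sorted((n for n in subgraph.nodes if n not in chosen), key=_rank_key)
        chosen.update(rest[: target - len(chosen)])
    elif len(chosen) > target:  # k_total below sum of per-class quotas
        chosen = set(sorted(chosen, key=_rank_key)[:target])
    return chosen


# ---------------------------------------------------------------------------
# Step 3: circuit collection
# ---------------------------------------------------------------------------

def collect_circuits(
    selected: set[str],
    circuits: list[Circuit],
) -> tuple[list[Circuit], set[str], set[str]]:
    """Greedy circuit collection until no selected node is left isolated.

    Iteratively adds circuits that share at least one member with the
    selected set, validated circuits strictly before predicted ones, each
    round picking the circuit that de-isolates the most currently edge-less
    selected nodes (lexicographic key tie-break).  Returns the collected
    circuits, the enlarged node set (selected plus circuit members), and the
    selected nodes no circuit could de-isolate (left to stitching).
    """
    selected = set(selected)
    applicable = [c for c in circuits if selected.intersection(c.members)]
    pools = (
        sorted((c for c in applicable if c.evidence == "validated"), key=lambda c: c.key),
        sorted((c for c in applicable if c.evidence == "predicted"), key=lambda c: c.key),
    )
    collected: dict[tuple[str, str, str], Circuit] = {}
    covered: set[str] = set()  # selected nodes with >= 1 incident collected edge
    while True:
        isolates = selected - covered
        if not isolates:
            break
        best: Circuit | None = None
        best_gain = 0
        for pool in pools:
            for c in pool:
                if c.key in collected:
                    continue
                gain = len(isolates.intersection(c.members))
                if gain > best_gain:  # pools are key-sorted: first max wins ties
                    best, best_gain = c, gain
            if best is not None:
                break  # validated priority: never fall through once one helps
        if best is None:
            break
        collected[best.key] = best
        covered.update(best.members)  # every member gains incident circuit edges
    nodes = selected | {m for c in collected.values() for m in c.members}
    remaining = selected - covered
    return sorted(collected.values(), key=lambda c: c.key), nodes, remaining


# ---------------------------------------------------------------------------
# Step 4: component stitching
# ---------------------------------------------------------------------------

def _circuit_edge_index(circuits: list[Circuit]) -> dict[tuple[str, str], list[Circuit]]:
    """Map each undirected edge to the circuits having it as a side."""
    index: dict[tuple[str, str], list[Circuit]] = {}
    for c in circuits:
        for a, b in (
            (c.mirna_id, c.mrna_id),
            (c.mirna_id, c.lncrna_id),
            (c.mrna_id, c.lncrna_id),
        ):
            index.setdefault(_edge_key(a, b), []).append(c)
    return index


def cover_path_edges(
    candidates: dict[str, set[tuple[str, str]]],
    uncovered: set[tuple[str, str]],
    method: str = "greedy",
) -> list[str]:
    """Choose third nodes covering the stitched path edges.

    Greedy weighted set cover (most new edges covered per node, lexicographic
    tie-break); ``method='exact'`` enumerates subsets for a provably minimal
    cover and is intended for small candidate sets.
    """
    coverable = uncovered & set().union(*candidates.values()) if candidates else set()
    if not coverable:
        return []
    if method == "exact":
        names = sorted(candidates)
        for size in range(1, len(names) + 1):
            for combo in itertools.combinations(names, size):
                if coverable <= set().union(*(candidates[n] for n in combo)):
                    return list(combo)
        return names
    chosen: list[str] = []
    remaining = set(coverable)
    while remaining:
        # deterministic: highest gain, then lexicographically smallest
        best = min(
            candidates,
            key=lambda n: (-len(candidates[n] & remaining), n),
        )
        gain = candidates[best] & remaining
        if not gain:
            break
        chosen.append(best)
        remaining -= gain
    return chosen


def _complete_circuits_on_edges(
    sub: nx.Graph,
    net: MasterNetwork,
    path_edges: list[tuple[str, str]],
    edge_index: dict[tuple[str, str], list[Circuit]],
    circuit_ids: set[str],
    cover_method: str = "greedy",
) -> None:
    """Add one extra node per stitched edge to recover circuits through it.

    Nodes already present in the subnetwork cover their edges for free; the
    remaining edges are covered by a set-cover choice of new third nodes so
    as few nodes as possible are introduced.
    """
    uncovered: set[tuple[str, str]] = set()
    candidates: dict[str, set[tuple[str, str]]] = {}
    free_hits: list[tuple[str, tuple[str, str], Circuit]] = []
    for edge in path_edges:
        for c in edge_index.get(edge, []):
            third = (set(c.members) - set(edge)).pop()
            if third in sub:
                free_hits.append((third, edge, c))
            else:
                candidates.setdefault(third, set()).add(edge)
        uncovered.add(edge)
    covered_free = {edge for _, edge, _ in free_hits}
    for third, edge, c in free_hits:
        for a, b in ((third, edge[0]), (third, edge[1])):
            if net.graph.has_edge(a, b):
                _add_master_edge(sub, net.graph, a, b)
        circuit_ids.add("|".join(c.key))
    chosen = cover_path_edges(candidates, uncovered - covered_free, method=cover_method)
    for third in chosen:
        _add_node(sub, net.graph, net.pagerank, third, origin="stitched", stitch_kind="cover")
        for edge in candidates[third]:
            for c in edge_index.get(edge, []):
                if (set(c.members) - set(edge)) == {third}:
                    circuit_ids.add("|".join(c.key))
            for a, b in ((third, edge[0]), (third, edge[1])):
                if net.graph.has_edge(a, b):
                    _add_master_edge(sub, net.graph, a, b)


def _components_sorted(graph: nx.Graph) -> list[set[str]]:
    return sorted(nx.connected_components(graph), key=lambda c: (len(c), min(c)))


def stitch_components(
    net: MasterNetwork,
    partial: Subnetwork,
    pagerank: dict[str, float] | None = None,
    circuits: list[Circuit] | None = None,
    weight: str = "w",
    cover_method: str = "greedy",
) -> Subnetwork:
    """Merge components until a single one remains.

    Each round joins the smallest and the largest component: their
    highest-PageRank nodes are connected by the shortest path in the master
    network (edge length ``w`` by default, hop count with ``weight='hops'``),
    path nodes/edges are added with origin ``stitched``, and one extra node
    per path edge is added where it completes a functional circuit (greedy
    maximal reuse).  Components unreachable in the master network are
    dropped with a warning, so the result is always connected.
    """
    pr = pagerank or net.pagerank
    edge_index = _circuit_edge_index(circuits or [])
    sub = partial.graph
    wkey = None if weight == "hops" else weight
    while True:
        comps = _components_sorted(sub)
        if len(comps) <= 1:
            break
        small, large = comps[0], comps[-1]
        u = _top_pagerank(small, pr)
        v = _top_pagerank(large, pr)
        try:
            path = nx.shortest_path(net.graph, u, v, weight=wkey)
        except nx.NetworkXNoPath:
            logger.warning(
                "component %s unreachable in the master network; dropping it", sorted(small)
            )
            sub.remove_nodes_from(small)
            continue
        path_edges = [_edge_key(a, b) for a, b in zip(path, path[1:])]
        for node in path:
            _add_node(sub, net.graph, pr, node, origin="stitched", stitch_kind="path")
        for a, b in zip(path, path[1:]):
            _add_master_edge(sub, net.graph, a, b)
        _complete_circuits_on_edges(
            sub, net, path_edges, edge_index, partial.circuit_ids, cover_method
        )
    return partial


# ---------------------------------------------------------------------------
# Node-centric composition
# ---------------------------------------------------------------------------

def node_centric_network(
    net: MasterNetwork,
    circuits: list[Circuit],
    center: str,
    config: Config | None = None,
    cover_method: str = "greedy",
) -> Subnetwork:
    """The most relevant connected network centered at one node."""
    cfg = config or Config()
    nbhd = two_step_neighborhood(net, center)
    selected = select_balanced_top(nbhd, net.pagerank, cfg.k_total, cfg.k_per_class)
    selected.add(center)
    collected, nodes, _isolates = collect_circuits(selected, circuits)

    sub = nx.Graph()
    for node in sorted(nodes):
        origin = "query" if node == center else "selected"
        _add_node(sub, net.graph, net.pagerank, node, origin=origin)
    circuit_ids = set()
    for c in collected:
        circuit_ids.add("|".join(c.key))
        for a, b in (
            (c.mirna_id, c.mrna_id),
            (c.mirna_id, c.lncrna_id),
            (c.mrna_id, c.lncrna_id),
        ):
            _add_master_edge(sub, net.graph, a, b)
    partial = Subnetwork(graph=sub, circuit_ids=circuit_ids)
    result = stitch_components(net, partial, circuits=circuits, cover_method=cover_method)
    if center not in result.graph:
        raise RuntimeError(f"center {center!r} lost during stitching")  # pragma: no cover
    return result


# ---------------------------------------------------------------------------
# Custom network from a user query list
# ---------------------------------------------------------------------------

class QueryTooLargeError(ValueError):
    def __init__(self, overflow: list[str], cap: int):
        self.overflow = overflow
        super().__init__(
            f"query exceeds the {cap}-node limit; rejected ids: {', '.join(overflow)}"
        )


def custom_network(
    net: MasterNetwork,
    circuits: list[Circuit],
    query: list[str],
    config: Config | None = None,
    cover_method: str = "greedy",
) -> Subnetwork:
    """Connected network around a user list of up to 30 known nodes.

    The induced subgraph on the query is connected component-by-component
    along MST paths between the components' highest-PageRank nodes, with
    circuit completion on the stitched edges.  The result is capped at 150
    nodes by evicting the lowest-PageRank circuit-completion nodes first,
    then path interiors; query nodes are never evicted.
    """
    cfg = config or Config()
    if len(query) > cfg.query_cap:
        raise QueryTooLargeError(overflow=list(query[cfg.query_cap:]), cap=cfg.query_cap)
    present = [q for q in query if q in net.graph]
    unknown = [q for q in query if q not in net.graph]
    if unknown:
        logger.warning("query ids absent from the master network (ignored): %s", unknown)
    if not present:
        raise ValueError("no query node is present in the master network")

    sub = nx.Graph()
    for node in sorted(set(present)):
        _add_node(sub, net.graph, net.pagerank, node, origin="query")
    for a, b in net.graph.subgraph(present).edges:
        _add_master_edge(sub, net.graph, a, b)
    partial = Subnetwork(graph=sub, circuit_ids=set())

    mst_graph = net.mst_graph
    edge_index = _circuit_edge_index(circuits)
    while True:
        comps = _components_sorted(sub)
        if len(comps) <= 1:
            break
        small, large = comps[0], comps[-1]
        u = _top_pagerank(small, net.pagerank)
        v = _top_pagerank(large, net.pagerank)
        try:
            path = nx.shortest_path(mst_graph, u, v)
        except nx.NetworkXNoPath:
            logger.warning("query components unreachable on the MST; dropping %s", sorted(small))
            sub.remove_nodes_from(small)
            continue
        for node in path:
            _add_node(sub, net.graph, net.pagerank, node, origin="stitched", stitch_kind="path")
        path_edges = [_edge_key(a, b) for a, b in zip(path, path[1:])]
        for a, b in zip(path, path[1:]):
            _add_master_edge(sub, net.graph, a, b)
        _complete_circuits_on_edges(
            sub, net, path_edges, edge_index, partial.circuit_ids, cover_method
        )

    _enforce_node_cap(sub, net.pagerank, cap=cfg.custom_cap)
    return partial


def _enforce_node_cap(sub: nx.Graph, pagerank: dict[str, float], cap: int) -> None:
    """Evict lowest-PageRank stitched nodes until at most ``cap`` remain.

    Circuit-completion nodes go first, path interiors only if still over the
    cap; query nodes are never removed.
    """
    def _evictable(kind: str) -> list[str]:
        nodes = [
            n for n, d in sub.nodes(data=True)
            if d["origin"] == "stitched" and d.get("stitch_kind") == kind
        ]
        return sorted(nodes, key=lambda n: (pagerank.get(n, 0.0), n))

    for kind in ("cover", "path"):
        over = sub.number_of_nodes() - cap
        if over <= 0:
            return
        for node in _evictable(kind)[:over]:
            sub.remove_node(node)
    if sub.number_of_nodes() > cap:  # pragma: no cover - query larger than cap impossible (30 <= 150)
        logger.warning("network still exceeds the node cap after eviction")
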