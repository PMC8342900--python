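"""The master network: union of circuit edges with dual weights w / wpg.

Every edge of every functional circuit enters one undirected graph.  Each
edge carries two weights:

* ``w``  — the permutation p-value of the Spearman correlation between the
  edge's endpoints (small w = statistically strong edge);
* ``wpg`` — the weight used for PageRank.  Predicted-circuit edges get
  ``1 - w``; validated-circuit edges get ``1 - w * sf`` where the scale
  factor ``sf`` is the ratio of predicted-circuit to validated-circuit edge
  counts.  Because predictions vastly outnumber validated interactions, sf
  rescales validated edges so they are not drowned out.  The validated
  formula can go negative when ``w * sf > 1``, so wpg is clamped to
  ``[wpg_floor, 1]`` to keep the random walk well defined while preserving
  the intended up-weighting of small-w validated edges.

PageRank (uniform teleport, undirected edges treated as two arcs of equal
weight) and the minimum spanning forest under edge length ``w`` are
precomputed once and reused by every subnetwork extraction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .circuits import Circuit
from .model_io import Config, logger


@dataclass
class MasterNetwork:
    graph: nx.Graph
    sf: float
    pagerank: dict[str, float]
    mst: set[tuple[str, str]]  # sorted endpoint pairs
    damping: float = 0.85
    wpg_floor: float = 1e-6

    @property
    def mst_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes(data=True))
        for a, b in self.mst:
            g.add_edge(a, b, **self.graph.edges[a, b])
        return g


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def compute_sf(graph: nx.Graph, mode: str = "edges", circuits: list[Circuit] | None = None) -> float:
    """Scale factor: predicted-circuit count over validated-circuit count.

    ``mode='edges'`` (default) counts master-network edges appearing in at
    least one predicted (resp. validated) circuit; ``mode='circuits'`` counts
    the circuits themselves.  With no validated edges the ratio is undefined
    and sf falls back to 1 with a prominent warning (weighting then treats
    every edge alike).
    """
    if mode == "edges":
        n_pred = sum(1 for *_, d in graph.edges(data=True) if d["in_predicted"])
        n_val = sum(1 for *_, d in graph.edges(data=True) if d["in_validated"])
    elif mode == "circuits":
        if circuits is None:
            raise ValueError("mode='circuits' requires the circuit list")
        n_pred = sum(1 for c in circuits if c.evidence == "predicted")
        n_val = sum(1 for c in circuits if c.evidence == "validated")
    else:
        raise ValueError("mode must be 'edges' or 'circuits'")
    if n_val == 0:
        logger.warning(
            "no edges from validated circuits: scale factor undefined, falling back to sf=1"
        )
        return 1.0
    return n_pred / n_val


def assign_wpg(w: float, validated: bool, sf: float, floor: float = 1e-6) -> float:
    """PageRank weight for one edge, clamped to [floor, 1]."""
    if not (0.0 < w <= 1.0):
        raise ValueError(f"w must be in (0, 1], got {w}")
    if sf < 0:
        raise ValueError("sf must be >= 0")
    raw = 1.0 - w * sf if validated else 1.0 - w
    return min(1.0, max(floor, raw))


def pagerank(graph: nx.Graph, damping: float = 0.85, tol: float = 1e-9) -> dict[str, float]:
    """Stationary scores of the wpg-weighted walk with uniform teleport."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("pagerank needs at least one node")
    # networkx stops at sum-error < n * tol; rescale so tol bounds total error
    return nx.pagerank(graph, alpha=damping, weight="wpg", tol=tol / n, max_iter=10_000)


def minimum_spanning_forest(graph: nx.Graph) -> set[tuple[str, str]]:
    """Kruskal forest under edge length ``w``; lexicographic tie-break.

    Determinism relies on edges being inserted in sorted endpoint order
    (build_master guarantees this) together with Kruskal's stable sort.
    """
    return {
        _edge_key(a, b)
        for a, b, _ in nx.minimum_spanning_edges(graph, algorithm="kruskal", weight="w", data=True)
    }


def build_master(circuits: list[Circuit], config: Config | None = None) -> MasterNetwork:
    """Assemble the master network from a circuit list.

    Node/edge sets are the union over circuit sides; each edge remembers the
    circuits it belongs to.  sf is computed before wpg assignment.  Edges in
    both a validated and a predicted circuit use the validated formula.
    """
    if not circuits:
        raise ValueError("cannot build a master network from zero circuits")
    cfg = config or Config()

    nodes: dict[str, str] = {}
    edges: dict[tuple[str, str], dict] = {}
    for c in circuits:
        cid = "|".join(c.key)
        nodes[c.mrna_id] = "mRNA"
        nodes[c.lncrna_id] = "lncRNA"
        nodes[c.mirna_id] = "miRNA"
        sides = (
            (c.mirna_id, c.mrna_id, c.edge_mm.p_emp, c.edge_mm.rho, "mirna-mrna", c.edge_mm.source_db),
            (c.mirna_id, c.lncrna_id, c.edge_ml.p_emp, c.edge_ml.rho, "mirna-lncrna", c.edge_ml.source_db),
            (c.mrna_id, c.lncrna_id, c.edge_cl.p_emp, c.edge_cl.rho, "mrna-lncrna", ""),
        )
        for a, b, w, rho, pair_class, source_db in sides:
            if not (isinstance(w, float) and 0.0 < w <= 1.0) or math.isnan(w):
                raise ValueError(f"edge ({a},{b}): w must be in (0,1], got {w}")
            key = _edge_key(a, b)
            attrs = edges.setdefault(
                key,
                {
                    "w": w, "rho": rho, "pair_class": pair_class,
                    "source_db": source_db, "circuit_ids": [],
                    "in_validated": False, "in_predicted": False,
                },
            )
            attrs["circuit_ids"].append(cid)
            if c.evidence == "validated":
                attrs["in_validated"] = True
            else:
                attrs["in_predicted"] = True

    graph = nx.Graph()
    for node, rna_class in sorted(nodes.items()):
        graph.add_node(node, rna_class=rna_class)
    for (a, b), attrs in sorted(edges.items()):
        attrs["circuit_ids"] = sorted(set(attrs["circuit_ids"]))
        attrs["evidence"] = "validated" if attrs["in_validated"] else "predicted"
        graph.add_edge(a, b, **attrs)

    sf = compute_sf(graph)
    for a, b, d in graph.edges(data=True):
        d["wpg"] = assign_wpg(d["w"], d["in_validated"], sf, floor=cfg.wpg_floor)

    scores = pagerank(graph, damping=cfg.damping)
    mst = minimum_spanning_forest(graph)
    return MasterNetwork(
        graph=graph, sf=sf, pagerank=scores, mst=mst,
        damping=cfg.damping, wpg_floor=cfg.wpg_floor,
    )


# ---------------------------------------------------------------------------
# Flat-file persistence (edges.tsv, nodes.tsv, pagerank.tsv, mst.tsv, meta.json)
# ---------------------------------------------------------------------------

def write_master(net: MasterNetwork, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "nodes.tsv", "w") as fh:
        fh.write("id\trna_class\n")
        for node, d in sorted(net.graph.nodes(data=True)):
            fh.write(f"{node}\t{d['rna_class']}\n")
    with open(out / "edges.tsv", "w") as fh:
        fh.write(
            "a\tb\tw\twpg\trho\tpair_class\tevidence\tin_validated"
            "\tin_predicted\tsource_db\tcircuit_ids\n"
        )
        for a, b in sorted(_edge_key(a, b) for a, b in net.graph.edges):
            d = net.graph.edges[a, b]
            fh.write(
                f"{a}\t{b}\t{d['w']!r}\t{d['wpg']!r}\t{d['rho']!r}\t{d['pair_class']}"
                f"\t{d['evidence']}\t{int(d['in_validated'])}\t{int(d['in_predicted'])}"
                f"\t{d['source_db']}\t{','.join(d['circuit_ids'])}\n"
            )
    with open(out / "pagerank.tsv", "w") as fh:
        fh.write("id\tscore\n")
        for node in sorted(net.pagerank):
            fh.write(f"{node}\t{net.pagerank[node]!r}\n")
    with open(out / "mst.tsv", "w") as fh:
        fh.write("a\tb\n")
        for a, b in sorted(net.mst):
            fh.write(f"{a}\t{b}\n")
    (out / "meta.json").write_text(
        json.dumps({"sf": net.sf, "damping": net.damping, "wpg_floor": net.wpg_floor})
    )


def read_master(in_dir: str | Path) -> MasterNetwork:
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    graph = nx.Graph()
    with open(src / "nodes.tsv") as fh:
        fh.readline()
        for raw in fh:
            if raw.strip():
                node, rna_class = raw.rstrip("\n").split("\t")
                graph.add_node(node, rna_class=rna_class)
    with open(src / "edges.tsv") as fh:
        fh.readline()
        for raw in fh:
            if not raw.strip():
                continue
            a, b, w, wpg, rho, pair_class, evidence, in_val, in_pred, source_db, cids = (
                raw.rstrip("\n").split("\t")
            )
            graph.add_edge(
                a, b, w=float(w), wpg=float(wpg), rho=float(rho),
                pair_class=pair_class, evidence=evidence,
                in_validated=bool(int(in_val)), in_predicted=bool(int(in_pred)),
                source_db=source_db, circuit_ids=cids.split(",") if cids else [],
            )
    scores = {}
    with open(src / "pagerank.tsv") as fh:
        fh.readline()
        for raw in fh:
            if raw.strip():
                node, score = raw.rstrip("\n").split("\t")
                scores[node] = float(score)
    mst = set()
    with open(src / "mst.tsv") as fh:
        fh.readline()
        for raw in fh:
            if raw.strip():
                a, b = raw.rstrip("\n").split("\t")
                mst.add((a, b))
    return MasterNetwork(
        graph=graph, sf=meta["sf"], pagerank=scores, mst=mst,
        damping=meta["damping"], wpg_floor=meta["wpg_floor"],
    )
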