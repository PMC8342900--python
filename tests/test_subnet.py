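"""Node-centric and custom subnetwork extraction."""

import itertools

import networkx as nx
import pytest

import cernet as cn
from cernet.circuits import GatedRelation
from cernet.correlation import CorrelationRecord
from cernet.fixtures import simulate_master
from cernet.model_io import Config
from cernet.subnet import (
    QueryTooLargeError,
    Subnetwork,
    cover_path_edges,
    _add_node,
)


def _circuit(m, l, i, evidence="validated", w=0.01):
    return cn.Circuit(
        mrna_id=m, lncrna_id=l, mirna_id=i,
        edge_mm=GatedRelation(i, m, "mRNA", evidence, "db", -0.6, w),
        edge_ml=GatedRelation(i, l, "lncRNA", evidence, "db", -0.6, w),
        edge_cl=CorrelationRecord(m, l, "mrna-lncrna", 0.7, w, True),
    )


# ---------------------------------------------------------------------------
# two-step neighborhood
# ---------------------------------------------------------------------------

def test_neighborhood_isolated_and_path():
    net = cn.build_master(
        [_circuit("m1", "l1", "i1"), _circuit("m2", "l2", "i2")]
    )
    sub = cn.two_step_neighborhood(net, "m1")
    assert set(sub.nodes) == {"m1", "l1", "i1"}
    with pytest.raises(KeyError, match="ghost"):
        cn.two_step_neighborhood(net, "ghost")


def test_neighborhood_path_depth_two():
    """On a path a-b-c-d (achieved through chained circuits), the 2-step
    neighborhood of an end node stops at distance 2."""
    circuits = [_circuit("m1", "l1", "i1"), _circuit("m2", "l1", "i2")]
    net = cn.build_master(circuits)
    sub = cn.two_step_neighborhood(net, "m2")
    # m2 -(1)- l1/i2 -(2)- m1,i1
    assert set(sub.nodes) == {"m2", "l1", "i2", "m1", "i1"}


def test_neighborhood_equals_bfs_oracle(master_net):
    for center in sorted(master_net.graph.nodes)[:10]:
        sub = cn.two_step_neighborhood(master_net, center)
        bfs = {center}
        for n1 in master_net.graph[center]:
            bfs.add(n1)
            bfs.update(master_net.graph[n1])
        assert set(sub.nodes) == bfs
        # induced: every master edge among the kept nodes is present
        for a, b in itertools.combinations(sorted(bfs), 2):
            assert sub.has_edge(a, b) == master_net.graph.has_edge(a, b)


# ---------------------------------------------------------------------------
# balanced top-k selection
# ---------------------------------------------------------------------------

def _graph_with_classes(counts, seed=0):
    g = nx.Graph()
    pr = {}
    k = 0
    for rna_class, n in counts.items():
        for j in range(n):
            name = f"{rna_class}_{j:02d}"
            g.add_node(name, rna_class=rna_class)
            pr[name] = 1.0 / (k + 2)
            k += 1
    return g, pr


def test_balanced_selection_full_classes():
    g, pr = _graph_with_classes({"mRNA": 15, "lncRNA": 12, "miRNA": 11})
    chosen = cn.select_balanced_top(g, pr)
    assert len(chosen) == 30
    per_class = {c: sum(1 for n in chosen if n.startswith(c)) for c in ("mRNA", "lncRNA", "miRNA")}
    assert per_class == {"mRNA": 10, "lncRNA": 10, "miRNA": 10}


def test_balanced_selection_shortfall_backfilled():
    """3 lncRNAs only: all kept, shortfall filled by global PageRank."""
    g, pr = _graph_with_classes({"mRNA": 25, "lncRNA": 3, "miRNA": 12})
    chosen = cn.select_balanced_top(g, pr)
    assert len(chosen) == 30
    assert sum(1 for n in chosen if n.startswith("lncRNA")) == 3
    # sort-and-slice oracle: quota picks + best remaining by global score
    quota = set()
    for cls, cap in (("mRNA", 10), ("lncRNA", 10), ("miRNA", 10)):
        ranked = sorted((n for n in g if n.startswith(cls)), key=lambda n: (-pr[n], n))
        quota.update(ranked[:cap])
    rest = sorted((n for n in g if n not in quota), key=lambda n: (-pr[n], n))
    assert chosen == quota | set(rest[: 30 - len(quota)])


def test_balanced_selection_small_neighborhood():
    g, pr = _graph_with_classes({"mRNA": 3, "miRNA": 2})
    assert cn.select_balanced_top(g, pr) == set(g.nodes)


def test_balanced_selection_ties_lexicographic():
    g, _ = _graph_with_classes({"mRNA": 12})
    flat = {n: 0.5 for n in g}
    chosen = cn.select_balanced_top(g, flat, k_total=30, k_per_class=10)
    assert chosen == set(sorted(g.nodes)[:10]) | set(sorted(n for n in g if n not in set(sorted(g.nodes)[:10]))[:2])


def test_candidate_set_never_exceeds_cap(master_net):
    for center in sorted(master_net.graph.nodes)[:20]:
        sub = cn.two_step_neighborhood(master_net, center)
        chosen = cn.select_balanced_top(sub, master_net.pagerank)
        assert len(chosen) <= 30
        by_class = {}
        for n in sub.nodes:
            by_class.setdefault(sub.nodes[n]["rna_class"], []).append(n)
        if all(len(v) >= 10 for v in by_class.values()) and len(by_class) == 3:
            for cls, members in by_class.items():
                assert sum(1 for n in chosen if n in members) == 10


# ---------------------------------------------------------------------------
# circuit collection
# ---------------------------------------------------------------------------

def test_collect_full_triangle():
    c = _circuit("m1", "l1", "i1", "validated")
    collected, nodes, isolates = cn.collect_circuits({"m1", "l1", "i1"}, [c])
    assert collected == [c]
    assert nodes == {"m1", "l1", "i1"}
    assert isolates == set()


def test_collect_prefers_validated():
    val = _circuit("m1", "l1", "i1", "validated")
    pred = _circuit("m1", "l2", "i2", "predicted")
    collected, _, _ = cn.collect_circuits({"m1"}, [pred, val])
    assert collected == [val]


def test_collect_greedy_matches_replay_oracle(master_circuits, master_net):
    """Isolate count after collection equals a brute-force greedy replay."""
    selected = set(sorted(master_net.graph.nodes)[:12])
    collected, nodes, isolates = cn.collect_circuits(selected, master_circuits)

    # independent replay: same rule, separate bookkeeping
    chosen = []
    covered = set()
    pools = (
        sorted((c for c in master_circuits
                if c.evidence == "validated" and selected & set(c.members)), key=lambda c: c.key),
        sorted((c for c in master_circuits
                if c.evidence == "predicted" and selected & set(c.members)), key=lambda c: c.key),
    )
    while selected - covered:
        pick = None
        for pool in pools:
            scored = [
                (len((selected - covered) & set(c.members)), c)
                for c in pool if c not in chosen
            ]
            scored = [t for t in scored if t[0] > 0]
            if scored:
                pick = max(scored, key=lambda t: (t[0], tuple(-ord(ch) for ch in "|".join(t[1].key))))[1]
                # max gain; lexicographic smallest on ties
                best_gain = max(t[0] for t in scored)
                pick = min((c for g, c in scored if g == best_gain), key=lambda c: c.key)
                break
        if pick is None:
            break
        chosen.append(pick)
        covered.update(pick.members)
    assert isolates == selected - covered
    assert {c.key for c in collected} == {c.key for c in chosen}


def test_collected_nodes_all_touch_an_edge(master_circuits, master_net):
    selected = set(sorted(master_net.graph.nodes)[:12])
    collected, nodes, isolates = cn.collect_circuits(selected, master_circuits)
    touched = {m for c in collected for m in c.members}
    assert nodes == selected | touched
    for n in selected - isolates:
        assert n in touched


# ---------------------------------------------------------------------------
# stitching
# ---------------------------------------------------------------------------

def _partial_from_nodes(net, node_sets):
    g = nx.Graph()
    for nodes in node_sets:
        for n in nodes:
            _add_node(g, net.graph, net.pagerank, n, origin="selected")
        for a, b in itertools.combinations(nodes, 2):
            if net.graph.has_edge(a, b):
                g.add_edge(a, b, **net.graph.edges[a, b])
    return Subnetwork(graph=g)


def test_stitch_already_connected_identity():
    net = cn.build_master([_circuit("m1", "l1", "i1")])
    partial = _partial_from_nodes(net, [{"m1", "l1", "i1"}])
    before = set(partial.graph.nodes)
    out = cn.stitch_components(net, partial)
    assert set(out.graph.nodes) == before


def test_stitch_two_components_adds_path_interior():
    """Two triangles sharing no node, joined through a bridging circuit:
    the path interior node arrives with origin=stitched."""
    bridge = _circuit("m1", "lB", "i2")  # connects circuit 1's m1 to circuit 2's i2
    circuits = [_circuit("m1", "l1", "i1"), _circuit("m2", "l2", "i2"), bridge]
    net = cn.build_master(circuits)
    partial = _partial_from_nodes(net, [{"m1", "l1", "i1"}, {"m2", "l2", "i2"}])
    out = cn.stitch_components(net, partial, circuits=circuits)
    assert nx.is_connected(out.graph)
    added = {n for n, d in out.graph.nodes(data=True) if d["origin"] == "stitched"}
    assert added  # lB or another interior appears
    for n in added:
        assert out.graph.nodes[n]["origin"] == "stitched"


def test_stitch_shortest_path_follows_w(master_net, master_circuits):
    """Stitched connections replay a Dijkstra oracle on w."""
    comps = sorted(nx.connected_components(master_net.graph), key=len)
    big = max(comps, key=len)
    inside = sorted(big)
    a_nodes, b_nodes = {inside[0]}, {inside[-1]}
    partial = _partial_from_nodes(master_net, [a_nodes, b_nodes])
    out = cn.stitch_components(master_net, partial, circuits=master_circuits)
    assert nx.is_connected(out.graph)
    u = next(iter(a_nodes))
    v = next(iter(b_nodes))
    oracle_path = nx.dijkstra_path(master_net.graph, u, v, weight="w")
    assert set(oracle_path) <= set(out.graph.nodes)


def test_stitch_unreachable_component_dropped(caplog):
    net = cn.build_master([_circuit("m1", "l1", "i1"), _circuit("m2", "l2", "i2")])
    partial = _partial_from_nodes(net, [{"m1", "l1", "i1"}, {"m2"}])
    with caplog.at_level("WARNING", logger="cernet"):
        out = cn.stitch_components(net, partial)
    assert nx.is_connected(out.graph)
    assert "m2" not in out.graph


def test_cover_exact_minimizes_added_nodes():
    """A reusable third node covering both path edges beats two singles;
    greedy agrees with the exhaustive solver on small instances."""
    candidates = {
        "reuse": {("a", "b"), ("b", "c")},
        "single1": {("a", "b")},
        "single2": {("b", "c")},
    }
    uncovered = {("a", "b"), ("b", "c")}
    assert cover_path_edges(candidates, uncovered, method="exact") == ["reuse"]
    assert cover_path_edges(candidates, uncovered, method="greedy") == ["reuse"]


def test_cover_greedy_matches_exact_on_random_small_instances():
    import numpy as np

    rng = np.random.default_rng(9)
    edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]
    for _ in range(30):
        n_cand = int(rng.integers(1, 7))
        candidates = {}
        for k in range(n_cand):
            cover = {edges[j] for j in rng.choice(4, size=int(rng.integers(1, 4)), replace=False)}
            candidates[f"t{k}"] = cover
        uncovered = set(edges)
        exact = cover_path_edges(candidates, uncovered, method="exact")
        greedy = cover_path_edges(candidates, uncovered, method="greedy")
        coverable = set().union(*candidates.values()) & uncovered
        covered_by_greedy = set().union(*(candidates[n] for n in greedy)) if greedy else set()
        assert coverable <= covered_by_greedy
        # greedy never uses fewer nodes than the optimum
        assert len(greedy) >= len(exact)


# ---------------------------------------------------------------------------
# composed extractions
# ---------------------------------------------------------------------------

def test_node_centric_single_component_and_origins(master_net, master_circuits):
    for center in sorted(master_net.graph.nodes)[:8]:
        sub = cn.node_centric_network(master_net, master_circuits, center)
        assert nx.is_connected(sub.graph)
        assert sub.graph.nodes[center]["origin"] == "query"
        assert set(nx.get_node_attributes(sub.graph, "origin").values()) <= {
            "query", "selected", "stitched"
        }


def test_node_centric_deterministic(master_net, master_circuits):
    center = sorted(master_net.graph.nodes)[0]
    a = cn.node_centric_network(master_net, master_circuits, center)
    b = cn.node_centric_network(master_net, master_circuits, center)
    assert nx.utils.graphs_equal(a.graph, b.graph)
    assert a.circuit_ids == b.circuit_ids


def test_custom_single_and_adjacent_queries(master_net, master_circuits):
    nodes = sorted(master_net.graph.nodes)
    solo = cn.custom_network(master_net, master_circuits, [nodes[0]])
    assert set(solo.graph.nodes) == {nodes[0]}
    a, b = next(iter(master_net.graph.edges))
    pair = cn.custom_network(master_net, master_circuits, [a, b])
    assert set(pair.graph.nodes) == {a, b}
    assert pair.graph.number_of_edges() == 1


def test_custom_rejects_oversized_query(master_net, master_circuits):
    query = [f"q{k}" for k in range(35)]
    with pytest.raises(QueryTooLargeError) as err:
        cn.custom_network(master_net, master_circuits, query)
    assert err.value.overflow == query[30:]


def test_custom_unknown_only_query_is_error(master_net, master_circuits):
    with pytest.raises(ValueError, match="no query node"):
        cn.custom_network(master_net, master_circuits, ["ghost1", "ghost2"])


def test_custom_scattered_query_connected_and_capped(master_net, master_circuits):
    comps = sorted(nx.connected_components(master_net.graph), key=len)
    big = sorted(max(comps, key=len))
    query = big[:: max(1, len(big) // 20)][:25]
    sub = cn.custom_network(master_net, master_circuits, query)
    assert nx.is_connected(sub.graph)
    assert sub.graph.number_of_nodes() <= 150
    assert set(query) <= set(sub.graph.nodes)
    # every non-query node is stitched (MST path or circuit completion)
    for n, d in sub.graph.nodes(data=True):
        if n not in query:
            assert d["origin"] == "stitched"


def test_custom_stitch_follows_mst_paths(master_net, master_circuits):
    """Path-kind stitched nodes lie on MST paths between query components."""
    comps = sorted(nx.connected_components(master_net.graph), key=len)
    big = sorted(max(comps, key=len))
    query = [big[0], big[-1]]
    sub = cn.custom_network(master_net, master_circuits, query)
    mst_g = master_net.mst_graph
    oracle = set(nx.shortest_path(mst_g, *query))
    path_nodes = {
        n for n, d in sub.graph.nodes(data=True)
        if d.get("stitch_kind") == "path"
    }
    assert path_nodes <= oracle


def test_custom_cap_eviction_never_drops_query(master_net, master_circuits):
    cfg = Config(custom_cap=10)
    comps = sorted(nx.connected_components(master_net.graph), key=len)
    big = sorted(max(comps, key=len))
    query = [big[0], big[len(big) // 2], big[-1]]
    sub = cn.custom_network(master_net, master_circuits, query, config=cfg)
    assert set(query) <= set(sub.graph.nodes)
    assert sub.graph.number_of_nodes() <= 10


def test_subnetwork_document_export(master_net, master_circuits):
    sub = cn.node_centric_network(
        master_net, master_circuits, sorted(master_net.graph.nodes)[0]
    )
    doc = sub.to_document()
    assert len(doc.nodes) == sub.graph.number_of_nodes()
    assert len(doc.edges) == sub.graph.number_of_edges()
    ids = {n.id for n in doc.nodes}
    assert all(e.source in ids and e.target in ids for e in doc.edges)
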