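"""Seeded synthetic data with planted ceRNA circuits.

Each planted circuit is driven by a latent per-sample driver z ~ N(0, 1):
the circuit's mRNA and lncRNA read out z positively and its miRNA reads out
-z, each plus independent Gaussian noise.  Because the link functions are
monotone, the *Spearman* targets hold regardless of marginal distributions.
Noise scales are calibrated through the bivariate-normal identity
rho_pearson = 2*sin(pi*rho_spearman/6): at ``noise_sd=1`` the planted pairs
hit the requested Spearman targets in expectation, and at ``noise_sd=0``
they are exactly +/-1.  All remaining genes are independent N(0, 1)
background, and distractor interactions connect uncorrelated genes so the
correlation gates reject them.

Fiber-type labels cycle through the six myofiber types purely as metadata —
the inference pipeline never stratifies by them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .circuits import Circuit, GatedRelation
from .correlation import CorrelationRecord
from .model_io import (
    CatalogEntry,
    ClusterSet,
    ExpressionMatrix,
    FIBER_TYPES,
    GeneCatalog,
    InteractionRecord,
    PathwayTopology,
    write_catalog,
    write_clusters,
    write_expression,
    write_interactions,
    write_pathways,
)


@dataclass
class FixtureSpec:
    """Study conditions for one simulated dataset.

    ``n_samples=60`` mirrors ten biological replicates for each of the six
    myofiber types.  ``rho_pos``/``rho_neg`` are the target Spearman
    correlations of planted sponge pairs and miRNA-target pairs; the gate
    thresholds (0.45 / -0.35) sit well inside them so planted circuits are
    recoverable while distractors (built on independent genes) are not.
    """

    n_mrna: int = 40
    n_lncrna: int = 20
    n_mirna: int = 15
    n_samples: int = 60
    n_planted_circuits: int = 8
    rho_pos: float = 0.8
    rho_neg: float = -0.7
    noise_sd: float = 1.0
    frac_validated: float = 0.5
    n_distractor_edges: int = 20
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_mirna", "n_samples", "n_planted_circuits"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.rho_pos < 1) or not (-1 < self.rho_neg < 0):
            raise ValueError("need 0 < rho_pos < 1 and -1 < rho_neg < 0")
        if not (0.0 <= self.frac_validated <= 1.0):
            raise ValueError("frac_validated must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PlantedCircuit:
    mrna_id: str
    lncrna_id: str
    mirna_id: str
    evidence: str


@dataclass
class SimulatedDataset:
    expression: ExpressionMatrix
    catalog: GeneCatalog
    interactions: list[InteractionRecord]
    truth: list[PlantedCircuit]
    clusters: ClusterSet | None = None


def _noise_scales(rho_pos: float, rho_neg: float) -> tuple[float, float]:
    """Per-gene noise SDs hitting the Spearman targets at noise_sd=1."""
    rp = 2.0 * math.sin(math.pi * rho_pos / 6.0)  # Pearson equivalent
    rn = 2.0 * math.sin(math.pi * abs(rho_neg) / 6.0)
    s_pos = math.sqrt(1.0 / rp - 1.0)
    inner = 1.0 / (rn * rn * (1.0 + s_pos * s_pos)) - 1.0
    if inner < 0:
        raise ValueError(
            "infeasible targets: |rho_neg| too large relative to rho_pos"
        )
    return s_pos, math.sqrt(inner)


def simulate_dataset(spec: FixtureSpec) -> SimulatedDataset:
    """Simulate expression, catalog, interactions and the planted truth."""
    k = spec.n_planted_circuits
    if k > min(spec.n_mrna, spec.n_lncrna, spec.n_mirna):
        raise ValueError(
            f"cannot plant {k} circuits with only "
            f"{spec.n_mrna}/{spec.n_lncrna}/{spec.n_mirna} genes per class"
        )
    rng = np.random.default_rng(spec.seed)
    mrnas = [f"mRNA_{i:03d}" for i in range(spec.n_mrna)]
    lncrnas = [f"lnc_{i:03d}" for i in range(spec.n_lncrna)]
    mirnas = [f"miR_{i:03d}" for i in range(spec.n_mirna)]
    catalog = GeneCatalog(
        {g: CatalogEntry("mRNA", g) for g in mrnas}
        | {g: CatalogEntry("lncRNA", g) for g in lncrnas}
        | {g: CatalogEntry("miRNA", g) for g in mirnas}
    )

    s_pos, s_neg = _noise_scales(spec.rho_pos, spec.rho_neg)
    n = spec.n_samples
    values = pd.DataFrame(
        rng.normal(size=(len(catalog), n)),
        index=mrnas + lncrnas + mirnas,
        columns=[f"S{j:03d}" for j in range(n)],
    )
    truth: list[PlantedCircuit] = []
    interactions: list[InteractionRecord] = []
    n_validated = round(spec.frac_validated * k)
    for j in range(k):
        z = rng.normal(size=n)
        values.loc[mrnas[j]] = z + spec.noise_sd * s_pos * rng.normal(size=n)
        values.loc[lncrnas[j]] = z + spec.noise_sd * s_pos * rng.normal(size=n)
        values.loc[mirnas[j]] = -z + spec.noise_sd * s_neg * rng.normal(size=n)
        evidence = "validated" if j < n_validated else "predicted"
        source = "hitsclip-synth" if evidence == "validated" else "seedmatch-synth"
        truth.append(PlantedCircuit(mrnas[j], lncrnas[j], mirnas[j], evidence))
        interactions.append(InteractionRecord(mirnas[j], mrnas[j], "mRNA", evidence, source))
        interactions.append(InteractionRecord(mirnas[j], lncrnas[j], "lncRNA", evidence, source))

    # distractor interactions between independent background genes
    bg_mirnas = mirnas[k:] or mirnas
    bg_mrnas = mrnas[k:] or mrnas
    bg_lncrnas = lncrnas[k:] or lncrnas
    seen = {(r.mirna_id, r.target_id) for r in interactions}
    for d in range(spec.n_distractor_edges):
        for _attempt in range(100):
            mirna = bg_mirnas[int(rng.integers(len(bg_mirnas)))]
            if d % 2 == 0:
                target, t_class = bg_mrnas[int(rng.integers(len(bg_mrnas)))], "mRNA"
            else:
                target, t_class = bg_lncrnas[int(rng.integers(len(bg_lncrnas)))], "lncRNA"
            if (mirna, target) not in seen:
                seen.add((mirna, target))
                evidence = "validated" if rng.random() < spec.frac_validated else "predicted"
                interactions.append(
                    InteractionRecord(mirna, target, t_class, evidence, "distractor-synth")
                )
                break

    labels = {
        sample: FIBER_TYPES[j % len(FIBER_TYPES)]
        for j, sample in enumerate(values.columns)
    }
    expr = ExpressionMatrix(values=values, sample_labels=labels)
    clusters = make_cluster_set(truth)
    return SimulatedDataset(
        expression=expr, catalog=catalog, interactions=interactions,
        truth=truth, clusters=clusters,
    )


def make_cluster_set(
    truth: list[PlantedCircuit],
    n_clusters: int = 2,
    subgroups: tuple[str, ...] = ("WT", "DEx51"),
) -> ClusterSet:
    """Marker-gene clusters built from planted circuits (round-robin split)."""
    clusters: dict[str, list[str]] = {}
    subgroup: dict[str, str] = {}
    for idx in range(n_clusters):
        genes: list[str] = []
        for j, pc in enumerate(truth):
            if j % n_clusters == idx:
                genes.extend([pc.mrna_id, pc.lncrna_id, pc.mirna_id])
        name = f"nuclei_{idx}"
        if genes:
            clusters[name] = genes
            subgroup[name] = subgroups[idx % len(subgroups)]
    return ClusterSet(clusters=clusters, subgroup=subgroup)


# ---------------------------------------------------------------------------
# Direct circuit-list simulation for master/subnet tests
# ---------------------------------------------------------------------------

def simulate_master(
    n_per_class: int,
    edge_density: float = 0.02,
    frac_validated: float = 0.3,
    seed: int = 0,
    n_blocks: int = 1,
) -> list[Circuit]:
    """Random circuit list with controllable component structure.

    Genes of each class are split round-robin into ``n_blocks`` groups and
    circuits are sampled within a block only, so the resulting master
    network has (at least) ``n_blocks`` connected components.  Correlation
    statistics are synthetic draws respecting the gate constraints.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    blocks: list[tuple[list[str], list[str], list[str]]] = []
    for b in range(n_blocks):
        blocks.append((
            [f"mRNA_{i:03d}" for i in range(n_per_class) if i % n_blocks == b],
            [f"lnc_{i:03d}" for i in range(n_per_class) if i % n_blocks == b],
            [f"miR_{i:03d}" for i in range(n_per_class) if i % n_blocks == b],
        ))
    def _make_circuit(key: tuple[str, str, str]) -> Circuit:
        m, l, i = key
        evidence = "validated" if rng.random() < frac_validated else "predicted"
        source = "hitsclip-synth" if evidence == "validated" else "seedmatch-synth"
        def p() -> float:
            return float(rng.uniform(1.0 / 1001.0, 0.05))
        return Circuit(
            mrna_id=m, lncrna_id=l, mirna_id=i,
            edge_mm=GatedRelation(i, m, "mRNA", evidence, source,
                                  float(rng.uniform(-0.95, -0.36)), p()),
            edge_ml=GatedRelation(i, l, "lncRNA", evidence, source,
                                  float(rng.uniform(-0.95, -0.36)), p()),
            edge_cl=CorrelationRecord(m, l, "mrna-lncrna",
                                      float(rng.uniform(0.45, 0.95)), p(), True),
        )

    circuits: list[Circuit] = []
    seen: set[tuple[str, str, str]] = set()
    for ms, ls, is_ in blocks:
        if not (ms and ls and is_):
            raise ValueError("n_blocks too large for n_per_class")
        total = len(ms) * len(ls) * len(is_)
        want = max(1, int(round(edge_density * total)))
        block_circuits: list[Circuit] = []
        for _ in range(want * 20):
            if want == 0:
                break
            key = (
                ms[int(rng.integers(len(ms)))],
                ls[int(rng.integers(len(ls)))],
                is_[int(rng.integers(len(is_)))],
            )
            if key in seen:
                continue
            seen.add(key)
            want -= 1
            block_circuits.append(_make_circuit(key))
        # connect the block internally so component count == n_blocks exactly
        while True:
            g = nx.Graph()
            for c in block_circuits:
                g.add_edge(c.mrna_id, c.lncrna_id)
                g.add_edge(c.mirna_id, c.mrna_id)
            comps = sorted(nx.connected_components(g), key=min)
            if len(comps) <= 1:
                break
            c1, c2 = comps[0], comps[1]
            m = min(n for n in c1 if n.startswith("mRNA"))
            l = min(n for n in c2 if n.startswith("lnc"))
            i = min(n for n in (c1 | c2) if n.startswith("miR"))
            key = (m, l, i)
            if key in seen:  # pragma: no cover - connector collision
                key = (min((n for n in c2 if n.startswith("mRNA")), default=m), l, i)
            seen.add(key)
            block_circuits.append(_make_circuit(key))
        circuits.extend(block_circuits)
    circuits.sort(key=lambda c: c.key)
    return circuits


def make_toy_pathways(
    n_pathways: int = 5,
    sizes: list[int] | int = 12,
    overlap_fraction: float = 0.0,
    seed: int = 0,
) -> list[PathwayTopology]:
    """Toy pathway topologies with a controlled overlap between neighbors.

    Consecutive pathways share ``round(overlap_fraction * size)`` genes;
    with ``overlap_fraction=0`` all pathways are pairwise disjoint.  Edges
    chain the member genes (relation ``activation``).
    """
    if isinstance(sizes, int):
        sizes = [sizes] * n_pathways
    if len(sizes) != n_pathways:
        raise ValueError("sizes must have one entry per pathway")
    pathways: list[PathwayTopology] = []
    counter = 0
    prev_genes: list[str] = []
    for p_idx, size in enumerate(sizes):
        n_shared = min(round(overlap_fraction * size), len(prev_genes))
        genes = prev_genes[:n_shared]
        while len(genes) < size:
            genes.append(f"PWG_{counter:04d}")
            counter += 1
        edges = [
            (genes[e], genes[e + 1], "activation") for e in range(len(genes) - 1)
        ]
        pathways.append(
            PathwayTopology(
                pathway_id=f"path{p_idx:02d}",
                title=f"Toy pathway {p_idx}",
                node_ids=list(genes),
                edges=edges,
            )
        )
        prev_genes = list(genes)
    return pathways


def write_fixture_dir(dataset: SimulatedDataset, out_dir: str | Path) -> None:
    """Emit every input file format consumed by the readers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(dataset.expression, out / "expression.tsv", out / "labels.tsv")
    write_catalog(dataset.catalog, out / "catalog.tsv")
    write_interactions(dataset.interactions, out / "interactions.tsv")
    if dataset.clusters is not None:
        write_clusters(dataset.clusters, out / "clusters.gmt", out / "subgroups.tsv")
    pathways = make_toy_pathways()
    write_pathways(pathways, out / "pathway_nodes.tsv", out / "pathway_edges.tsv")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("mrna\tlncrna\tmirna\tevidence\n")
        for pc in dataset.truth:
            fh.write(f"{pc.mrna_id}\t{pc.lncrna_id}\t{pc.mirna_id}\t{pc.evidence}\n")
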