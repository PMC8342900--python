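"""Correlation gating of database interactions and circuit enumeration.

A *functional circuit* is the minimal ceRNA motif: one mRNA, one lncRNA and
one miRNA, where the miRNA anti-correlates with both of its database-supported
targets and the mRNA and lncRNA co-vary positively.  Enumeration is an
index join — hash the retained mRNA-lncRNA pairs, then walk each miRNA's
gated adjacency — whose output contract is identical to the cubic brute
force over all (mRNA, lncRNA, miRNA) triples.
"""

from __future__ import annotations

from dataclasses import dataclass

from .correlation import CorrelationRecord
from .model_io import ClusterSet, InteractionRecord, logger


@dataclass(frozen=True)
class GatedRelation:
    """A database interaction that passed the anticorrelation gate."""

    mirna_id: str
    target_id: str
    target_class: str
    evidence: str
    source_db: str
    rho: float
    p_emp: float


@dataclass(frozen=True)
class Circuit:
    mrna_id: str
    lncrna_id: str
    mirna_id: str
    edge_mm: GatedRelation  # miRNA - mRNA
    edge_ml: GatedRelation  # miRNA - lncRNA
    edge_cl: CorrelationRecord  # mRNA - lncRNA

    @property
    def evidence(self) -> str:
        """'validated' only when both interaction edges are validated."""
        if self.edge_mm.evidence == "validated" and self.edge_ml.evidence == "validated":
            return "validated"
        return "predicted"

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.mrna_id, self.lncrna_id, self.mirna_id)

    @property
    def members(self) -> tuple[str, str, str]:
        return (self.mrna_id, self.lncrna_id, self.mirna_id)


def gate_interactions(
    records: list[InteractionRecord],
    corr: list[CorrelationRecord],
) -> list[GatedRelation]:
    """Keep interactions whose (miRNA, target) pair has a retained
    anticorrelation record, annotating each with rho and the empirical p.

    Interactions without any correlation record (e.g. a gene absent from the
    expression data) are dropped and counted.
    """
    retained = {
        (r.id_a, r.id_b): r
        for r in corr
        if r.retained and r.pair_class in ("mirna-mrna", "mirna-lncrna")
    }
    gated: list[GatedRelation] = []
    dropped = 0
    for rec in records:
        hit = retained.get((rec.mirna_id, rec.target_id))
        if hit is None:
            dropped += 1
            continue
        gated.append(
            GatedRelation(
                mirna_id=rec.mirna_id,
                target_id=rec.target_id,
                target_class=rec.target_class,
                evidence=rec.evidence,
                source_db=rec.source_db,
                rho=hit.rho,
                p_emp=hit.p_emp,
            )
        )
    if dropped:
        logger.info("gating dropped %d interactions without a retained anticorrelation", dropped)
    return gated


def enumerate_circuits(
    gated_mm: list[GatedRelation],
    gated_ml: list[GatedRelation],
    retained_cl: list[CorrelationRecord],
) -> list[Circuit]:
    """Enumerate every (mRNA, lncRNA, miRNA) triple supported by all three gates.

    Output is sorted by (mrna, lncrna, mirna) and duplicate-free.  When
    several gated relations exist for the same (miRNA, target) pair (one
    validated and one predicted), the validated one is used.
    """
    def _index(relations: list[GatedRelation]) -> dict[str, dict[str, GatedRelation]]:
        by_mirna: dict[str, dict[str, GatedRelation]] = {}
        for rel in relations:
            slot = by_mirna.setdefault(rel.mirna_id, {})
            prev = slot.get(rel.target_id)
            if prev is None or (prev.evidence == "predicted" and rel.evidence == "validated"):
                slot[rel.target_id] = rel
        return by_mirna

    mm = _index(gated_mm)
    ml = _index(gated_ml)
    cl_pairs = {
        (r.id_a, r.id_b): r
        for r in retained_cl
        if r.retained and r.pair_class == "mrna-lncrna"
    }
    circuits: list[Circuit] = []
    for mirna in sorted(set(mm) & set(ml)):
        for mrna, rel_mm in sorted(mm[mirna].items()):
            for lncrna, rel_ml in sorted(ml[mirna].items()):
                rec_cl = cl_pairs.get((mrna, lncrna))
                if rec_cl is None:
                    continue
                circuits.append(
                    Circuit(
                        mrna_id=mrna, lncrna_id=lncrna, mirna_id=mirna,
                        edge_mm=rel_mm, edge_ml=rel_ml, edge_cl=rec_cl,
                    )
                )
    circuits.sort(key=lambda c: c.key)
    return circuits


def filter_circuits_by_cluster(
    circuits: list[Circuit],
    cluster: list[str] | set[str],
    require: str = "any",
) -> list[Circuit]:
    """Circuits overlapping a marker-gene set.

    ``require='any'`` keeps a circuit when at least one of its three members
    is in the cluster; ``require='mrna'`` demands the mRNA specifically.
    """
    if require not in ("any", "mrna"):
        raise ValueError("require must be 'any' or 'mrna'")
    genes = set(cluster)
    if not genes:
        logger.warning("empty cluster gene list; no circuits retained")
        return []
    if require == "mrna":
        return [c for c in circuits if c.mrna_id in genes]
    return [c for c in circuits if genes.intersection(c.members)]


def filter_circuits_by_clusterset(
    circuits: list[Circuit],
    clusters: ClusterSet,
    require: str = "any",
) -> dict[tuple[str, str | None], list[Circuit]]:
    """Per-cluster circuit filters, keyed by (cluster name, subgroup label).

    When the cluster set defines subgroups (e.g. WT vs DEx51 nuclei) the
    per-subgroup circuit lists are kept separate and never merged.
    """
    out: dict[tuple[str, str | None], list[Circuit]] = {}
    for name, genes in clusters.clusters.items():
        label = clusters.subgroup[name] if clusters.subgroup else None
        out[(name, label)] = filter_circuits_by_cluster(circuits, genes, require=require)
    return out


def discover_circuits(
    expr,
    catalog,
    interactions: list[InteractionRecord],
    config=None,
    n_perm: int | None = None,
    seed: int | None = None,
):
    """End-to-end circuit discovery: correlate, gate, enumerate.

    Runs the three pair-class correlation screens (seeded deterministically
    from ``seed``), gates the interaction tables, and enumerates circuits.
    Returns (circuits, correlations) where correlations maps pair class to
    its record list.
    """
    from .correlation import correlate_pairs

    seeds = {pc: (None if seed is None else seed + off) for off, pc in
             enumerate(("mrna-lncrna", "mirna-mrna", "mirna-lncrna"))}
    corr = {
        pc: correlate_pairs(expr, catalog, pc, config=config, n_perm=n_perm, seed=s)
        for pc, s in seeds.items()
    }
    gated_mm = gate_interactions(
        [r for r in interactions if r.target_class == "mRNA"], corr["mirna-mrna"]
    )
    gated_ml = gate_interactions(
        [r for r in interactions if r.target_class == "lncRNA"], corr["mirna-lncrna"]
    )
    circuits = enumerate_circuits(gated_mm, gated_ml, corr["mrna-lncrna"])
    return circuits, corr


_CIRCUIT_COLS = (
    "mrna\tlncrna\tmirna\trho_mm\tp_mm\tev_mm\tsrc_mm"
    "\trho_ml\tp_ml\tev_ml\tsrc_ml\trho_cl\tp_cl\tevidence"
)


def write_circuits(circuits: list[Circuit], path) -> None:
    """Circuit TSV with full edge provenance, round-trippable by read_circuits."""
    with open(path, "w") as fh:
        fh.write(_CIRCUIT_COLS + "\n")
        for c in circuits:
            fh.write(
                f"{c.mrna_id}\t{c.lncrna_id}\t{c.mirna_id}"
                f"\t{c.edge_mm.rho!r}\t{c.edge_mm.p_emp!r}\t{c.edge_mm.evidence}\t{c.edge_mm.source_db}"
                f"\t{c.edge_ml.rho!r}\t{c.edge_ml.p_emp!r}\t{c.edge_ml.evidence}\t{c.edge_ml.source_db}"
                f"\t{c.edge_cl.rho!r}\t{c.edge_cl.p_emp!r}\t{c.evidence}\n"
            )


def read_circuits(path) -> list[Circuit]:
    circuits: list[Circuit] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _CIRCUIT_COLS:
            raise ValueError(f"{path}: unexpected circuit header")
        for raw in fh:
            if not raw.strip():
                continue
            (m, l, i, rho_mm, p_mm, ev_mm, src_mm, rho_ml, p_ml, ev_ml, src_ml,
             rho_cl, p_cl, _ev) = raw.rstrip("\n").split("\t")
            circuits.append(
                Circuit(
                    mrna_id=m, lncrna_id=l, mirna_id=i,
                    edge_mm=GatedRelation(i, m, "mRNA", ev_mm, src_mm, float(rho_mm), float(p_mm)),
                    edge_ml=GatedRelation(i, l, "lncRNA", ev_ml, src_ml, float(rho_ml), float(p_ml)),
                    edge_cl=CorrelationRecord(m, l, "mrna-lncrna", float(rho_cl), float(p_cl), True),
                )
            )
    return circuits
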