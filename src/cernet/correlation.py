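"""Spearman correlation between RNA classes with permutation p-values.

Pairs are screened with class-specific thresholds: putative sponge partners
(mRNA-lncRNA) must co-vary positively (rho >= 0.45, inclusive), while a
miRNA and its putative target must anti-correlate (rho < -0.35, strict).
Statistical significance of retained pairs is assessed with a one-sided
permutation test in the direction the class filter requires; the empirical
p-value uses add-one smoothing, (b + 1) / (n_perm + 1), so it is never zero
(it later becomes the edge weight ``w`` and must stay in (0, 1]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model_io import Config, ExpressionMatrix, GeneCatalog, logger

#: supported pair classes, named "<classA>-<classB>"; correlate_pairs emits
#: records with id_a from the first class and id_b from the second.
PAIR_CLASSES = ("mrna-lncrna", "mirna-mrna", "mirna-lncrna")

_CLASS_OF = {
    "mrna-lncrna": ("mRNA", "lncRNA"),
    "mirna-mrna": ("miRNA", "mRNA"),
    "mirna-lncrna": ("miRNA", "lncRNA"),
}


@dataclass(frozen=True)
class CorrelationRecord:
    id_a: str
    id_b: str
    pair_class: str
    rho: float
    p_emp: float  # NaN when the permutation test was not run (pair not retained)
    retained: bool


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation; NaN sentinel when not computable.

    Computed as the Pearson correlation of average (fractional) ranks.  A
    constant vector has zero rank variance, making the coefficient undefined;
    such pairs are excluded upstream rather than treated as zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        return math.nan
    return float(((rx - rx.mean()) @ (ry - ry.mean())) / (x.size * sx * sy))


def permutation_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    direction: str = "positive",
) -> float:
    """One-sided empirical p-value for spearman(x, y) under permutation.

    Only ``y`` is permuted (equivalent in distribution to permuting both).
    p = (1 + #{rho_perm at least as extreme as observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if direction not in ("positive", "negative"):
        raise ValueError(f"direction must be 'positive' or 'negative', got {direction!r}")
    observed = spearman(x, y)
    if math.isnan(observed):
        raise ValueError("correlation not computable (constant vector)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rx = stats.rankdata(np.asarray(x, dtype=float))
    ry = stats.rankdata(np.asarray(y, dtype=float))
    n = rx.size
    rx_c = (rx - rx.mean()) / (rx.std() * n)
    ry_c = ry - ry.mean()
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    rho_perm = (ry_c[perms] @ rx_c) / ry_c.std()  # std invariant under permutation
    if direction == "positive":
        hits = int(np.sum(rho_perm >= observed - 1e-12))
    else:
        hits = int(np.sum(rho_perm <= observed + 1e-12))
    return (1 + hits) / (n_perm + 1)


def is_retained(pair_class: str, rho: float, config: Config | None = None) -> bool:
    """Class-specific retention rule.

    mRNA-lncRNA pairs: rho >= 0.45 (inclusive).  miRNA-mRNA and
    miRNA-lncRNA pairs: rho strictly below -0.35.
    """
    cfg = config or Config()
    if pair_class not in PAIR_CLASSES:
        raise ValueError(f"pair_class must be one of {PAIR_CLASSES}")
    if pair_class == "mrna-lncrna":
        return rho >= cfg.rho_min_pos
    return rho < cfg.rho_max_neg


def correlate_pairs(
    expr: ExpressionMatrix,
    catalog: GeneCatalog,
    pair_class: str,
    config: Config | None = None,
    n_perm: int | None = None,
    seed: int | None = None,
) -> list[CorrelationRecord]:
    """All-pairs Spearman between the two RNA classes of ``pair_class``.

    Retention is decided by the class threshold alone; the permutation test
    (direction matched to the sign requirement) runs only for retained pairs.
    Pairs with non-computable correlation are excluded.  Deterministic given
    ``seed``: pairs are processed in sorted gene-id order.
    """
    if pair_class not in PAIR_CLASSES:
        raise ValueError(f"pair_class must be one of {PAIR_CLASSES}")
    cfg = config or Config()
    if n_perm is None:
        n_perm = cfg.n_perm
    class_a, class_b = _CLASS_OF[pair_class]
    present = set(expr.gene_ids)
    ids_a = sorted(g for g in catalog.ids_of_class(class_a) if g in present)
    ids_b = sorted(g for g in catalog.ids_of_class(class_b) if g in present)
    if not ids_a or not ids_b:
        logger.warning("pair class %s: one side empty, no correlations", pair_class)
        return []

    # all-pairs Spearman as a rank-matrix product
    def _rank_rows(ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        vals = expr.values.loc[ids].to_numpy(dtype=float)
        ranks = np.apply_along_axis(stats.rankdata, 1, vals)
        centered = ranks - ranks.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        return centered, norms

    ra, na = _rank_rows(ids_a)
    rb, nb = _rank_rows(ids_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho_mat = (ra @ rb.T) / np.outer(na, nb)

    rng = np.random.default_rng(seed)
    direction = "positive" if pair_class == "mrna-lncrna" else "negative"
    records: list[CorrelationRecord] = []
    for i, ga in enumerate(ids_a):
        for j, gb in enumerate(ids_b):
            rho = float(rho_mat[i, j])
            if math.isnan(rho):  # constant vector on either side
                continue
            keep = is_retained(pair_class, rho, cfg)
            p_emp = math.nan
            if keep:
                p_emp = permutation_pvalue(
                    expr.values.loc[ga].to_numpy(),
                    expr.values.loc[gb].to_numpy(),
                    n_perm=n_perm,
                    seed=rng,
                    direction=direction,
                )
            records.append(
                CorrelationRecord(
                    id_a=ga, id_b=gb, pair_class=pair_class,
                    rho=rho, p_emp=p_emp, retained=keep,
                )
            )
    return records


def write_correlations(records: list[CorrelationRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tpair_class\trho\tp_emp\tretained\n")
        for r in records:
            fh.write(
                f"{r.id_a}\t{r.id_b}\t{r.pair_class}\t{r.rho!r}\t{r.p_emp!r}"
                f"\t{int(r.retained)}\n"
            )


def read_correlations(path) -> list[CorrelationRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id_a"):
            raise ValueError(f"{path}: missing correlation header")
        for raw in fh:
            if not raw.strip():
                continue
            a, b, pc, rho, p, kept = raw.rstrip("\n").split("\t")
            records.append(
                CorrelationRecord(a, b, pc, float(rho), float(p), bool(int(kept)))
            )
    return records
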