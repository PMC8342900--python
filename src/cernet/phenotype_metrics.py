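"""Mitochondrial fragmentation index from per-fragment volume lists.

Each mitochondrial fragment's volume share is V_S = 100 * v_i / sum(v);
the fragmentation index is the fraction of fragments whose share is at
most the cutoff (20% by default, inclusive).  A perfectly fused network
(one or few large fragments) scores 0; a highly fragmented one approaches
1.  The statistic is unit-free: any consistent volume unit works.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


def fragmentation_index(volumes: Sequence[float], share_cutoff: float = 20.0) -> float:
    """Fraction of fragments with volume share <= ``share_cutoff`` percent."""
    v = np.asarray(list(volumes), dtype=float)
    if v.size == 0:
        raise ValueError("need at least one fragment volume")
    if not np.isfinite(v).all() or (v <= 0).any():
        raise ValueError("fragment volumes must be positive and finite")
    shares = 100.0 * v / v.sum()
    return float(np.count_nonzero(shares <= share_cutoff) / v.size)


def read_volumes(path) -> list[list[float]]:
    """Read per-cell fragment volumes: one column per cell, or one per line.

    Lines with a single value and no header are treated as one cell; a
    multi-column TSV yields one volume list per column (blank cells allowed).
    """
    rows = []
    for raw in open(path):
        if not raw.strip():
            continue
        rows.append(raw.rstrip("\n").split("\t"))
    if not rows:
        raise ValueError(f"{path}: empty volume table")
    n_cols = max(len(r) for r in rows)
    cells: list[list[float]] = [[] for _ in range(n_cols)]
    for r in rows:
        for j, cell in enumerate(r):
            if cell.strip():
                cells[j].append(float(cell))
    return [c for c in cells if c]
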