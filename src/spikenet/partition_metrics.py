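"""Agreement between functional modules and anatomical areas.

A module partition (node -> module id, with -1 meaning "unassigned" after the
minimum-module-size filter) is compared with the areal labelling through a
contingency table n_ij = |M_i ∩ A_j|. From it we derive

* per-module coverage  max_j n_ij / |A_j|  — how fully the module covers its
  best-matching area,
* per-module purity    max_j n_ij / |M_i|  — how exclusively the module draws
  from one area,
* their module-size-weighted averages (network-level summaries), and
* the pair-counting Adjusted Rand Index between the two partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb

__all__ = [
    "contingency_table",
    "coverage_purity",
    "CoveragePurity",
    "adjusted_rand_index",
]

UNASSIGNED = -1


def _aligned(modules, areas) -> tuple[pd.Series, pd.Series]:
    modules = pd.Series(modules)
    areas = pd.Series(areas)
    if not modules.index.equals(areas.index):
        areas = areas.reindex(modules.index)
        if areas.isna().any():
            raise ValueError("every node needs an area label")
    return modules, areas


def contingency_table(
    modules, areas, include_unassigned: bool = False
) -> pd.DataFrame:
    """Contingency table n_ij (rows: modules, columns: areas).

    Nodes with module id -1 (filtered out by the minimum-size rule) are
    dropped by default; with ``include_unassigned=True`` each becomes its own
    singleton module (sensitivity-analysis mode).
    """
    modules, areas = _aligned(modules, areas)
    if include_unassigned:
        modules = modules.copy()
        mask = modules == UNASSIGNED
        if mask.any():
            start = modules.max() + 1
            modules.loc[mask] = np.arange(start, start + mask.sum())
    else:
        keep = modules != UNASSIGNED
        modules, areas = modules[keep], areas[keep]
    if modules.empty:
        raise ValueError("no assigned nodes to tabulate")
    return pd.crosstab(modules, areas)


@dataclass(frozen=True)
class CoveragePurity:
    per_module: pd.DataFrame  # size, coverage, purity, best_area per module
    wa_coverage: float
    wa_purity: float


def coverage_purity(modules, areas, include_unassigned: bool = False) -> CoveragePurity:
    """Per-module coverage/purity and their size-weighted averages."""
    table = contingency_table(modules, areas, include_unassigned)
    n = table.to_numpy(dtype=float)
    sizes = n.sum(axis=1)
    area_sizes = n.sum(axis=0)
    coverage = (n / area_sizes[None, :]).max(axis=1)
    purity = n.max(axis=1) / sizes
    best_area = table.columns.to_numpy()[np.argmax(n / area_sizes[None, :], axis=1)]
    per_module = pd.DataFrame(
        {
            "size": sizes.astype(int),
            "coverage": coverage,
            "purity": purity,
            "best_area": best_area,
        },
        index=table.index,
    )
    wa_cov = float(np.sum(sizes * coverage) / sizes.sum())
    wa_pur = float(np.sum(n.max(axis=1)) / sizes.sum())
    return CoveragePurity(per_module=per_module, wa_coverage=wa_cov, wa_purity=wa_pur)


def adjusted_rand_index(table: pd.DataFrame | np.ndarray) -> float:
    """Adjusted Rand Index from a contingency table (pair-counting form).

    Equals 1 iff the two partitions coincide up to relabelling; returns NaN
    when the chance-correction denominator vanishes (e.g. both partitions
    all-singleton or the table is a single cell), which is reported as
    undefined rather than forced to a value.
    """
    n_ij = np.asarray(table, dtype=np.int64)
    n = int(n_ij.sum())
    if n < 2:
        raise ValueError("need at least 2 classified nodes")
    a = n_ij.sum(axis=1)
    b = n_ij.sum(axis=0)
    sum_ij = comb(n_ij, 2).sum()
    sum_a = comb(a, 2).sum()
    sum_b = comb(b, 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0.0:
        return float("nan")
    return float((sum_ij - expected) / denom)
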