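"""Single-cell library quality control.

Low-quality libraries show two symptoms: low complexity (few genes carry
most reads, measured by the Gini-Simpson diversity of the gene proportion
vector) and low coverage (many genes seen exactly once, measured by the
Good-Turing coverage estimate). Cells whose expression is *more uniform*
than a clean reference — an excess "background" fraction spread thinly
across the transcriptome — are filtered with a one-sided Lorenz-curve
statistic: the maximum vertical excess of the cell's Lorenz curve over the
pooled reference curve, with an empirical rank p-value among reference
cells and Benjamini-Hochberg control across the cells under test.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .stats import bh_adjust, empirical_pvalues_1d

__all__ = ["qc_metrics", "lorenz_filter", "lorenz_statistic"]

MIN_REFERENCE_CELLS = 10


def gini_simpson(counts: np.ndarray) -> float:
    """1 - sum p_i^2 over gene proportions; 0 for a single-gene library."""
    total = counts.sum()
    if total == 0:
        return np.nan
    p = counts / total
    return 1.0 - float(np.sum(p * p))


def good_turing_coverage(counts: np.ndarray) -> float:
    """1 - (#genes with count 1) / library size."""
    total = counts.sum()
    if total == 0:
        return np.nan
    singletons = int(np.sum(counts == 1))
    return 1.0 - singletons / total


def qc_metrics(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-cell diversity and coverage metrics from raw counts.

    Zero-library cells get NaN metrics (undefined, reported as missing).
    """
    if m.norm_state != "raw":
        raise ValueError("qc_metrics needs raw counts")
    rows = []
    for j, cell in enumerate(m.cells):
        c = m.values[:, j]
        rows.append(
            {
                "cell": cell,
                "library_size": float(c.sum()),
                "gini_simpson": gini_simpson(c),
                "good_turing_coverage": good_turing_coverage(c),
            }
        )
    return pd.DataFrame(rows).set_index("cell")


def _lorenz_curve(counts: np.ndarray) -> np.ndarray:
    """Cumulative expression share at gene fractions k/G, genes sorted
    ascending. Length G+1, from 0 to 1."""
    total = counts.sum()
    shares = np.sort(np.asarray(counts, dtype=float)) / total
    return np.concatenate([[0.0], np.cumsum(shares)])


def lorenz_statistic(cell_counts: np.ndarray, reference_curve: np.ndarray) -> float:
    """sup_k (L_cell(k) - L_ref(k)): one-sided deviation toward uniformity.

    A cell identical in shape to the reference scores 0; a perfectly uniform
    cell against a concentrated reference scores the maximum.
    """
    curve = _lorenz_curve(cell_counts)
    if curve.size != reference_curve.size:
        raise ValueError("cell and reference must share the gene universe")
    return float(np.max(curve - reference_curve))


def lorenz_filter(
    m: ExpressionMatrix,
    reference: Optional[ExpressionMatrix] = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Flag cells with a significantly high background fraction.

    The reference profile is the pooled (summed) counts of the reference
    matrix (or of `m` itself). Each cell's statistic is ranked against the
    per-cell statistics of the reference cells (add-one empirical p, upper
    tail), BH-adjusted across the tested cells; a cell fails when q <
    q_threshold.
    """
    ref = reference if reference is not None else m
    if ref.n_cells < MIN_REFERENCE_CELLS:
        raise ValueError(
            f"need >= {MIN_REFERENCE_CELLS} reference cells, got {ref.n_cells}"
        )
    if not m.genes.equals(ref.genes):
        raise ValueError("test and reference matrices must share genes")
    pooled = ref.values.sum(axis=1)
    ref_curve = _lorenz_curve(pooled)
    ref_stats = np.array(
        [lorenz_statistic(ref.values[:, j], ref_curve) for j in range(ref.n_cells)]
    )
    stats = np.array(
        [lorenz_statistic(m.values[:, j], ref_curve) for j in range(m.n_cells)]
    )
    pvals = empirical_pvalues_1d(stats, ref_stats, tail="upper")
    qvals = bh_adjust(pvals)
    report = pd.DataFrame(
        {
            "lorenz_statistic": stats,
            "lorenz_p": pvals,
            "lorenz_q": qvals,
            "pass": qvals >= q_threshold,
        },
        index=m.cells,
    )
    report.index.name = "cell"
    return report
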