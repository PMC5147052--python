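"""Shared statistical primitives: BH adjustment and empirical tail p-values."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "empirical_pvalues_1d"]


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values), NaN-safe.

    NaN entries are ignored in the family and returned as NaN.
    """
    p = np.asarray(pvals, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = np.isfinite(p.ravel())
    if mask.any():
        _, qflat, _, _ = multipletests(p.ravel()[mask], method="fdr_bh")
        out = q.ravel()
        out[mask] = qflat
        q = out.reshape(p.shape)
    return q


def empirical_pvalues_1d(
    values: np.ndarray, reference: np.ndarray, tail: str
) -> np.ndarray:
    """Add-one empirical tail p-values of `values` against a reference sample.

    tail="lower": p = (1 + #{ref <= v}) / (n + 1)
    tail="upper": p = (1 + #{ref >= v}) / (n + 1)

    Ties are counted as "as or more extreme" (conservative). The add-one
    convention keeps p strictly positive so BH never sees a zero.
    """
    ref = np.sort(np.asarray(reference, dtype=float))
    n = ref.size
    v = np.asarray(values, dtype=float)
    if tail == "lower":
        counts = np.searchsorted(ref, v, side="right")
    elif tail == "upper":
        counts = n - np.searchsorted(ref, v, side="left")
    else:
        raise ValueError(f"tail must be 'lower' or 'upper', got {tail!r}")
    return (1.0 + counts) / (n + 1.0)
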