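"""Exon-level depletion test for in-frame intragenic deletions.

For one gene of interest (e.g. a receptor tyrosine kinase), each sample —
tumor or blood control — contributes a per-exon read-count profile. The
statistic per sample is the fraction of the gene's reads falling on a
target exon set (e.g. the dimerization-domain exons). Tumor samples are
tested against the blood-control distribution with a lower-tail add-one
empirical p-value, BH-corrected across tumors; an adjusted p below 0.25 is
significant. A fixed-threshold call (fraction below the controls' 10th
percentile) is reported alongside.

Cohort prevalence of the deletion is estimated by background-correcting
the fixed-threshold call rate: pi1 = (call rate - q) / (1 - q), where q is
the control quantile level — unbiased when depleted samples fall below the
threshold with near certainty. The raw BH-significant fraction is also
reported; it overcounts by design at a permissive FDR level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .stats import bh_adjust, empirical_pvalues_1d

__all__ = [
    "ExonCoverageProfile",
    "exon_fraction",
    "depletion_test",
    "estimate_prevalence",
    "cooccurrence_report",
]

MIN_CONTROLS = 10


@dataclass
class ExonCoverageProfile:
    """Per-exon read counts for one gene in one sample. Exons are numbered
    1..E in transcript order."""

    sample: str
    cohort: str  # tumor | control
    exon_counts: np.ndarray

    def __post_init__(self) -> None:
        self.exon_counts = np.asarray(self.exon_counts, dtype=float)
        if self.exon_counts.ndim != 1 or self.exon_counts.size < 2:
            raise ValueError("profile needs counts for at least 2 exons")
        if (self.exon_counts < 0).any():
            raise ValueError(f"negative exon count in sample {self.sample!r}")

    @property
    def n_exons(self) -> int:
        return self.exon_counts.size


def exon_fraction(
    profile: ExonCoverageProfile, target_exons: Sequence[int]
) -> Optional[float]:
    """Reads on the target exons as a fraction of all reads on the gene.

    Target exons are 1-based. Returns None (missing) for a zero-read
    profile — the sample cannot be assessed.
    """
    targets = sorted(set(int(e) for e in target_exons))
    if not targets:
        raise ValueError("target_exons must be non-empty")
    if any(not 1 <= e <= profile.n_exons for e in targets):
        raise ValueError("target exon index out of range")
    total = profile.exon_counts.sum()
    if total == 0:
        return None
    return float(profile.exon_counts[[e - 1 for e in targets]].sum() / total)


def depletion_test(
    tumors: Sequence[ExonCoverageProfile],
    controls: Sequence[ExonCoverageProfile],
    target_exons: Sequence[int],
    alpha: float = 0.25,
    control_quantile: float = 0.10,
    amplification: Optional[Set[str]] = None,
) -> pd.DataFrame:
    """Per-tumor depletion calls against the blood-control distribution.

    Returns one row per assessable tumor with the exon fraction, the
    lower-tail empirical p, the BH-adjusted p, the significance flag
    (adjusted p < alpha), and the fixed-threshold flag (fraction below the
    controls' `control_quantile`). Zero-read samples are excluded with a
    warning; fewer than 10 assessable controls is an error.
    """
    import warnings

    ctrl_fracs = []
    for p in controls:
        f = exon_fraction(p, target_exons)
        if f is None:
            warnings.warn(f"control {p.sample!r} has no reads; dropped")
        else:
            ctrl_fracs.append(f)
    if len(ctrl_fracs) < MIN_CONTROLS:
        raise ValueError(
            f"need >= {MIN_CONTROLS} assessable controls, got {len(ctrl_fracs)}"
        )
    ctrl_fracs = np.array(ctrl_fracs)
    threshold = float(np.quantile(ctrl_fracs, control_quantile))
    samples, fracs = [], []
    for p in tumors:
        f = exon_fraction(p, target_exons)
        if f is None:
            warnings.warn(f"tumor {p.sample!r} has no reads; excluded")
            continue
        samples.append(p.sample)
        fracs.append(f)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate tumor sample ids")
    fracs = np.array(fracs)
    pvals = empirical_pvalues_1d(fracs, ctrl_fracs, tail="lower")
    qvals = bh_adjust(pvals)
    amp = amplification or set()
    return pd.DataFrame(
        {
            "exon_fraction": fracs,
            "p": pvals,
            "q": qvals,
            "significant": qvals < alpha,
            "below_threshold": fracs < threshold,
            "amplified": [s in amp for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )


def estimate_prevalence(
    calls: pd.DataFrame, control_quantile: float = 0.10
) -> Dict[str, float]:
    """Cohort prevalence estimates of the deletion.

    "threshold_corrected" (the primary estimate) background-corrects the
    fixed-threshold call rate for the expected false-positive rate q of the
    control-quantile threshold; "bh_fraction" and "threshold_fraction" are
    the raw call rates.
    """
    n = len(calls)
    bh_rate = float(calls["significant"].mean()) if n else np.nan
    thr_rate = float(calls["below_threshold"].mean()) if n else np.nan
    corrected = max(0.0, (thr_rate - control_quantile) / (1.0 - control_quantile))
    return {
        "n": n,
        "bh_fraction": bh_rate,
        "threshold_fraction": thr_rate,
        "threshold_corrected": corrected,
    }


def cooccurrence_report(
    depletion_calls: Sequence[str],
    amplification_calls: Sequence[str],
    small_deletion_calls: Sequence[str],
    universe: Optional[Sequence[str]] = None,
) -> Dict[str, object]:
    """Three-way Venn counts of samples with exon depletion, gene
    amplification, and small in-frame deletions, with nesting flags."""
    sets = {}
    for name, ids in (
        ("depletion", depletion_calls),
        ("amplification", amplification_calls),
        ("small_deletion", small_deletion_calls),
    ):
        ids = list(ids)
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sample ids in {name} set")
        sets[name] = set(ids)
    if universe is not None:
        uni = set(universe)
        for name, s in sets.items():
            if not s <= uni:
                raise ValueError(f"{name} set contains ids outside the sample universe")
    d, a, s = sets["depletion"], sets["amplification"], sets["small_deletion"]
    report = {
        "depletion_only": len(d - a - s),
        "amplification_only": len(a - d - s),
        "small_deletion_only": len(s - d - a),
        "depletion_and_amplification": len((d & a) - s),
        "depletion_and_small_deletion": len((d & s) - a),
        "amplification_and_small_deletion": len((a & s) - d),
        "all_three": len(d & a & s),
        "small_deletions_nested_in_amplified": bool(s) and s <= a,
    }
    return report
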