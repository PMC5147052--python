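"""Per-cell CNV presence/absence genotyping from scRNA-seq expression.

Copy-number changes are reflected in RNA-seq read counts when averaged over
large genomic regions, so for each bulk-called CNV candidate region the
library-size-normalized (CPM) counts of its member genes are summed per
cell. The distribution of these region scores across CNV-free control cells
provides a null: each tumor cell gets a one-tailed add-one empirical
p-value in the direction of the CNV (upper tail for gains, lower for
losses), Benjamini-Hochberg corrected jointly over all cell x region tests;
a call is made when q < alpha (default 0.05, mirroring the 5% significance
level taken on the control distribution).

The classifier's false-call rate is estimated by 10-fold cross-validation
on the control cells alone: a reference is built from the 90% training
tranche, held-out control cells are genotyped, and the per-fold FDR is
(# positive calls) / (# tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import pywt
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .matrix import ExpressionMatrix
from .stats import bh_adjust, empirical_pvalues_1d
from .triage import CnvSegment

__all__ = [
    "RegionScoreMatrix",
    "ControlReference",
    "GenotypeMatrix",
    "region_label",
    "score_regions",
    "empirical_pvalues",
    "call_genotypes",
    "crossval_fdr",
    "wavelet_smooth_track",
    "flag_stromal",
]

MIN_CONTROL_CELLS = 10


def region_label(segment: CnvSegment) -> str:
    return f"{segment.chrom}:{segment.start}-{segment.end}:{segment.direction}"


@dataclass
class RegionScoreMatrix:
    scores: pd.DataFrame  # regions x cells, summed CPM
    directions: pd.Series  # region -> gain | loss
    region_genes: Dict[str, List[str]]
    flagged: List[str]  # regions that resolved to zero genes (excluded)


def _resolve_genes(m: ExpressionMatrix, seg: CnvSegment) -> List[str]:
    if seg.genes:
        present = [g for g in seg.genes if g in m.genes]
        missing = len(seg.genes) - len(present)
        if missing:
            warnings.warn(
                f"{region_label(seg)}: {missing} region gene(s) absent from the "
                "matrix were skipped"
            )
        return present
    if m.gene_intervals is None:
        raise ValueError(
            f"{region_label(seg)} lists no genes and the matrix has no "
            "gene coordinates to resolve by overlap"
        )
    gi = m.gene_intervals
    hit = (gi["chrom"] == seg.chrom) & (gi["start"] < seg.end) & (gi["end"] > seg.start)
    return [g for g in gi.index[hit] if g in m.genes]


def score_regions(
    m: ExpressionMatrix, regions: Sequence[CnvSegment]
) -> RegionScoreMatrix:
    """Sum per-cell CPM over each region's member genes."""
    if m.norm_state != "cpm":
        raise ValueError("score_regions expects a CPM-normalized matrix")
    rows, labels, dirs, gene_map, flagged = [], [], [], {}, []
    for seg in regions:
        label = region_label(seg)
        genes = _resolve_genes(m, seg)
        gene_map[label] = genes
        labels.append(label)
        dirs.append(seg.direction if seg.direction else "gain")
        if not genes:
            flagged.append(label)
            rows.append(np.zeros(m.n_cells))
            continue
        idx = m.genes.get_indexer(genes)
        rows.append(m.values[idx, :].sum(axis=0))
    scores = pd.DataFrame(np.array(rows), index=pd.Index(labels, name="region"), columns=m.cells)
    return RegionScoreMatrix(
        scores=scores,
        directions=pd.Series(dirs, index=scores.index),
        region_genes=gene_map,
        flagged=flagged,
    )


@dataclass
class ControlReference:
    """Per-region score distributions over control cells, with the
    direction-appropriate 5% tail threshold (lower tail for losses, upper
    for gains)."""

    scores: pd.DataFrame  # regions x control cells
    directions: pd.Series
    tail_level: float = 0.05

    def __post_init__(self) -> None:
        if self.scores.shape[1] < MIN_CONTROL_CELLS:
            raise ValueError(
                f"need >= {MIN_CONTROL_CELLS} control cells, got {self.scores.shape[1]}"
            )

    @classmethod
    def from_matrix(
        cls,
        control: ExpressionMatrix,
        regions: Sequence[CnvSegment],
        tail_level: float = 0.05,
    ) -> "ControlReference":
        rsm = score_regions(control, regions)
        return cls(scores=rsm.scores, directions=rsm.directions, tail_level=tail_level)

    @property
    def thresholds(self) -> pd.Series:
        out = {}
        for region, row in self.scores.iterrows():
            q = (
                self.tail_level
                if self.directions[region] == "loss"
                else 1.0 - self.tail_level
            )
            out[region] = float(np.quantile(row.to_numpy(), q))
        return pd.Series(out, name="threshold")


@dataclass
class GenotypeMatrix:
    calls: pd.DataFrame  # cells x regions, bool
    pvals: pd.DataFrame
    qvals: pd.DataFrame
    alpha: float

    def genotype_sets(self) -> pd.Series:
        """Per-cell genotype: the frozenset of called region labels."""
        return self.calls.apply(
            lambda row: frozenset(row.index[row.to_numpy().astype(bool)]), axis=1
        )


def empirical_pvalues(scores: RegionScoreMatrix, ref: ControlReference) -> pd.DataFrame:
    """One-tailed add-one empirical p-values (cells x regions), tail chosen by
    CNV direction. Regions flagged as gene-free are NaN."""
    missing = [r for r in scores.scores.index if r not in ref.scores.index]
    if missing:
        raise ValueError(f"regions missing from the control reference: {missing}")
    out = {}
    for region, row in scores.scores.iterrows():
        if region in scores.flagged:
            out[region] = np.full(row.size, np.nan)
            continue
        tail = "lower" if scores.directions[region] == "loss" else "upper"
        out[region] = empirical_pvalues_1d(
            row.to_numpy(), ref.scores.loc[region].to_numpy(), tail=tail
        )
    return pd.DataFrame(out, index=scores.scores.columns)


def call_genotypes(
    pvals: pd.DataFrame, alpha: float = 0.05, correction: str = "bh"
) -> GenotypeMatrix:
    """BH over all cell x region tests jointly; call iff q < alpha."""
    if correction != "bh":
        raise ValueError("only Benjamini-Hochberg correction is supported")
    q = pd.DataFrame(bh_adjust(pvals.to_numpy()), index=pvals.index, columns=pvals.columns)
    if alpha >= 1.0:  # degenerate threshold: every assessable test is a call
        calls = q.notna()
    else:
        calls = (q < alpha).fillna(False)
    return GenotypeMatrix(calls=calls, pvals=pvals, qvals=q, alpha=alpha)


def crossval_fdr(
    control: ExpressionMatrix,
    regions: Sequence[CnvSegment],
    folds: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """K-fold cross-validated false-call rate on CNV-free control cells.

    Each fold: reference from the training tranche, genotyping of the
    held-out tranche (BH within the tranche), FDR = positives / tests.
    Returns one row per fold plus an "overall" row pooling all folds.
    """
    if control.norm_state == "raw":
        from .matrix import cpm_normalize

        control = cpm_normalize(control)
    n = control.n_cells
    if n < folds * 2:
        raise ValueError(f"need >= {folds * 2} control cells for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for k, chunk in enumerate(np.array_split(order, folds)):
        fold_of[chunk] = k
    rows = []
    total_pos = total_tests = 0
    for k in range(folds):
        test_cells = control.cells[fold_of == k]
        train_cells = control.cells[fold_of != k]
        ref = ControlReference.from_matrix(control.subset_cells(train_cells), regions)
        rsm = score_regions(control.subset_cells(test_cells), regions)
        pv = empirical_pvalues(rsm, ref)
        gm = call_genotypes(pv, alpha=alpha)
        positives = int(gm.calls.to_numpy().sum())
        tests = int(np.isfinite(pv.to_numpy()).sum())
        rows.append({"fold": k, "positives": positives, "tests": tests,
                     "fdr": positives / tests if tests else np.nan})
        total_pos += positives
        total_tests += tests
    rows.append({"fold": "overall", "positives": total_pos, "tests": total_tests,
                 "fdr": total_pos / total_tests if total_tests else np.nan})
    return pd.DataFrame(rows).set_index("fold")


def wavelet_smooth_track(
    m: ExpressionMatrix,
    control: ExpressionMatrix,
    chrom_order: Optional[Sequence[str]] = None,
    pseudo_cpm: float = 1.0,
    wavelet: str = "haar",
) -> pd.DataFrame:
    """Per-cell z-scored, wavelet-smoothed log2 expression ratio track.

    Per gene: log2((cell CPM + eps) / (control median CPM + eps)); genes are
    laid out in genomic order and each chromosome's profile is denoised by
    single-level soft-threshold wavelet shrinkage (universal threshold,
    noise scale from the median absolute detail coefficient); finally each
    cell's track is z-scored. Rows are cells, columns genes in genomic
    order — ready for heatmap rendering.
    """
    if m.norm_state != "cpm" or control.norm_state != "cpm":
        raise ValueError("both matrices must be CPM-normalized")
    if m.gene_intervals is None:
        raise ValueError("gene coordinates required for a genomic track")
    shared = m.genes.intersection(control.genes)
    coords = m.gene_intervals.loc[m.gene_intervals.index.intersection(shared)]
    dropped = len(shared) - len(coords)
    if dropped:
        warnings.warn(f"{dropped} gene(s) lacking coordinates were dropped")
    if chrom_order is None:
        chrom_order = sorted(coords["chrom"].unique())
    ordered: List[str] = []
    chrom_slices: List[slice] = []
    for chrom in chrom_order:
        sub = coords[coords["chrom"] == chrom].sort_values("start")
        chrom_slices.append(slice(len(ordered), len(ordered) + len(sub)))
        ordered.extend(sub.index)
    med = np.median(
        control.values[control.genes.get_indexer(ordered), :], axis=1
    )
    cellv = m.values[m.genes.get_indexer(ordered), :]
    ratio = np.log2((cellv + pseudo_cpm) / (med[:, None] + pseudo_cpm))
    smooth = np.empty_like(ratio)
    for sl in chrom_slices:
        for j in range(ratio.shape[1]):
            x = ratio[sl, j]
            approx, detail = pywt.dwt(x, wavelet)
            sigma = np.median(np.abs(detail)) / 0.6745 if detail.size else 0.0
            thr = sigma * np.sqrt(2.0 * np.log(max(x.size, 2)))
            detail = np.sign(detail) * np.maximum(np.abs(detail) - thr, 0.0)
            smooth[sl, j] = pywt.idwt(approx, detail, wavelet)[: x.size]
    sd = smooth.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (smooth - smooth.mean(axis=0)) / sd
    return pd.DataFrame(z.T, index=m.cells, columns=pd.Index(ordered, name="gene"))


def wavelet_smooth_expression(
    m: ExpressionMatrix,
    chrom_order: Optional[Sequence[str]] = None,
    wavelet: str = "haar",
) -> ExpressionMatrix:
    """Denoise each cell's CPM profile along genomic order (same single-level
    soft-threshold shrinkage as the ratio track) and return a CPM matrix,
    e.g. to check that genotype triage is insensitive to smoothing."""
    if m.norm_state != "cpm":
        raise ValueError("expects a CPM matrix")
    if m.gene_intervals is None:
        raise ValueError("gene coordinates required")
    coords = m.gene_intervals.loc[m.gene_intervals.index.intersection(m.genes)]
    if chrom_order is None:
        chrom_order = sorted(coords["chrom"].unique())
    values = m.values.copy()
    for chrom in chrom_order:
        sub = coords[coords["chrom"] == chrom].sort_values("start")
        idx = m.genes.get_indexer(sub.index)
        for j in range(m.n_cells):
            x = values[idx, j]
            approx, detail = pywt.dwt(x, wavelet)
            sigma = np.median(np.abs(detail)) / 0.6745 if detail.size else 0.0
            thr = sigma * np.sqrt(2.0 * np.log(max(x.size, 2)))
            detail = np.sign(detail) * np.maximum(np.abs(detail) - thr, 0.0)
            values[idx, j] = np.maximum(
                pywt.idwt(approx, detail, wavelet)[: x.size], 0.0
            )
    from dataclasses import replace

    return replace(m, values=values)


def flag_stromal(
    genotypes: GenotypeMatrix,
    mutation_evidence: pd.Series,
    m: ExpressionMatrix,
    marker_panel: Sequence[str] = (),
    n_clusters: int = 2,
) -> pd.DataFrame:
    """Triage infiltrating stromal/non-malignant cells.

    A cell is putative-stromal iff it has zero CNV calls, zero expressed
    somatic mutation evidence, and falls in a hierarchical-clustering
    cluster (correlation distance, average linkage, on marker-panel
    log2(CPM+1)) whose majority is zero-CNV cells. With an empty marker
    panel the clustering criterion is skipped with a warning.
    """
    cells = genotypes.calls.index
    evidence = mutation_evidence.reindex(cells).fillna(0)
    n_calls = genotypes.calls.sum(axis=1)
    markers = [g for g in marker_panel if g in m.genes]
    clusters = pd.Series(1, index=cells)
    use_clustering = bool(markers)
    if not use_clustering:
        warnings.warn(
            "empty marker panel: stromal triage uses CNV and mutation "
            "criteria only"
        )
    else:
        if m.norm_state != "cpm":
            raise ValueError("flag_stromal expects a CPM matrix")
        data = np.log2(m.values[m.genes.get_indexer(markers), :][:, m.cells.get_indexer(cells)] + 1.0).T
        link = sch.linkage(ssd.pdist(data, metric="correlation"), method="average")
        clusters = pd.Series(sch.fcluster(link, t=n_clusters, criterion="maxclust"), index=cells)
    zero_cnv = n_calls == 0
    if use_clustering:
        majority_zero = {
            c: zero_cnv[clusters == c].mean() > 0.5 for c in clusters.unique()
        }
        in_stromal_cluster = clusters.map(majority_zero)
    else:
        in_stromal_cluster = pd.Series(True, index=cells)
    stromal = zero_cnv & (evidence == 0) & in_stromal_cluster
    return pd.DataFrame(
        {
            "n_cnv_calls": n_calls,
            "mutation_evidence": evidence,
            "cluster": clusters,
            "label": np.where(stromal, "putative-stromal", "tumor"),
        },
        index=cells,
    )
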