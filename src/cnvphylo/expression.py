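"""Expression analyses conditioned on the clone phylogeny and genotypes.

Clonal pseudotime: a backbone root-to-leaf path is chosen through the
fitted tree by following, at each fork, the clade whose newly acquired CNV
has the highest cell frequency. Genotype classes along the path are binned
early/mid/late by terciles of path position, and genes whose bin means are
strictly ordered are reported as monotone.

Dose-response: Spearman rank correlation of every (prefiltered) gene with a
focal transcript's per-cell expression; the top and bottom 5% tails form
the positively and negatively responding gene sets.

Subtype classification: per-cell linear regression on four expression
centroids (label = largest coefficient in magnitude), and a two-module
mean-expression rule with a twofold-margin ambiguity zone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.stats

from .matrix import ExpressionMatrix
from .phylogeny import ClonePhylogeny, GenotypeClass

__all__ = [
    "BackbonePath",
    "backbone_path",
    "monotone_genes",
    "DoseResponseResult",
    "dose_response",
    "de_gene_filter",
    "export_clone_submatrices",
    "verhaak_classify",
    "sun_classify",
]

BIN_NAMES = ("early", "mid", "late")


@dataclass
class BackbonePath:
    classes: List[GenotypeClass]  # ordered root-outward
    acquired: List[frozenset]  # regions newly acquired at each step
    bin_of: pd.Series  # class name -> early | mid | late

    def cells_in_bin(self, bin_name: str) -> List[str]:
        cells: List[str] = []
        for c in self.classes:
            if self.bin_of[c.name] == bin_name:
                cells.extend(c.member_cells)
        return cells

    @property
    def bins(self) -> List[str]:
        return [b for b in BIN_NAMES if (self.bin_of == b).any()]


def backbone_path(tree: ClonePhylogeny, classes: Sequence[GenotypeClass]) -> BackbonePath:
    """Trace the dominant root-to-leaf path through the fitted tree.

    At each fork the clade is chosen whose newly acquired region (the
    regions common to all clade leaves but not yet on the path) has the
    highest total cell frequency; ties go to the larger clade, then to the
    lexicographically smallest leaf label. Leaf classes hanging off the
    backbone are collected and ordered by cumulative genotype size, then
    binned early/mid/late by terciles of path position (earlier bins take
    the extra classes when the count is not divisible by three).
    """
    by_name = {c.name: c for c in classes}
    region_freq: Dict[str, int] = {}
    for c in classes:
        for r in c.genotype:
            region_freq[r] = region_freq.get(r, 0) + c.frequency
    root, children = tree.rooted()

    def clade_leaves(node: int) -> List[str]:
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            kids = children.get(n, [])
            if not kids:
                lab = tree.leaf_label(n)
                if lab is not None:
                    out.append(lab)
            for k, _ in kids:
                stack.append(k)
        return out

    def clade_cells(leaves: List[str]) -> int:
        return sum(by_name[l].frequency for l in leaves if l in by_name)

    seen_leaves: List[str] = []
    current: frozenset = frozenset()
    node = root
    while True:
        kids = [
            (child, ln)
            for child, ln in children.get(node, [])
            if tree.leaf_label(child) != tree.outgroup
        ]
        leaf_kids = [c for c, _ in kids if not children.get(c)]
        internal_kids = [c for c, _ in kids if children.get(c)]
        for c in leaf_kids:
            lab = tree.leaf_label(c)
            if lab in by_name:
                seen_leaves.append(lab)
        if not internal_kids:
            break
        if len(internal_kids) == 1:
            chosen = internal_kids[0]
        else:

            def rank(child: int):
                # most frequent mutation newly acquired within this clade:
                # cells of the clade carrying a region not yet on the path
                leaves = clade_leaves(child)
                new_freq: Dict[str, int] = {}
                for l in leaves:
                    if l not in by_name:
                        continue
                    for r in by_name[l].genotype - current:
                        new_freq[r] = new_freq.get(r, 0) + by_name[l].frequency
                freq = max(new_freq.values(), default=-1)
                return (
                    -freq,
                    -clade_cells(leaves),
                    min(leaves) if leaves else "",
                )

            chosen = min(internal_kids, key=rank)
        leaves = clade_leaves(chosen)
        common = frozenset.intersection(
            *[by_name[l].genotype for l in leaves if l in by_name]
        ) if leaves else frozenset()
        current = current | common
        node = chosen

    # terminal genotype of the backbone: the largest genotype reached
    terminal = max(
        (by_name[l].genotype for l in seen_leaves), key=len, default=frozenset()
    )
    # every class nested inside the terminal genotype lies on the
    # root-to-leaf evolutionary path, wherever least-squares fitting
    # happened to attach its leaf
    path_classes = sorted(
        (c for c in classes if c.genotype <= terminal),
        key=lambda c: (len(c.genotype), c.name),
    )
    n = len(path_classes)
    if n == 1:
        warnings.warn("single genotype class: one-bin backbone path")
    # terciles of cell-weighted path position: a class joins the bin
    # holding the midpoint of its cumulative cell span
    total = sum(c.frequency for c in path_classes)
    bin_of = {}
    cum = 0
    for c in path_classes:
        mid = cum + c.frequency / 2.0
        bin_of[c.name] = BIN_NAMES[min(2, int(3 * mid / max(total, 1)))]
        cum += c.frequency
    bin_of = pd.Series(bin_of)
    steps = [
        path_classes[i].genotype - (path_classes[i - 1].genotype if i else frozenset())
        for i in range(n)
    ]
    return BackbonePath(classes=path_classes, acquired=steps, bin_of=bin_of)


def monotone_genes(
    m: ExpressionMatrix,
    path: Union[BackbonePath, Dict[str, List[str]]],
    direction: str = "increasing",
    genes: Optional[Sequence[str]] = None,
) -> Tuple[List[str], pd.DataFrame]:
    """Genes whose per-bin mean expression is strictly ordered along the
    early -> mid -> late path. Returns (gene list, per-bin mean +/- SD table).

    `path` is a fitted BackbonePath, or an explicit bin -> cells mapping
    (useful for permutation calibration of the strict-ordering rule).
    """
    if direction not in ("increasing", "decreasing"):
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    if isinstance(path, dict):
        bin_cells = {b: path[b] for b in BIN_NAMES if b in path}
        bins = list(bin_cells)
    else:
        bins = path.bins
        bin_cells = {b: path.cells_in_bin(b) for b in bins}
    bins = [b for b in bins if len(bin_cells[b]) >= 2]
    if len(bins) < 2:
        raise ValueError("need at least 2 bins with >= 2 cells each")
    use_genes = m.genes if genes is None else pd.Index([g for g in genes if g in m.genes])
    gidx = m.genes.get_indexer(use_genes)
    table = {}
    means = []
    for b in bins:
        cidx = m.cells.get_indexer(bin_cells[b])
        sub = m.values[np.ix_(gidx, cidx)]
        mu = sub.mean(axis=1)
        table[f"mean_{b}"] = mu
        table[f"sd_{b}"] = sub.std(axis=1, ddof=1)
        means.append(mu)
    means = np.array(means)  # bins x genes
    diffs = np.diff(means, axis=0)
    mono = (diffs > 0).all(axis=0) if direction == "increasing" else (diffs < 0).all(axis=0)
    df = pd.DataFrame(table, index=use_genes)
    df["monotone"] = mono
    return list(use_genes[mono]), df


@dataclass
class DoseResponseResult:
    focal: str
    table: pd.DataFrame  # gene -> rho, rank
    positive_set: List[str]
    negative_set: List[str]
    tail: float


def dose_response(
    m: ExpressionMatrix,
    focal: Union[str, pd.Series, np.ndarray],
    tail: float = 0.05,
    min_expressing_cells: int = 10,
) -> DoseResponseResult:
    """Rank-correlate every gene with the focal transcript across cells.

    The focal covariate is a gene of the matrix or any per-cell vector
    (e.g. transcript-level quantification of a deletion isoform). Each
    tail's gene set has exactly ceil(tail * #tested genes) members.
    """
    if isinstance(focal, str):
        if focal not in m.genes:
            raise KeyError(f"focal gene {focal!r} not in matrix")
        fvec = m.values[m.genes.get_loc(focal), :]
        name = focal
        test_genes = m.genes.drop(focal)
    else:
        fvec = np.asarray(pd.Series(focal).reindex(m.cells) if isinstance(focal, pd.Series) else focal, dtype=float)
        if fvec.shape[0] != m.n_cells:
            raise ValueError("focal vector length must equal the cell count")
        name = getattr(focal, "name", None) or "focal"
        test_genes = m.genes
    if np.ptp(fvec) == 0:
        raise ValueError("focal vector is constant; rank correlation undefined")
    if int(np.sum(fvec > 0)) < min_expressing_cells:
        raise ValueError(
            f"focal expressed in fewer than {min_expressing_cells} cells"
        )
    franks = scipy.stats.rankdata(fvec)
    gidx = m.genes.get_indexer(test_genes)
    granks = scipy.stats.rankdata(m.values[gidx, :], axis=1)
    fr = franks - franks.mean()
    gr = granks - granks.mean(axis=1, keepdims=True)
    denom = np.sqrt((gr * gr).sum(axis=1) * (fr * fr).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (gr * fr).sum(axis=1) / denom, np.nan)
    table = pd.DataFrame({"rho": rho}, index=test_genes)
    tested = table.dropna().sort_values("rho", ascending=False)
    table["rank"] = table["rho"].rank(ascending=False)
    k = math.ceil(tail * len(tested))
    positive = list(tested.index[:k])
    negative = list(tested.index[::-1][:k])
    return DoseResponseResult(
        focal=name, table=table, positive_set=positive, negative_set=negative, tail=tail
    )


def de_gene_filter(
    m: ExpressionMatrix, max_lowexpr_frac: float = 0.8, cpm_floor: float = 1.0
) -> List[str]:
    """Drop genes expressed below `cpm_floor` CPM in more than
    `max_lowexpr_frac` of cells; return the retained gene list."""
    if m.norm_state != "cpm":
        raise ValueError("de_gene_filter expects a CPM matrix")
    low_frac = (m.values < cpm_floor).mean(axis=1)
    return list(m.genes[low_frac <= max_lowexpr_frac])


def export_clone_submatrices(
    m: ExpressionMatrix, genotypes, grouping: str = "clone"
) -> Tuple[Dict[str, ExpressionMatrix], pd.DataFrame]:
    """Split the raw count matrix into per-group submatrices for an external
    differential-expression engine (each cell a replicate).

    grouping="clone" groups by full genotype class; a region label groups
    cells into carriers vs wild-type for that region. Counts are preserved
    bit-exact; the manifest maps each cell to its group.
    """
    calls = genotypes.calls if hasattr(genotypes, "calls") else genotypes
    if grouping == "clone":
        sets = calls.apply(
            lambda row: frozenset(row.index[row.to_numpy().astype(bool)]), axis=1
        )
        group_of = sets.map(lambda g: "+".join(sorted(g)) if g else "wildtype")
    else:
        if grouping not in calls.columns:
            raise KeyError(f"unknown region {grouping!r}")
        group_of = calls[grouping].map(lambda v: "carrier" if v else "wildtype")
    out: Dict[str, ExpressionMatrix] = {}
    for group in sorted(group_of.unique()):
        cells = list(group_of.index[group_of == group])
        if len(cells) < 2:
            warnings.warn(f"group {group!r} has fewer than 2 cells")
        out[group] = m.subset_cells(cells)
    manifest = pd.DataFrame({"cell": group_of.index, "group": group_of.values})
    return out, manifest


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def verhaak_classify(
    m: ExpressionMatrix, centroids: pd.DataFrame, min_genes: int = 10
) -> pd.DataFrame:
    """Per-cell subtype call by regressing the cell's standardized
    log2(CPM+1) profile (over the signature genes) on the four standardized
    centroid columns, without intercept; the label is the subtype with the
    largest coefficient in magnitude.
    """
    if m.norm_state != "cpm":
        raise ValueError("verhaak_classify expects a CPM matrix")
    shared = [g for g in centroids.index if g in m.genes]
    if len(shared) < min_genes:
        raise ValueError(
            f"only {len(shared)} signature genes present; need >= {min_genes}"
        )
    X = np.column_stack([_standardize(centroids.loc[shared, c].to_numpy(dtype=float))
                         for c in centroids.columns])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("centroid matrix is rank-deficient")
    gidx = m.genes.get_indexer(shared)
    rows = []
    for j, cell in enumerate(m.cells):
        y = _standardize(np.log2(m.values[gidx, j] + 1.0))
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        label = centroids.columns[int(np.argmax(np.abs(coef)))]
        rows.append([cell, label, *coef])
    return pd.DataFrame(
        rows, columns=["cell", "label", *[f"coef_{c}" for c in centroids.columns]]
    ).set_index("cell")


def sun_classify(
    m: ExpressionMatrix,
    module_a: Sequence[str],
    module_b: Sequence[str],
    fold: float = 2.0,
    labels: Tuple[str, str] = ("PDGFRA-module", "EGFR-module"),
) -> pd.DataFrame:
    """Two-module mean-expression classifier: a cell is assigned to a module
    only when its mean log2(CPM+1) over that module is more than `fold`
    times the other module's mean; otherwise ambiguous."""
    if m.norm_state != "cpm":
        raise ValueError("sun_classify expects a CPM matrix")
    ga = [g for g in module_a if g in m.genes]
    gb = [g for g in module_b if g in m.genes]
    if not ga or not gb:
        raise ValueError("a module is empty after intersecting with matrix genes")
    la = np.log2(m.values[m.genes.get_indexer(ga), :] + 1.0).mean(axis=0)
    lb = np.log2(m.values[m.genes.get_indexer(gb), :] + 1.0).mean(axis=0)
    label = np.where(la > fold * lb, labels[0], np.where(lb > fold * la, labels[1], "ambiguous"))
    return pd.DataFrame(
        {"label": label, "mean_module_a": la, "mean_module_b": lb}, index=m.cells
    )
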