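"""Rooted phylogenies of CNV cellular genotypes.

Cells are grouped into genotype classes (identical sets of CNV calls);
pairwise Jaccard distances between class genotypes feed a Fitch-Margoliash
least-squares tree: minimize sum_{i<j} (d_ij - p_ij)^2 / d_ij^2 over
unrooted binary topologies and non-negative branch lengths, where p_ij is
the path length between leaves i and j. Branch lengths for a candidate
topology are the exact weighted non-negative least-squares solution on the
path-membership design matrix. Topology search is exhaustive up to 8
leaves ((2n-5)!! trees) and stepwise addition plus nearest-neighbor-
interchange refinement above that. The tree is rooted on the branch to a
CNV-free "normal" out-group genotype and serialized as newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.optimize

__all__ = [
    "GenotypeClass",
    "ClonePhylogeny",
    "jaccard_distance",
    "collapse_genotypes",
    "fitch_margoliash_fit",
    "to_newick",
    "build_clone_phylogeny",
    "OUTGROUP_LABEL",
]

OUTGROUP_LABEL = "normal"
_EPS_IMPROVE = 1e-12


def jaccard_distance(g1, g2) -> float:
    """1 - |intersection| / |union|; two empty sets are at distance 0."""
    s1, s2 = set(g1), set(g2)
    union = s1 | s2
    if not union:
        return 0.0
    return 1.0 - len(s1 & s2) / len(union)


@dataclass(frozen=True)
class GenotypeClass:
    name: str
    genotype: FrozenSet[str]
    member_cells: Tuple[str, ...]

    @property
    def frequency(self) -> int:
        return len(self.member_cells)


def collapse_genotypes(genotypes) -> Tuple[List[GenotypeClass], pd.DataFrame]:
    """Group cells by identical call sets and build the Jaccard distance
    matrix over class genotypes, with the CNV-free out-group appended.

    Accepts a GenotypeMatrix or a cells x regions 0/1 DataFrame. Classes are
    named G0, G1, ... ordered by genotype size then lexicographically, so
    naming is deterministic.
    """
    calls = genotypes.calls if hasattr(genotypes, "calls") else genotypes
    sets = calls.apply(
        lambda row: frozenset(row.index[row.to_numpy().astype(bool)]), axis=1
    )
    grouped: Dict[FrozenSet[str], List[str]] = {}
    for cell, g in sets.items():
        grouped.setdefault(g, []).append(cell)
    ordered = sorted(grouped, key=lambda g: (len(g), tuple(sorted(g))))
    classes = [
        GenotypeClass(name=f"G{i}", genotype=g, member_cells=tuple(grouped[g]))
        for i, g in enumerate(ordered)
    ]
    labels = [c.name for c in classes] + [OUTGROUP_LABEL]
    genos = [c.genotype for c in classes] + [frozenset()]
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = jaccard_distance(genos[i], genos[j])
    return classes, pd.DataFrame(d, index=labels, columns=labels)


# --------------------------------------------------------------- tree fitting

Edge = Tuple[int, int]


def _edge(u: int, v: int) -> Edge:
    return (u, v) if u < v else (v, u)


def _adjacency(edges: Sequence[Edge]) -> Dict[int, List[int]]:
    adj: Dict[int, List[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    return adj


def _leaf_paths(edges: Sequence[Edge], n_leaves: int) -> np.ndarray:
    """Path-membership design matrix: one row per leaf pair (combinations
    order), one column per edge."""
    edge_idx = {e: k for k, e in enumerate(edges)}
    adj = _adjacency(edges)
    pairs = list(combinations(range(n_leaves), 2))
    A = np.zeros((len(pairs), len(edges)))
    for row, (i, j) in enumerate(pairs):
        # DFS from i to j recording the path
        stack = [(i, -1, [])]
        while stack:
            node, parent, path = stack.pop()
            if node == j:
                for e in path:
                    A[row, edge_idx[e]] = 1.0
                break
            for nxt in adj[node]:
                if nxt != parent:
                    stack.append((nxt, node, path + [_edge(node, nxt)]))
    return A


def _fm_weights(dvec: np.ndarray) -> np.ndarray:
    """Classic Fitch-Margoliash weights 1/d^2; zero distances get the weight
    of the smallest positive distance (capped)."""
    positive = dvec[dvec > 0]
    floor = positive.min() if positive.size else 1.0
    return 1.0 / np.maximum(dvec, floor) ** 2


def _fit_branch_lengths(
    edges: Sequence[Edge], dvec: np.ndarray, w: np.ndarray, n_leaves: int
):
    A = _leaf_paths(edges, n_leaves)
    sw = np.sqrt(w)
    lengths, _ = scipy.optimize.nnls(sw[:, None] * A, sw * dvec)
    resid = float(np.sum(w * (dvec - A @ lengths) ** 2))
    return lengths, resid


def _enumerate_topologies(n_leaves: int):
    """All unrooted binary topologies over leaves 0..n-1 ((2n-5)!! of them),
    in a deterministic insertion order. Internal node ids start at n."""
    base = [_edge(0, n_leaves), _edge(1, n_leaves), _edge(2, n_leaves)]

    def extend(edges: List[Edge], leaf: int, next_internal: int):
        if leaf == n_leaves:
            yield edges
            return
        for k in range(len(edges)):
            u, v = edges[k]
            new = (
                edges[:k]
                + edges[k + 1 :]
                + [_edge(u, next_internal), _edge(v, next_internal), _edge(leaf, next_internal)]
            )
            yield from extend(new, leaf + 1, next_internal + 1)

    if n_leaves == 3:
        yield base
    else:
        yield from extend(base, 3, n_leaves + 1)


def _nni_neighbors(edges: List[Edge], n_leaves: int):
    """The two nearest-neighbor-interchange rearrangements of every internal
    edge, in deterministic order."""
    adj = _adjacency(edges)
    eset = set(edges)
    for u, v in sorted(edges):
        if u < n_leaves or v < n_leaves:
            continue  # pendant edge
        a, b = sorted(x for x in adj[u] if x != v)
        c, d = sorted(x for x in adj[v] if x != u)
        for swap_u, swap_v in ((b, c), (b, d)):
            new = eset - {_edge(u, swap_u), _edge(v, swap_v)}
            new |= {_edge(u, swap_v), _edge(v, swap_u)}
            yield sorted(new)


@dataclass
class ClonePhylogeny:
    """A fitted, out-group-rooted tree over genotype classes.

    `edges` hold the unrooted fit (leaf ids 0..n-1 map to `labels`);
    the root is introduced at the midpoint of the out-group's pendant edge.
    """

    labels: List[str]
    edges: Dict[Edge, float]
    residual: float
    outgroup: str = OUTGROUP_LABEL
    classes: Optional[List[GenotypeClass]] = None
    _root_id: int = field(default=-1, repr=False)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def rooted(self) -> Tuple[int, Dict[int, List[Tuple[int, float]]]]:
        """(root id, children map node -> [(child, branch length), ...]).

        The root splits the out-group pendant edge at its midpoint, so the
        out-group is a direct child of the root.
        """
        og = self.labels.index(self.outgroup)
        adj: Dict[int, List[Tuple[int, float]]] = {}
        for (u, v), ln in self.edges.items():
            adj.setdefault(u, []).append((v, ln))
            adj.setdefault(v, []).append((u, ln))
        (p, ln) = adj[og][0]
        root = max(max(e) for e in self.edges) + 1
        children: Dict[int, List[Tuple[int, float]]] = {root: [(og, ln / 2)]}
        # orient the rest of the tree away from the root
        stack = [(p, og, ln / 2, root)]
        while stack:
            node, came_from, length, parent = stack.pop()
            children.setdefault(parent, []).append((node, length))
            for nxt, l2 in adj.get(node, []):
                if nxt != came_from:
                    stack.append((nxt, node, l2, node))
        return root, children

    def leaf_label(self, node: int) -> Optional[str]:
        return self.labels[node] if node < len(self.labels) else None


def _quote(label: str) -> str:
    if any(ch in label for ch in "(),:;'\" \t[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: ClonePhylogeny, include_counts: bool = True) -> str:
    """Serialize the rooted tree as newick with branch lengths.

    Leaf labels are class IDs, suffixed with member counts when genotype
    classes are attached. Reserved characters are quoted.
    """
    counts = {}
    if include_counts and tree.classes:
        counts = {c.name: c.frequency for c in tree.classes}
    root, children = tree.rooted()

    def label_of(node: int) -> str:
        lab = tree.leaf_label(node)
        if lab in counts:
            lab = f"{lab}_n{counts[lab]}"
        return _quote(lab) if lab else ""

    def render(node: int) -> str:
        kids = children.get(node, [])
        if not kids:
            return label_of(node)
        inner = ",".join(f"{render(c)}:{ln:.10g}" for c, ln in sorted(kids))
        return f"({inner})"

    return render(root) + ";"


def fitch_margoliash_fit(
    D,
    labels: Optional[Sequence[str]] = None,
    outgroup: str = OUTGROUP_LABEL,
    exhaustive_max: int = 8,
    classes: Optional[List[GenotypeClass]] = None,
) -> ClonePhylogeny:
    """Fit a Fitch-Margoliash least-squares tree to a distance matrix.

    D may be a labeled DataFrame or an ndarray with `labels`. For up to
    `exhaustive_max` leaves every unrooted binary topology is scored; above
    that, stepwise addition in label order followed by NNI refinement. Ties
    between equally optimal topologies resolve to the first in enumeration
    order (lexicographic leaf insertion), so results are deterministic.
    """
    if isinstance(D, pd.DataFrame):
        labels = list(D.index)
        mat = D.to_numpy(dtype=float)
    else:
        mat = np.asarray(D, dtype=float)
        if labels is None:
            raise ValueError("labels required with a bare distance matrix")
        labels = list(labels)
    n = len(labels)
    if mat.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(mat, mat.T) or not np.allclose(np.diag(mat), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if n < 3:
        raise ValueError("need at least 3 labels to fit a tree")
    if outgroup not in labels:
        raise ValueError(f"out-group {outgroup!r} not among labels")
    pairs = list(combinations(range(n), 2))
    dvec = np.array([mat[i, j] for i, j in pairs])
    if np.all(dvec == 0):
        import warnings

        warnings.warn("all distances are zero: degenerate star-like tree")
    w = _fm_weights(dvec)

    best_edges, best_lengths, best_resid = None, None, np.inf
    if n <= exhaustive_max:
        for edges in _enumerate_topologies(n):
            lengths, resid = _fit_branch_lengths(edges, dvec, w, n)
            if resid < best_resid - _EPS_IMPROVE:
                best_edges, best_lengths, best_resid = list(edges), lengths, resid
    else:
        best_edges, best_lengths, best_resid = _stepwise_nni(mat, n)
        # recompute with the full weight vector for consistency
        best_lengths, best_resid = _fit_branch_lengths(best_edges, dvec, w, n)

    edge_lengths = {e: float(l) for e, l in zip(best_edges, best_lengths)}
    return ClonePhylogeny(
        labels=labels,
        edges=edge_lengths,
        residual=best_resid,
        outgroup=outgroup,
        classes=classes,
    )


def _stepwise_nni(mat: np.ndarray, n: int):
    pairs = list(combinations(range(n), 2))
    dvec = np.array([mat[i, j] for i, j in pairs])
    w = _fm_weights(dvec)

    def sub_fit(edges, k):
        """Fit restricted to the first k leaves."""
        sub_pairs = list(combinations(range(k), 2))
        dv = np.array([mat[i, j] for i, j in sub_pairs])
        wv = _fm_weights(dv)
        return _fit_branch_lengths(edges, dv, wv, k)

    edges = [_edge(0, n), _edge(1, n), _edge(2, n)]
    next_internal = n + 1
    for leaf in range(3, n):
        best, best_r = None, np.inf
        for k in range(len(edges)):
            u, v = edges[k]
            cand = (
                edges[:k]
                + edges[k + 1 :]
                + [_edge(u, next_internal), _edge(v, next_internal), _edge(leaf, next_internal)]
            )
            _, r = sub_fit(cand, leaf + 1)
            if r < best_r - _EPS_IMPROVE:
                best, best_r = cand, r
        edges = best
        next_internal += 1
    lengths, resid = _fit_branch_lengths(edges, dvec, w, n)
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbors(edges, n):
            l2, r2 = _fit_branch_lengths(cand, dvec, w, n)
            if r2 < resid - _EPS_IMPROVE:
                edges, lengths, resid = list(cand), l2, r2
                improved = True
                break
    return edges, lengths, resid


def build_clone_phylogeny(genotypes, outgroup: str = OUTGROUP_LABEL) -> ClonePhylogeny:
    """Collapse a genotype matrix into classes and fit the rooted tree."""
    classes, D = collapse_genotypes(genotypes)
    return fitch_margoliash_fit(D, outgroup=outgroup, classes=classes)


def bipartitions(tree: ClonePhylogeny) -> set:
    """Non-trivial splits of the unrooted fitted topology, as frozensets of
    label frozensets (used for topology comparison)."""
    adj = _adjacency(list(tree.edges))
    n = tree.n_leaves
    out = set()
    for u, v in tree.edges:
        # leaves on v's side of the edge
        stack, seen, side = [v], {u, v}, []
        while stack:
            node = stack.pop()
            if node < n:
                side.append(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if 1 < len(side) < n - 1:
            s = frozenset(tree.labels[i] for i in side)
            rest = frozenset(tree.labels) - s
            out.add(frozenset({s, rest}))
    return out
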