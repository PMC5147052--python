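"""Synthetic data: clone trees with sequentially acquired CNVs, dosage-affected
negative-binomial single-cell counts, a CNV-free control population, and
per-exon coverage profiles with or without focal exon depletion.

Generative model
----------------
A clone tree lists clones with cumulative acquired CNV region sets, nested
along every root-to-leaf path. Regions are contiguous, disjoint gene blocks.
A cell of clone k has expected count for gene g

    mu(g, cell) = base_mean * dose(region(g), clone k) * libfactor(cell)

with dose = dosage_gain_factor for a carried gain, dosage_loss_factor for a
carried loss, 1 otherwise; libfactor is log-normal. Counts are negative
binomial with common size parameter `nb_dispersion` (variance
mu + mu^2/size), drawn as a gamma-Poisson mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "Clone",
    "SimConfig",
    "SimTruth",
    "simulate_truth",
    "simulate_cells",
    "simulate_controls",
    "simulate_exon_coverage",
    "linear_clone_tree",
]


@dataclass(frozen=True)
class Clone:
    """A clone with its *cumulative* set of acquired CNV regions."""

    name: str
    parent: Optional[int]  # index into the clone list; None for the root clone
    regions: frozenset


def linear_clone_tree(n_steps: int, start: int = 0) -> List[Clone]:
    """A linear chain: clone i has acquired regions start..start+i-1."""
    clones = [Clone("c0", None, frozenset())]
    for i in range(1, n_steps + 1):
        clones.append(
            Clone(f"c{i}", i - 1, frozenset(range(start, start + i)))
        )
    return clones


@dataclass
class SimConfig:
    n_genes: int = 6000
    n_regions: int = 10
    genes_per_region: int = 300
    clone_tree: Sequence[Clone] = field(default_factory=lambda: [Clone("c0", None, frozenset())])
    cells_per_clone: int = 50
    n_control_cells: int = 100
    base_mean: float = 0.5
    nb_dispersion: float = 2.0
    dosage_gain_factor: float = 1.5
    dosage_loss_factor: float = 0.5
    libsize_sigma: float = 0.2
    region_directions: Optional[Sequence[str]] = None  # per region, default all "gain"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "genes_per_region", "cells_per_clone"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_regions < 0:
            raise ValueError("n_regions must be >= 0")
        if self.n_regions * self.genes_per_region > self.n_genes:
            raise ValueError("regions do not fit into the gene universe")
        if min(self.dosage_gain_factor, self.dosage_loss_factor) <= 0:
            raise ValueError("dosage factors must be positive")
        if self.region_directions is None:
            self.region_directions = ["gain"] * self.n_regions
        if len(self.region_directions) != self.n_regions:
            raise ValueError("region_directions length must equal n_regions")
        if any(d not in ("gain", "loss") for d in self.region_directions):
            raise ValueError("region directions must be 'gain' or 'loss'")
        self._validate_tree()

    def _validate_tree(self) -> None:
        for i, clone in enumerate(self.clone_tree):
            if clone.parent is not None:
                if not (0 <= clone.parent < i):
                    raise ValueError(
                        f"clone {clone.name!r}: parent index must precede the clone"
                    )
                parent = self.clone_tree[clone.parent]
                if not clone.regions >= parent.regions:
                    raise ValueError(
                        f"clone {clone.name!r}: acquired set is not a superset of "
                        f"its parent {parent.name!r} (non-nested clone tree)"
                    )
            bad = [r for r in clone.regions if not 0 <= r < self.n_regions]
            if bad:
                raise ValueError(f"clone {clone.name!r}: unknown region indices {bad}")

    def dose_factor(self, direction: str) -> float:
        return self.dosage_gain_factor if direction == "gain" else self.dosage_loss_factor


@dataclass
class SimTruth:
    true_genotypes: pd.DataFrame  # cells x regions, 0/1
    clone_of_cell: pd.Series  # cell -> clone name
    region_gene_map: Dict[int, np.ndarray]  # region -> gene row indices
    config: SimConfig
    focal_gene_profile: Optional[pd.Series] = None


def _region_names(n: int) -> List[str]:
    return [f"region_{r}" for r in range(n)]


def simulate_truth(config: SimConfig) -> SimTruth:
    """Assign cells to clones and regions to contiguous gene blocks.

    Deterministic given the config (cell-to-clone assignment is by clone
    order; randomness enters only in count generation).
    """
    cells = []
    clone_of_cell = []
    rows = []
    region_names = _region_names(config.n_regions)
    for clone in config.clone_tree:
        for i in range(config.cells_per_clone):
            cells.append(f"{clone.name}_cell{i}")
            clone_of_cell.append(clone.name)
            rows.append(
                [1 if r in clone.regions else 0 for r in range(config.n_regions)]
            )
    genotypes = pd.DataFrame(rows, index=pd.Index(cells, name="cell"), columns=region_names)
    region_gene_map = {
        r: np.arange(r * config.genes_per_region, (r + 1) * config.genes_per_region)
        for r in range(config.n_regions)
    }
    return SimTruth(
        true_genotypes=genotypes,
        clone_of_cell=pd.Series(clone_of_cell, index=genotypes.index),
        region_gene_map=region_gene_map,
        config=config,
    )


def _gene_index(config: SimConfig) -> pd.Index:
    return pd.Index([f"gene_{g}" for g in range(config.n_genes)], name="gene")


def gene_intervals(config: SimConfig, gene_span: int = 100_000) -> pd.DataFrame:
    """Synthetic genomic coordinates: all genes on one chromosome, laid out
    end to end so that region blocks are contiguous intervals (BED, 0-based)."""
    starts = np.arange(config.n_genes, dtype=int) * gene_span
    return pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + gene_span},
        index=_gene_index(config),
    )


def _dose_matrix(truth: SimTruth, config: SimConfig) -> np.ndarray:
    """genes x cells multiplicative dosage factors from the true genotypes."""
    n_cells = len(truth.true_genotypes)
    dose = np.ones((config.n_genes, n_cells))
    geno = truth.true_genotypes.to_numpy()
    for r, genes in truth.region_gene_map.items():
        factor = config.dose_factor(config.region_directions[r])
        carriers = geno[:, r].astype(bool)
        if carriers.any():
            dose[np.ix_(genes, np.where(carriers)[0])] = factor
    return dose


def _nb_counts(mean: np.ndarray, size: float, rng: np.random.Generator) -> np.ndarray:
    lam = rng.gamma(shape=size, scale=mean / size)
    return rng.poisson(lam).astype(float)


def simulate_cells(truth: SimTruth, config: SimConfig) -> ExpressionMatrix:
    """Tumor-cell counts under the dosage model. Deterministic given seed."""
    rng = np.random.default_rng([config.seed, 1])
    n_cells = len(truth.true_genotypes)
    lib = np.exp(rng.normal(0.0, config.libsize_sigma, size=n_cells))
    mean = config.base_mean * _dose_matrix(truth, config) * lib[None, :]
    counts = _nb_counts(mean, config.nb_dispersion, rng)
    return ExpressionMatrix(
        counts,
        genes=_gene_index(config),
        cells=truth.true_genotypes.index,
        gene_intervals=gene_intervals(config),
    )


def simulate_controls(config: SimConfig) -> ExpressionMatrix:
    """CNV-free control cells (all-normal copy state, same gene universe)."""
    if config.n_control_cells < 2:
        raise ValueError("need at least 2 control cells")
    rng = np.random.default_rng([config.seed, 2])
    lib = np.exp(rng.normal(0.0, config.libsize_sigma, size=config.n_control_cells))
    mean = np.full((config.n_genes, config.n_control_cells), config.base_mean) * lib[None, :]
    counts = _nb_counts(mean, config.nb_dispersion, rng)
    cells = pd.Index(
        [f"control_cell{i}" for i in range(config.n_control_cells)], name="cell"
    )
    return ExpressionMatrix(
        counts, genes=_gene_index(config), cells=cells,
        gene_intervals=gene_intervals(config),
    )


def truth_regions(truth: SimTruth, gene_span: int = 100_000):
    """The simulated CNV regions as bulk-call segments (one per region block),
    with member gene lists and directions — the input downstream genotyping
    expects."""
    from .triage import CnvSegment

    config = truth.config
    gene_names = _gene_index(config)
    segments = []
    for r in range(config.n_regions):
        genes = truth.region_gene_map[r]
        segments.append(
            CnvSegment(
                chrom="chr1",
                start=int(genes[0]) * gene_span,
                end=(int(genes[-1]) + 1) * gene_span,
                n_exons=len(genes),
                ratio=config.dose_factor(config.region_directions[r]),
                direction=config.region_directions[r],
                genes=tuple(gene_names[genes]),
            )
        )
    return segments


def simulate_exon_coverage(
    n_exons: int,
    target_exons: Sequence[int],
    n_tumor: int,
    n_control: int,
    depleted_fraction: float,
    depth: float = 200.0,
    suppression: float = 0.05,
    libsize_sigma: float = 0.2,
    seed: int = 0,
) -> Tuple[list, list, pd.Series]:
    """Per-exon read counts for one gene across tumor and blood-control
    cohorts.

    A `depleted_fraction` of tumors carry a focal deletion: their target-exon
    means are multiplied by `suppression` (partial suppression emulates
    heterozygous/subclonal deletions; 0 means complete loss). Controls have
    full coverage everywhere. Returns (tumor profiles, control profiles,
    boolean truth labels per tumor).
    """
    from .depletion import ExonCoverageProfile

    targets = sorted(set(int(e) for e in target_exons))
    if not targets:
        raise ValueError("target_exons must be non-empty")
    if any(not 1 <= e <= n_exons for e in targets):
        raise ValueError("target exons out of range 1..n_exons")
    if not 0.0 <= depleted_fraction <= 1.0:
        raise ValueError("depleted_fraction must be in [0, 1]")
    rng = np.random.default_rng([seed, 3])
    n_depleted = int(round(depleted_fraction * n_tumor))
    depleted = np.zeros(n_tumor, dtype=bool)
    depleted[rng.choice(n_tumor, size=n_depleted, replace=False)] = True
    tmask = np.zeros(n_exons)
    tmask[[e - 1 for e in targets]] = 1.0

    def _profiles(n: int, cohort: str, dep: np.ndarray) -> list:
        out = []
        for i in range(n):
            scale = np.exp(rng.normal(0.0, libsize_sigma))
            mean = np.full(n_exons, depth) * scale
            if dep[i]:
                mean = mean * (1.0 - tmask * (1.0 - suppression))
            counts = rng.poisson(mean)
            out.append(
                ExonCoverageProfile(
                    sample=f"{cohort}_{i}", cohort=cohort, exon_counts=counts
                )
            )
        return out

    tumors = _profiles(n_tumor, "tumor", depleted)
    controls = _profiles(n_control, "control", np.zeros(n_control, dtype=bool))
    labels = pd.Series(depleted, index=[p.sample for p in tumors], name="truly_depleted")
    return tumors, controls, labels
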