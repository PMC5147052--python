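from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import cnvphylo as cp
from cnvphylo import simulate as sim


def make_matrix(values, genes=None, cells=None, **kw):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return cp.ExpressionMatrix(values, pd.Index(genes), pd.Index(cells), **kw)


@dataclass
class PipelineRun:
    config: sim.SimConfig
    truth: sim.SimTruth
    tumor_cpm: cp.ExpressionMatrix
    control_cpm: cp.ExpressionMatrix
    regions: list
    genotypes: cp.GenotypeMatrix


def run_genotyping(config: sim.SimConfig) -> PipelineRun:
    """Simulate tumor + control cells and genotype every cell."""
    truth = sim.simulate_truth(config)
    tumor = cp.cpm_normalize(sim.simulate_cells(truth, config))
    control = cp.cpm_normalize(sim.simulate_controls(config))
    regions = sim.truth_regions(truth)
    ref = cp.ControlReference.from_matrix(control, regions)
    gm = cp.call_genotypes(
        cp.empirical_pvalues(cp.score_regions(tumor, regions), ref)
    )
    return PipelineRun(config, truth, tumor, control, regions, gm)


@pytest.fixture(scope="session")
def small_run() -> PipelineRun:
    """A small but well-powered tumor/control simulation shared by tests."""
    clones = sim.linear_clone_tree(3)
    config = sim.SimConfig(
        n_genes=2000,
        n_regions=3,
        genes_per_region=300,
        clone_tree=clones,
        cells_per_clone=30,
        n_control_cells=80,
        base_mean=1.0,
        region_directions=["gain", "loss", "gain"],
        seed=11,
    )
    return run_genotyping(config)


def bh_oracle(pvals):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q
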