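"""Per-cell CNV genotyping: region scores, empirical p-values, calls,
cross-validated FDR, the smoothed ratio track, and stromal triage."""

import numpy as np
import pandas as pd
import pytest

import cnvphylo as cp
from cnvphylo import simulate as sim
from cnvphylo.genotype import region_label
from cnvphylo.stats import empirical_pvalues_1d

from conftest import bh_oracle, make_matrix, run_genotyping


def segment(genes, direction="gain", start=0, end=1000):
    return cp.CnvSegment(
        chrom="chr1", start=start, end=end, n_exons=len(genes),
        ratio=1.5 if direction == "gain" else 0.5,
        direction=direction, genes=tuple(genes),
    )


class TestScores:
    def test_score_is_sum_of_region_cpm(self):
        m = make_matrix([[100.0], [300.0], [50.0]], norm_state="cpm",
                        library_sizes=np.array([450.0]))
        rsm = cp.score_regions(m, [segment(["g0", "g1"])])
        assert rsm.scores.iloc[0, 0] == pytest.approx(400.0)

    def test_region_without_matrix_genes_flagged(self):
        m = make_matrix([[1.0]], norm_state="cpm", library_sizes=np.array([1.0]))
        seg = segment(["absent1", "absent2"])
        with pytest.warns(UserWarning):
            rsm = cp.score_regions(m, [seg])
        assert rsm.flagged == [region_label(seg)]

    def test_requires_cpm(self):
        with pytest.raises(ValueError, match="CPM"):
            cp.score_regions(make_matrix([[1.0]]), [segment(["g0"])])

    def test_additive_over_merged_regions(self, small_run):
        r = small_run
        parts = [segment([f"gene_{i}" for i in range(0, 50)]),
                 segment([f"gene_{i}" for i in range(50, 100)])]
        whole = [segment([f"gene_{i}" for i in range(100)])]
        s_parts = cp.score_regions(r.tumor_cpm, parts).scores
        s_whole = cp.score_regions(r.tumor_cpm, whole).scores
        np.testing.assert_allclose(
            s_parts.iloc[0] + s_parts.iloc[1], s_whole.iloc[0], rtol=1e-10
        )

    def test_carriers_score_above_noncarriers(self, small_run):
        r = small_run
        rsm = cp.score_regions(r.tumor_cpm, r.regions)
        carriers = r.truth.true_genotypes["region_0"].astype(bool).to_numpy()
        row = rsm.scores.iloc[0].to_numpy()
        assert row[carriers].mean() > row[~carriers].mean()


class TestEmpiricalPvalues:
    def test_loss_score_below_all_controls(self):
        # 19 controls all positive, cell score 0: p = 1/20
        p = empirical_pvalues_1d(np.array([0.0]), np.arange(1, 20, dtype=float), "lower")
        assert p[0] == pytest.approx(1 / 20)

    def test_median_score_is_half(self):
        ref = np.arange(1, 102, dtype=float)
        p = empirical_pvalues_1d(np.array([51.0]), ref, "upper")
        assert p[0] == pytest.approx(0.5, abs=0.01)

    def test_matches_rank_count_oracle(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(size=37)
        vals = rng.normal(size=11)
        for tail, cmp in (("lower", np.less_equal), ("upper", np.greater_equal)):
            got = empirical_pvalues_1d(vals, ref, tail)
            want = [(1 + cmp(ref, v).sum()) / (len(ref) + 1) for v in vals]
            np.testing.assert_allclose(got, want)

    def test_null_pvalues_roughly_uniform(self):
        # unconditional uniformity: a fresh reference per batch (conditional
        # on any single finite reference the p-values are never uniform)
        import scipy.stats

        rng = np.random.default_rng(9)
        p = np.concatenate([
            empirical_pvalues_1d(rng.normal(size=25), rng.normal(size=500), "upper")
            for _ in range(80)
        ])
        assert scipy.stats.kstest(p, "uniform").pvalue > 0.01

    def test_missing_region_in_reference_errors(self, small_run):
        r = small_run
        rsm = cp.score_regions(r.tumor_cpm, r.regions)
        ref = cp.ControlReference.from_matrix(r.control_cpm, r.regions[:2])
        with pytest.raises(ValueError, match="missing"):
            cp.empirical_pvalues(rsm, ref)


class TestCalls:
    def test_single_test(self):
        pv = pd.DataFrame({"r": [0.01]}, index=["cell"])
        gm = cp.call_genotypes(pv, alpha=0.05)
        assert gm.qvals.iloc[0, 0] == pytest.approx(0.01)
        assert bool(gm.calls.iloc[0, 0])

    def test_joint_bh_matches_oracle(self):
        pv = pd.DataFrame(
            [[0.001, 0.2], [0.04, 0.9], [0.03, 0.5]],
            index=list("abc"), columns=["r1", "r2"],
        )
        gm = cp.call_genotypes(pv)
        np.testing.assert_allclose(
            gm.qvals.to_numpy().ravel(), bh_oracle(pv.to_numpy().ravel())
        )

    def test_null_cells_rarely_called(self, small_run):
        r = small_run
        ref = cp.ControlReference.from_matrix(r.control_cpm, r.regions)
        cfg2 = sim.SimConfig(
            n_genes=r.config.n_genes, n_regions=r.config.n_regions,
            genes_per_region=r.config.genes_per_region,
            clone_tree=[sim.Clone("c0", None, frozenset())],
            cells_per_clone=2, n_control_cells=100, base_mean=r.config.base_mean,
            region_directions=list(r.config.region_directions), seed=77,
        )
        nulls = cp.cpm_normalize(sim.simulate_controls(cfg2))
        gm = cp.call_genotypes(
            cp.empirical_pvalues(cp.score_regions(nulls, r.regions), ref)
        )
        assert gm.calls.to_numpy().mean() <= 0.05


class TestCrossvalFdr:
    def test_alpha_one_calls_everything(self, small_run):
        r = small_run
        ctrl = sim.simulate_controls(r.config)
        out = cp.crossval_fdr(ctrl, r.regions, folds=5, alpha=1.0, seed=0)
        assert (out.loc[[f for f in out.index if f != "overall"], "fdr"] == 1.0).all()

    def test_seed_reproducible(self, small_run):
        r = small_run
        ctrl = sim.simulate_controls(r.config)
        a = cp.crossval_fdr(ctrl, r.regions, folds=5, seed=3)
        b = cp.crossval_fdr(ctrl, r.regions, folds=5, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_cells_rejected(self, small_run):
        r = small_run
        cfg = sim.SimConfig(
            n_genes=r.config.n_genes, n_regions=0, genes_per_region=1,
            clone_tree=[sim.Clone("c0", None, frozenset())],
            cells_per_clone=1, n_control_cells=5, seed=1,
        )
        ctrl = sim.simulate_controls(cfg)
        with pytest.raises(ValueError, match="control cells"):
            cp.crossval_fdr(ctrl, r.regions, folds=10)


class TestWaveletTrack:
    def test_cell_equal_to_control_median_is_flat_zero(self, small_run):
        r = small_run
        ctrl = r.control_cpm
        med = np.median(ctrl.values, axis=1)
        m = cp.ExpressionMatrix(
            med[:, None], ctrl.genes, pd.Index(["copycat"]),
            norm_state="cpm", library_sizes=np.array([med.sum()]),
            gene_intervals=ctrl.gene_intervals,
        )
        track = cp.wavelet_smooth_track(m, ctrl)
        np.testing.assert_allclose(track.to_numpy(), 0.0, atol=1e-9)

    def test_gain_block_forms_elevated_plateau(self, small_run):
        r = small_run
        track = cp.wavelet_smooth_track(r.tumor_cpm, r.control_cpm)
        carriers = r.truth.true_genotypes["region_0"].astype(bool).to_numpy()
        gain_genes = [f"gene_{i}" for i in range(300)]
        out_genes = [f"gene_{i}" for i in range(1200, 1500)]
        inside = track.loc[carriers, gain_genes].to_numpy().mean()
        outside = track.loc[carriers, out_genes].to_numpy().mean()
        assert inside > outside + 0.25

    def test_smoothing_preserves_genotype_triage(self, small_run):
        # genotyping re-run on wavelet-denoised expression agrees with the
        # calls on raw CPM for strong-effect data
        from cnvphylo.genotype import wavelet_smooth_expression

        r = small_run
        sm_tumor = wavelet_smooth_expression(r.tumor_cpm)
        sm_ctrl = wavelet_smooth_expression(r.control_cpm)
        ref = cp.ControlReference.from_matrix(sm_ctrl, r.regions)
        gm = cp.call_genotypes(
            cp.empirical_pvalues(cp.score_regions(sm_tumor, r.regions), ref)
        )
        agreement = (
            gm.calls.to_numpy() == r.genotypes.calls.to_numpy()
        ).mean()
        assert agreement >= 0.95


class TestStromal:
    def test_cnv_bearing_cell_is_tumor_regardless_of_clustering(self):
        calls = pd.DataFrame({"r1": [1, 0], "r2": [1, 0], "r3": [1, 0]},
                             index=["a", "b"]).astype(bool)
        gm = cp.GenotypeMatrix(calls, calls * 0.01, calls * 0.01, alpha=0.05)
        m = make_matrix(np.ones((2, 2)), genes=["g1", "g2"], cells=["a", "b"])
        with pytest.warns(UserWarning, match="marker"):
            out = cp.flag_stromal(gm, pd.Series(0, index=["a", "b"]), m, marker_panel=[])
        assert out.loc["a", "label"] == "tumor"
        assert out.loc["b", "label"] == "putative-stromal"

    def test_all_zero_genotypes_all_stromal(self):
        calls = pd.DataFrame(np.zeros((3, 2), bool), index=list("abc"), columns=["r1", "r2"])
        gm = cp.GenotypeMatrix(calls, calls.astype(float), calls.astype(float), 0.05)
        m = make_matrix(np.ones((2, 3)), cells=list("abc"))
        with pytest.warns(UserWarning):
            out = cp.flag_stromal(gm, pd.Series(0, index=list("abc")), m, marker_panel=[])
        assert (out["label"] == "putative-stromal").all()

    def test_spiked_control_cells_recovered(self, small_run):
        r = small_run
        ctrl = r.control_cpm
        spike_cells = list(ctrl.cells[:20])
        spike = ctrl.subset_cells(spike_cells)
        # the marker panel mixes tumor-program genes (here: genes of the
        # gained region, shared across malignant clones) with a stromal
        # program expressed only by the non-malignant spike-ins
        stromal_markers = [f"gene_{i}" for i in range(1000, 1100)]
        tumor_markers = [f"gene_{i}" for i in range(100)]
        markers = tumor_markers + stromal_markers
        spike_vals = spike.values.copy()
        idx = spike.genes.get_indexer(stromal_markers)
        spike_vals[idx, :] = spike_vals[idx, :] + 500.0
        mixed = cp.ExpressionMatrix(
            np.column_stack([r.tumor_cpm.values, spike_vals]),
            r.tumor_cpm.genes,
            pd.Index(list(r.tumor_cpm.cells) + spike_cells),
            norm_state="cpm",
            library_sizes=np.concatenate(
                [r.tumor_cpm.library_sizes, spike.library_sizes]
            ),
            gene_intervals=r.tumor_cpm.gene_intervals,
        )
        ref = cp.ControlReference.from_matrix(
            r.control_cpm.subset_cells(list(ctrl.cells[20:])), r.regions
        )
        gm = cp.call_genotypes(
            cp.empirical_pvalues(cp.score_regions(mixed, r.regions), ref)
        )
        evidence = pd.Series(
            [1] * r.tumor_cpm.n_cells + [0] * 20, index=mixed.cells
        )
        out = cp.flag_stromal(gm, evidence, mixed, marker_panel=markers)
        spiked = out.loc[spike_cells, "label"]
        # the tumor cells of the root clone carry no CNVs but do carry
        # mutation evidence, so only the spiked controls can be stromal
        assert (out.loc[list(r.tumor_cpm.cells), "label"] == "tumor").all()
        assert (spiked == "putative-stromal").mean() >= 0.8
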