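"""Backbone pseudotime, monotone genes, dose-response ranking, gene
prefiltering, submatrix export, and subtype classifiers."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import cnvphylo as cp
from cnvphylo.phylogeny import GenotypeClass

from conftest import make_matrix


def chain_calls(counts=(5, 5, 5)):
    """Cells for a linear 3-class chain {} -> {r1} -> {r1,r2}... wait the
    first class carries r1 so the chain is {r1} -> {r1,r2} -> {r1,r2,r3}."""
    rows, idx = [], []
    for k, n in enumerate(counts, start=1):
        for i in range(n):
            idx.append(f"k{k}_{i}")
            rows.append([1 if j <= k else 0 for j in range(1, 4)])
    return pd.DataFrame(rows, index=idx, columns=["r1", "r2", "r3"])


class TestBackbone:
    def test_linear_chain_bins_one_class_each(self):
        calls = chain_calls()
        tree = cp.build_clone_phylogeny(calls)
        classes, _ = cp.collapse_genotypes(calls)
        path = cp.backbone_path(tree, classes)
        assert [path.bin_of[c.name] for c in path.classes] == ["early", "mid", "late"]
        assert all(len(a) >= 1 for a in path.acquired[1:])

    def test_fork_follows_larger_clade(self):
        # shared founder region r1, then a fork: r2 carried by 40 cells,
        # r3 by 10 — the backbone must follow the r2 clade
        rows, idx = [], []
        for i in range(10):
            idx.append(f"base{i}"); rows.append([1, 0, 0])
        for i in range(40):
            idx.append(f"big{i}"); rows.append([1, 1, 0])
        for i in range(10):
            idx.append(f"small{i}"); rows.append([1, 0, 1])
        calls = pd.DataFrame(rows, index=idx, columns=["r1", "r2", "r3"])
        tree = cp.build_clone_phylogeny(calls)
        classes, _ = cp.collapse_genotypes(calls)
        path = cp.backbone_path(tree, classes)
        genotypes = [c.genotype for c in path.classes]
        assert frozenset({"r1", "r2"}) in genotypes
        assert frozenset({"r1", "r3"}) not in genotypes


class TestMonotone:
    def bins(self):
        return {
            "early": ["e0", "e1", "e2"],
            "mid": ["m0", "m1", "m2"],
            "late": ["l0", "l1", "l2"],
        }

    def matrix(self, early, mid, late):
        vals = np.array(list(early) + list(mid) + list(late)).reshape(1, 9)
        cells = self.bins()["early"] + self.bins()["mid"] + self.bins()["late"]
        return make_matrix(vals, genes=["g"], cells=cells, norm_state="cpm",
                           library_sizes=np.ones(9))

    def test_strictly_increasing_detected(self):
        m = self.matrix([1, 1, 1], [5, 5, 5], [9, 9, 9])
        hits, table = cp.monotone_genes(m, self.bins(), "increasing")
        assert hits == ["g"]
        assert table.loc["g", "mean_mid"] == pytest.approx(5.0)

    def test_non_monotone_rejected(self):
        m = self.matrix([1, 1, 1], [9, 9, 9], [5, 5, 5])
        hits, _ = cp.monotone_genes(m, self.bins(), "increasing")
        assert hits == []
        hits_dec, _ = cp.monotone_genes(m, self.bins(), "decreasing")
        assert hits_dec == []

    def test_decreasing_direction(self):
        m = self.matrix([9, 9, 9], [5, 5, 5], [1, 1, 1])
        hits, _ = cp.monotone_genes(m, self.bins(), "decreasing")
        assert hits == ["g"]

    def test_needs_two_populated_bins(self):
        m = self.matrix([1, 1, 1], [5, 5, 5], [9, 9, 9])
        with pytest.raises(ValueError, match="bins"):
            cp.monotone_genes(m, {"early": ["e0", "e1"], "mid": ["m0"]}, "increasing")


class TestDoseResponse:
    def toy(self):
        rng = np.random.default_rng(0)
        focal = np.array([1.0, 2, 3, 4, 5, 6])
        copy = focal * 10
        reverse = focal[::-1].copy()
        noise = rng.uniform(0.0, 10.0, size=(20, 6))
        vals = np.vstack([focal, copy, reverse, noise])
        genes = ["focal", "copycat", "reversed"] + [f"n{i}" for i in range(20)]
        return make_matrix(vals, genes=genes, norm_state="cpm",
                           library_sizes=np.ones(6))

    def test_copy_of_focal_tops_positive_set(self):
        res = cp.dose_response(self.toy(), "focal", tail=0.05, min_expressing_cells=3)
        assert res.table.loc["copycat", "rho"] == pytest.approx(1.0)
        assert "copycat" in res.positive_set

    def test_reversed_ranks_bottom_negative_set(self):
        res = cp.dose_response(self.toy(), "focal", tail=0.05, min_expressing_cells=3)
        assert res.table.loc["reversed", "rho"] == pytest.approx(-1.0)
        assert "reversed" in res.negative_set

    def test_set_sizes_are_ceil_of_tail(self):
        res = cp.dose_response(self.toy(), "focal", tail=0.2, min_expressing_cells=3)
        import math

        want = math.ceil(0.2 * res.table["rho"].notna().sum())
        assert len(res.positive_set) == len(res.negative_set) == want

    def test_matches_spearman_oracle_on_six_cells(self):
        m = self.toy()
        res = cp.dose_response(m, "focal", min_expressing_cells=3)
        focal = m.values[0]
        for gene in ["copycat", "reversed", "n0", "n7"]:
            want = scipy.stats.spearmanr(m.values[m.genes.get_loc(gene)], focal).statistic
            assert res.table.loc[gene, "rho"] == pytest.approx(want)

    def test_constant_focal_rejected(self):
        m = make_matrix(np.ones((2, 12)), norm_state="cpm", library_sizes=np.ones(12))
        with pytest.raises(ValueError, match="constant"):
            cp.dose_response(m, "g0")


class TestDeGeneFilter:
    def test_boundary_and_hand_count(self):
        # 10 cells; gene rows with CPM >= 1 in {0, 2, 3, 10} cells
        vals = np.zeros((4, 10))
        vals[1, :2] = 5
        vals[2, :3] = 5  # low in 70% of cells: retained
        vals[3, :] = 5
        m = make_matrix(vals, norm_state="cpm", library_sizes=np.ones(10))
        kept = cp.de_gene_filter(m)
        # g1 is low in exactly 80% of cells: the rule drops only "more
        # than 80%", so g1 stays
        assert kept == ["g1", "g2", "g3"]

    def test_quarter_expressed_gene_retained(self):
        vals = np.zeros((1, 20))
        vals[0, :5] = 2.0  # >= 1 CPM in 25% of cells -> low in 75% <= 80%
        m = make_matrix(vals, norm_state="cpm", library_sizes=np.ones(20))
        assert cp.de_gene_filter(m) == ["g0"]


class TestExport:
    def test_partition_and_bit_exact_counts(self):
        m = make_matrix(np.arange(12).reshape(2, 6), cells=list("abcdef"))
        calls = pd.DataFrame(
            {"r1": [1, 1, 1, 0, 0, 0]}, index=list("abcdef")
        ).astype(bool)
        groups, manifest = cp.export_clone_submatrices(m, calls, grouping="r1")
        assert set(groups) == {"carrier", "wildtype"}
        np.testing.assert_array_equal(groups["carrier"].values, m.values[:, :3])
        cells = sorted(sum((list(g.cells) for g in groups.values()), []))
        assert cells == list("abcdef")
        assert sorted(manifest["cell"]) == list("abcdef")
        assert manifest.groupby("group")["cell"].count().sum() == 6

    def test_small_group_warns(self):
        m = make_matrix(np.ones((1, 3)), cells=list("abc"))
        calls = pd.DataFrame({"r1": [1, 0, 0]}, index=list("abc")).astype(bool)
        with pytest.warns(UserWarning, match="fewer than 2"):
            cp.export_clone_submatrices(m, calls, grouping="r1")


def toy_centroids(rng=None):
    rng = rng or np.random.default_rng(5)
    genes = [f"s{i}" for i in range(30)]
    data = rng.normal(size=(30, 4))
    return pd.DataFrame(data, index=genes,
                        columns=["proneural", "neural", "classical", "mesenchymal"])


class TestVerhaak:
    def centroid_cell(self, centroids, col, sign=1.0):
        # a cell whose log-profile reproduces one centroid exactly
        log_expr = sign * centroids[col].to_numpy()
        cpm = np.exp2(5 + log_expr) - 1  # invert log2(cpm+1) up to affine shift
        return cpm

    def test_cell_equal_to_centroid_labeled_accordingly(self):
        cen = toy_centroids()
        vals = np.column_stack([self.centroid_cell(cen, c) for c in cen.columns])
        m = make_matrix(vals, genes=list(cen.index), cells=list(cen.columns),
                        norm_state="cpm", library_sizes=np.ones(4))
        out = cp.verhaak_classify(m, cen)
        assert list(out["label"]) == list(cen.columns)
        assert out.loc["proneural", "coef_proneural"] == pytest.approx(1.0, abs=0.05)

    def test_negated_centroid_same_label_by_magnitude(self):
        cen = toy_centroids()
        vals = self.centroid_cell(cen, "classical", sign=-1.0)[:, None]
        m = make_matrix(vals, genes=list(cen.index), cells=["anti"],
                        norm_state="cpm", library_sizes=np.ones(1))
        out = cp.verhaak_classify(m, cen)
        assert out.loc["anti", "label"] == "classical"
        assert out.loc["anti", "coef_classical"] < 0

    def test_matches_normal_equations_on_five_genes(self):
        rng = np.random.default_rng(2)
        cen = pd.DataFrame(rng.normal(size=(5, 4)), index=[f"s{i}" for i in range(5)],
                           columns=list("ABCD"))
        vals = rng.uniform(1, 100, size=(5, 1))
        m = make_matrix(vals, genes=list(cen.index), cells=["c"],
                        norm_state="cpm", library_sizes=np.ones(1))
        out = cp.verhaak_classify(m, cen, min_genes=5)
        X = np.column_stack([
            (cen[c] - cen[c].mean()) / cen[c].std(ddof=0) for c in cen.columns
        ])
        y = np.log2(vals[:, 0] + 1)
        y = (y - y.mean()) / y.std(ddof=0)
        want = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(out.iloc[0, 1:].to_numpy(dtype=float), want, atol=1e-8)

    def test_invariant_to_raw_count_scaling(self):
        cen = toy_centroids()
        rng = np.random.default_rng(3)
        raw = rng.integers(0, 50, size=(30, 6))
        a = cp.verhaak_classify(cp.cpm_normalize(make_matrix(raw, genes=list(cen.index))), cen)
        b = cp.verhaak_classify(cp.cpm_normalize(make_matrix(raw * 7, genes=list(cen.index))), cen)
        assert list(a["label"]) == list(b["label"])

    def test_rank_deficient_centroids_rejected(self):
        cen = toy_centroids()
        cen["neural"] = cen["proneural"]
        m = make_matrix(np.ones((30, 1)) + np.arange(30)[:, None],
                        genes=list(cen.index), norm_state="cpm",
                        library_sizes=np.ones(1))
        with pytest.raises(ValueError, match="rank"):
            cp.verhaak_classify(m, cen)


class TestSunClassifier:
    def matrix_with_module_means(self, a_log, b_log):
        vals = np.array([[2**a_log - 1], [2**a_log - 1], [2**b_log - 1], [2**b_log - 1]])
        return make_matrix(vals, genes=["a1", "a2", "b1", "b2"], norm_state="cpm",
                           library_sizes=np.ones(1))

    def test_clear_module_dominance(self):
        m = self.matrix_with_module_means(4.0, 1.0)
        out = cp.sun_classify(m, ["a1", "a2"], ["b1", "b2"])
        assert out["label"].iloc[0] == "PDGFRA-module"

    def test_less_than_twofold_is_ambiguous(self):
        m = self.matrix_with_module_means(3.0, 2.0)
        out = cp.sun_classify(m, ["a1", "a2"], ["b1", "b2"])
        assert out["label"].iloc[0] == "ambiguous"

    def test_equal_means_ambiguous(self):
        m = self.matrix_with_module_means(2.0, 2.0)
        out = cp.sun_classify(m, ["a1", "a2"], ["b1", "b2"])
        assert out["label"].iloc[0] == "ambiguous"

    def test_empty_module_rejected(self):
        m = self.matrix_with_module_means(2.0, 2.0)
        with pytest.raises(ValueError, match="empty"):
            cp.sun_classify(m, ["zz"], ["b1"])
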