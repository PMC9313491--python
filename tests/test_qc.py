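"""QC thresholds, normalization, HVG selection, clustering, annotation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from pvn import qc as qc_mod
from pvn.containers import CellAnnotation, ExpressionMatrix

from conftest import make_count_matrix


def _expr(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    meta = pd.DataFrame({"condition": "mono"}, index=pd.Index(cells))
    return ExpressionMatrix(values, pd.Index(genes), pd.Index(cells), meta)


class TestQCFilter:
    def _matrix(self):
        # 300 genes x 3 cells: cell 0 detects 150 genes, cells 1-2 detect 250
        counts = np.zeros((300, 3), dtype=int)
        counts[:150, 0] = 1
        counts[:250, 1] = 1
        counts[:250, 2] = 2
        return make_count_matrix(counts)

    def test_cell_below_min_genes_removed(self):
        out, report = qc_mod.qc_filter(self._matrix(), min_genes=200, min_cells=1)
        assert "c0" not in out.cell_ids
        assert report.n_cells_removed_min_genes == 1

    def test_mito_boundary_is_strict_greater(self):
        counts = np.array([[18, 19], [82, 81]])
        m = make_count_matrix(counts, genes=["MT-CO1", "ACTB"])
        out, report = qc_mod.qc_filter(m, min_genes=1, min_cells=1, max_mito=0.18)
        # 18% exactly is retained; 19% is removed
        assert list(out.cell_ids) == ["c0"]
        assert report.n_cells_removed_mito == 1

    def test_gene_prevalence_boundary(self):
        counts = np.zeros((2, 210), dtype=int)
        counts[0, :2] = 1   # detected in 2 cells -> removed
        counts[1, :3] = 1   # detected in 3 cells -> retained
        counts += np.eye(2, 210, dtype=int) * 0  # keep ints
        # give every cell enough detected genes to survive the cell filter
        m = make_count_matrix(counts)
        out, _ = qc_mod.qc_filter(m, min_genes=0, min_cells=3)
        assert list(out.gene_ids) == ["g1"]

    def test_all_cells_removed_raises(self):
        m = make_count_matrix(np.ones((5, 3), dtype=int))
        with pytest.raises(ValueError, match="every cell"):
            qc_mod.qc_filter(m, min_genes=100)

    def test_idempotent(self, small_experiment):
        m = small_experiment["tri"]
        once, _ = qc_mod.qc_filter(m)
        twice, report = qc_mod.qc_filter(once)
        assert twice.equals(once)
        assert report.n_cells_out == once.n_cells


class TestNormalizeLog:
    def test_closed_form(self):
        m = make_count_matrix([[2], [2]])
        e = qc_mod.normalize_log(m, target_sum=4, regress_covariates=False)
        assert np.allclose(e.values, np.log(3.0))

    def test_all_equal_matrix_stays_equal(self):
        m = make_count_matrix(np.full((4, 5), 3, dtype=int))
        e = qc_mod.normalize_log(m, target_sum=100, regress_covariates=False)
        assert np.allclose(e.values, e.values[0, 0])

    def test_column_sums_hit_target(self):
        rng = np.random.default_rng(0)
        m = make_count_matrix(rng.poisson(2.0, size=(30, 10)) + 1)
        e = qc_mod.normalize_log(m, target_sum=1e4, regress_covariates=False)
        assert np.allclose(np.expm1(e.values).sum(axis=0), 1e4)

    def test_zero_total_cell_raises(self):
        m = make_count_matrix([[0, 1], [0, 2]])
        with pytest.raises(ValueError, match="zero-total"):
            qc_mod.normalize_log(m)

    def test_regressed_copy_is_separate(self, small_experiment):
        filtered, _ = qc_mod.qc_filter(small_experiment["tri"])
        e = qc_mod.normalize_log(filtered, regress_covariates=True)
        assert e.pca_values is not None
        assert not np.allclose(e.pca_values, e.values)
        # the DE-facing values are plain log1p of the scaled counts
        assert e.values.min() >= 0


class TestSelectHVG:
    def test_clamps_to_available_genes(self):
        e = _expr(np.random.default_rng(0).normal(1, 0.2, size=(10, 20)))
        out = qc_mod.select_hvg(e, n_top=4000)
        assert out.hvg_mask.sum() == 10

    def test_constant_gene_never_beats_variable_gene(self):
        rng = np.random.default_rng(1)
        vals = np.vstack([np.full(50, 2.0), rng.normal(2.0, 0.5, size=(1, 50))])
        out = qc_mod.select_hvg(_expr(vals), n_top=1)
        assert out.hvg_mask.tolist() == [False, True]

    def test_planted_high_variance_genes_rank_top(self):
        rng = np.random.default_rng(2)
        base = rng.normal(1.0, 0.1, size=(500, 80)).clip(min=0)
        planted = rng.normal(1.0, 1.0, size=(5, 80)).clip(min=0)
        vals = np.vstack([base, planted])
        out = qc_mod.select_hvg(_expr(vals), n_top=5)
        assert out.hvg_mask[-5:].all()


class TestClusterSNN:
    def _blobs(self, seed=0, n=120, sep=8.0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(20, n))
        b = rng.normal(sep, 1, size=(20, n))
        vals = np.concatenate([a, b], axis=1)
        return _expr(vals), np.array([0] * n + [1] * n)

    def test_two_blobs_recovered_exactly(self):
        e, truth = self._blobs()
        ann = qc_mod.cluster_snn(e, n_pcs=5, resolution=0.2, seed=0)
        assert adjusted_rand_score(truth, ann.cluster) == 1.0
        assert len(np.unique(ann.cluster)) == 2

    def test_same_seed_identical_labels(self):
        e, _ = self._blobs(seed=3)
        a = qc_mod.cluster_snn(e, n_pcs=5, seed=42)
        b = qc_mod.cluster_snn(e, n_pcs=5, seed=42)
        assert np.array_equal(a.cluster, b.cluster)

    def test_too_few_cells_raises(self):
        e = _expr(np.random.default_rng(0).normal(size=(5, 10)))
        with pytest.raises(ValueError, match="k_neighbors"):
            qc_mod.cluster_snn(e, k_neighbors=15)


class TestAnnotateClusters:
    def _expr_with_markers(self, frac_pecam=0.9):
        # cluster 0: PECAM1-high; cluster 1: S100B-high; cluster 2: nothing
        rng = np.random.default_rng(0)
        n = 30
        vals = rng.uniform(0, 0.05, size=(4, 3 * n))
        genes = ["PECAM1", "S100B", "CDKN2A", "OTHER"]
        vals[0, :n] = 0.0
        expressed = rng.random(n) < frac_pecam
        vals[0, :n][expressed] = 2.0
        vals[1, n:2 * n] = 3.0
        e = _expr(vals, genes=genes)
        clusters = CellAnnotation(e.cell_ids, np.repeat([0, 1, 2], n))
        return e, clusters

    def test_marker_dominated_cluster_labeled(self):
        e, clusters = self._expr_with_markers()
        ann = qc_mod.annotate_clusters(e, clusters)
        assert set(ann.label[clusters.cluster == 0]) == {"EC"}
        assert set(ann.label[clusters.cluster == 1]) == {"astrocyte"}

    def test_markerless_cluster_is_unknown(self):
        e, clusters = self._expr_with_markers()
        ann = qc_mod.annotate_clusters(e, clusters)
        assert set(ann.label[clusters.cluster == 2]) == {"unknown"}

    def test_low_expressing_fraction_is_unknown(self):
        e, clusters = self._expr_with_markers(frac_pecam=0.3)
        ann = qc_mod.annotate_clusters(e, clusters)
        assert set(ann.label[clusters.cluster == 0]) == {"unknown"}

    def test_missing_marker_gene_raises(self):
        e, clusters = self._expr_with_markers()
        with pytest.raises(KeyError, match="NES"):
            qc_mod.annotate_clusters(e, clusters, markers={"GSC": "NES"})

    def test_cluster_relabeling_does_not_change_types(self):
        e, clusters = self._expr_with_markers()
        ann1 = qc_mod.annotate_clusters(e, clusters)
        permuted = CellAnnotation(e.cell_ids, 2 - clusters.cluster)
        ann2 = qc_mod.annotate_clusters(e, permuted)
        assert np.array_equal(ann1.label, ann2.label)

    def test_one_cluster_per_label(self):
        # two PECAM1-high clusters: only the higher-fraction one keeps "EC"
        rng = np.random.default_rng(1)
        n = 25
        vals = rng.uniform(0, 0.05, size=(3, 2 * n))
        genes = ["PECAM1", "S100B", "CDKN2A"]
        vals[0, :n][rng.random(n) < 0.95] += 2.0
        vals[0, n:][rng.random(n) < 0.6] += 2.0
        e = _expr(vals, genes=genes)
        clusters = CellAnnotation(e.cell_ids, np.repeat([0, 1], n))
        ann = qc_mod.annotate_clusters(e, clusters)
        assert set(ann.label[clusters.cluster == 0]) == {"EC"}
        assert set(ann.label[clusters.cluster == 1]) == {"unknown"}


class TestMarkerDE:
    def test_boosted_marker_found(self, small_experiment):
        gt = small_experiment["gt"]
        tri = small_experiment["tri"]
        e = qc_mod.normalize_log(tri, regress_covariates=False)
        truth_codes = pd.Categorical(gt.cell_types_tri).codes
        clusters = CellAnnotation(e.cell_ids, truth_codes)
        markers = qc_mod.marker_de(e, clusters)
        ec_cluster = truth_codes[gt.cell_types_tri == "EC"][0]
        assert "PECAM1" in markers[int(ec_cluster)].index

    def test_identical_clusters_have_no_markers(self):
        vals = np.tile(np.linspace(0, 1, 20), (6, 2))
        e = _expr(vals)
        clusters = CellAnnotation(e.cell_ids, np.repeat([0, 1], 20))
        markers = qc_mod.marker_de(e, clusters)
        assert all(len(t) == 0 for t in markers.values())

    def test_single_cluster_raises(self):
        e = _expr(np.ones((3, 10)))
        clusters = CellAnnotation(e.cell_ids, np.zeros(10, dtype=int))
        with pytest.raises(ValueError, match="two clusters"):
            qc_mod.marker_de(e, clusters)
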