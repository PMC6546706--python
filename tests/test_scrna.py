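"""Single-cell pipeline stages: filters, normalization, PCA, jackstraw,
clustering and marker detection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from myoconnect import scrna
from myoconnect.scrna import (ClusterLabels, CountMatrix, JackstrawConfig,
                              NormalizedMatrix, cluster_cells, filter_cells,
                              filter_genes, find_markers, find_variable_genes,
                              jackstraw_select_pcs, log_normalize, run_pca)
from myoconnect.synthetic import ExprSimParams, generate_expression_dataset


def _noise_matrix(n_genes, n_cells, seed):
    rng = np.random.default_rng(seed)
    return NormalizedMatrix(values=np.abs(rng.normal(size=(n_genes, n_cells))),
                            gene_ids=[f"g{i}" for i in range(n_genes)],
                            cell_ids=[f"c{i}" for i in range(n_cells)])


class TestFilters:
    def test_gene_filter_hand_enumeration(self, toy_counts):
        out = filter_genes(toy_counts)
        assert out.gene_ids == ["g0", "g3", "g5"]
        assert out.cell_ids == toy_counts.cell_ids

    def test_gene_filter_idempotent(self, toy_counts):
        once = filter_genes(toy_counts)
        twice = filter_genes(once)
        assert twice.gene_ids == once.gene_ids
        np.testing.assert_array_equal(twice.counts, once.counts)

    def test_cell_filter_boundary(self, toy_counts):
        filtered = filter_genes(toy_counts)
        # c0 and c2 express exactly 3 genes; others express 2
        out = filter_cells(filtered, min_genes=3)
        assert out.cell_ids == ["c0", "c2"]
        assert filter_cells(filtered, min_genes=0).cell_ids == filtered.cell_ids

    def test_cell_filter_all_removed_raises(self, toy_counts):
        with pytest.raises(ValueError, match="threshold"):
            filter_cells(toy_counts, min_genes=100)

    def test_filter_pair_is_fixed_point(self, toy_counts):
        once = filter_cells(filter_genes(toy_counts), min_genes=2)
        twice = filter_cells(filter_genes(once), min_genes=2)
        assert twice.gene_ids == once.gene_ids
        assert twice.cell_ids == once.cell_ids


class TestLogNormalize:
    def test_closed_form_entry(self):
        # count 5 in a cell of total 5000 -> ln(1 + 5 * 10000/5000) = ln(11)
        counts = np.zeros((2, 1), dtype=int)
        counts[0, 0] = 5
        counts[1, 0] = 4995
        m = CountMatrix(counts=counts, gene_ids=["a", "b"], cell_ids=["c"])
        nm = log_normalize(m)
        assert nm.values[0, 0] == pytest.approx(np.log(11.0), abs=1e-12)

    def test_zero_count_maps_to_zero(self):
        m = CountMatrix(counts=np.array([[0, 3], [5, 2]]),
                        gene_ids=["a", "b"], cell_ids=["c", "d"])
        assert log_normalize(m).values[0, 0] == 0.0

    def test_per_cell_identity(self, rng):
        counts = rng.poisson(3.0, size=(40, 25))
        counts[0] += 1  # no zero-total cells
        m = CountMatrix(counts=counts,
                        gene_ids=[f"g{i}" for i in range(40)],
                        cell_ids=[f"c{i}" for i in range(25)])
        nm = log_normalize(m)
        totals = np.expm1(nm.values).sum(axis=0)
        np.testing.assert_allclose(totals, 10000.0, rtol=1e-8)

    def test_zero_total_cell_named_in_error(self):
        m = CountMatrix(counts=np.array([[1, 0], [1, 0]]),
                        gene_ids=["a", "b"], cell_ids=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            log_normalize(m)


class TestVariableGenes:
    def test_constant_matrix_selects_none(self):
        nm = NormalizedMatrix(values=np.full((30, 10), 0.5),
                              gene_ids=[f"g{i}" for i in range(30)],
                              cell_ids=[f"c{i}" for i in range(10)])
        assert len(find_variable_genes(nm)) == 0

    def test_planted_variance_outlier_ranks_first(self, rng):
        values = rng.normal(1.0, 0.2, size=(100, 80))
        values[37] = rng.normal(1.0, 2.0, size=80)  # 10x inflated sd
        nm = NormalizedMatrix(values=np.abs(values),
                              gene_ids=[f"g{i}" for i in range(100)],
                              cell_ids=[f"c{i}" for i in range(80)])
        table = find_variable_genes(nm)
        assert table.gene.iloc[0] == "g37"

    def test_null_selection_rate_near_normal_tail(self, rng):
        # identically distributed genes: z > 1 should select ~16%
        counts = rng.poisson(5.0, size=(1000, 200))
        m = CountMatrix(counts=counts,
                        gene_ids=[f"g{i}" for i in range(1000)],
                        cell_ids=[f"c{i}" for i in range(200)])
        nm = log_normalize(filter_genes(m))
        frac = len(find_variable_genes(nm)) / nm.n_genes
        assert 0.08 <= frac <= 0.26

    def test_fewer_genes_than_bins_warns(self):
        nm = _noise_matrix(8, 30, seed=0)
        with pytest.warns(UserWarning, match="bins"):
            find_variable_genes(nm, n_bins=20)


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=50)
        v = rng.normal(size=30)
        nm = NormalizedMatrix(values=np.abs(np.outer(u, v)),
                              gene_ids=[f"g{i}" for i in range(50)],
                              cell_ids=[f"c{i}" for i in range(30)])
        pca = run_pca(nm, n_pcs=5)
        assert pca.variance_explained[0] > 0.95

    def test_full_reconstruction(self, rng):
        nm = _noise_matrix(20, 15, seed=3)
        pca = run_pca(nm, n_pcs=15)
        scaled = scrna._scale_genes(nm.values)
        recon = pca.embedding @ pca.loadings.T
        np.testing.assert_allclose(recon, scaled.T, atol=1e-8)

    def test_sign_convention_deterministic(self, rng):
        nm = _noise_matrix(25, 18, seed=5)
        a = run_pca(nm, n_pcs=6)
        b = run_pca(nm, n_pcs=6)
        np.testing.assert_array_equal(a.loadings, b.loadings)
        for j in range(6):
            col = a.loadings[:, j]
            assert col[np.abs(col).argmax()] > 0

    def test_unknown_gene_rejected_and_npcs_reduced(self):
        nm = _noise_matrix(10, 8, seed=1)
        with pytest.raises(KeyError):
            run_pca(nm, genes=["nope"])
        with pytest.warns(UserWarning, match="reduced"):
            pca = run_pca(nm, n_pcs=50)
        assert pca.n_pcs == 8


class TestJackstraw:
    def test_alpha_one_returns_all(self):
        nm = _noise_matrix(60, 40, seed=2)
        pca = run_pca(nm, n_pcs=5)
        cfg = JackstrawConfig(alpha=1.0, n_replicates=10, n_pcs_tested=5,
                              seed=0)
        sig, p = jackstraw_select_pcs(nm, pca, cfg)
        assert sig == [0, 1, 2, 3, 4]
        assert len(p) == 5

    def test_planted_factor_recovered(self):
        rng = np.random.default_rng(11)
        X = 5 * np.outer(rng.normal(size=300), rng.normal(size=150))
        X += rng.normal(size=(300, 150))
        nm = NormalizedMatrix(values=np.abs(X),
                              gene_ids=[f"g{i}" for i in range(300)],
                              cell_ids=[f"c{i}" for i in range(150)])
        pca = run_pca(nm, n_pcs=10)
        cfg = JackstrawConfig(n_replicates=50, seed=7, n_pcs_tested=10)
        sig, p = jackstraw_select_pcs(nm, pca, cfg)
        assert 0 in sig
        assert 4 not in sig  # nothing beyond the planted rank

    def test_noise_declares_none_at_default_alpha(self):
        nm = _noise_matrix(300, 150, seed=21)
        pca = run_pca(nm, n_pcs=10)
        sig, _ = jackstraw_select_pcs(
            nm, pca, JackstrawConfig(n_replicates=50, seed=3,
                                     n_pcs_tested=10))
        assert sig == []

    def test_type_one_error_binomially_consistent(self):
        # over 20 seeded null runs, false positives at alpha=0.05 should be
        # consistent with a Binomial(200, 0.05): central 99.9% interval
        fp = total = 0
        for s in range(20):
            nm = _noise_matrix(300, 150, seed=1000 + s)
            pca = run_pca(nm, n_pcs=10)
            _, p = jackstraw_select_pcs(
                nm, pca, JackstrawConfig(n_replicates=30, seed=s,
                                         n_pcs_tested=10))
            fp += int((p < 0.05).sum())
            total += len(p)
        from scipy.stats import binom
        lo, hi = binom.ppf([0.0005, 0.9995], total, 0.05)
        assert lo <= fp <= hi

    def test_few_replicates_warns(self):
        nm = _noise_matrix(40, 30, seed=0)
        pca = run_pca(nm, n_pcs=3)
        with pytest.warns(UserWarning, match="replicates"):
            jackstraw_select_pcs(nm, pca,
                                 JackstrawConfig(n_replicates=5, seed=0,
                                                 n_pcs_tested=3))


class TestClustering:
    @staticmethod
    def _blobs(rng, centers, n_per, sd):
        pts = np.concatenate([
            rng.normal(c, sd, size=(n_per, len(c))) for c in centers])
        truth = np.repeat(np.arange(len(centers)), n_per)
        return pts, truth

    def test_three_separated_blobs_exact_recovery(self, rng):
        centers = [(0, 0), (10, 0), (0, 10)]  # separation 10x the within-sd
        pts, truth = self._blobs(rng, centers, 40, sd=1.0)
        labels = cluster_cells(pts, seed=0)
        assert labels.n_clusters == 3
        assert adjusted_rand_score(truth, labels.assignments) == 1.0

    def test_single_blob_low_resolution(self, rng):
        pts, _ = self._blobs(rng, [(0.0, 0.0)], 60, sd=1.0)
        labels = cluster_cells(pts, resolution=0.1, seed=0)
        assert labels.n_clusters == 1

    def test_same_seed_identical_labels(self, rng):
        pts, _ = self._blobs(rng, [(0, 0), (6, 0)], 50, sd=1.0)
        a = cluster_cells(pts, seed=42)
        b = cluster_cells(pts, seed=42)
        assert a.assignments.equals(b.assignments)

    def test_labels_contiguous_and_size_ordered(self, rng):
        pts, _ = self._blobs(rng, [(0, 0), (12, 0), (0, 12)], 30, sd=1.0)
        labels = cluster_cells(pts, seed=1)
        sizes = labels.assignments.value_counts().sort_index()
        assert list(sizes.index) == list(range(labels.n_clusters))
        assert (sizes.values == sorted(sizes.values, reverse=True)).all()

    def test_small_n_reduces_k_with_warning(self, rng):
        pts = rng.normal(size=(8, 2))
        with pytest.warns(UserWarning, match="k_neighbors"):
            cluster_cells(pts, k_neighbors=20, seed=0)

    def test_recovery_on_synthetic_nb_dataset(self):
        m, truth_labels, _ = generate_expression_dataset(
            ExprSimParams(seed=42))
        filtered = filter_cells(filter_genes(m), min_genes=50)
        nm = log_normalize(filtered)
        pca = run_pca(nm, n_pcs=10)
        labels = cluster_cells(pca.embedding, seed=0, cell_ids=nm.cell_ids)
        ari = adjusted_rand_score(
            truth_labels.reindex(nm.cell_ids), labels.assignments)
        assert ari >= 0.9


class TestFindMarkers:
    def test_threshold_contract_and_sorting(self):
        m, labels, _ = generate_expression_dataset(
            ExprSimParams(n_clusters=2, cells_per_cluster=60, n_genes=100,
                          seed=5))
        nm = log_normalize(m)
        table = find_markers(nm, labels)
        assert (table.log_fc.abs() >= 0.25).all()
        for _, sub in table.groupby("cluster"):
            assert sub.p_adjusted.is_monotonic_increasing

    def test_planted_markers_recovered(self):
        p = ExprSimParams(n_clusters=3, cells_per_cluster=200, n_genes=200,
                          marker_genes_per_cluster=8,
                          marker_log_fold_change=1.0, seed=8)
        m, labels, truth = generate_expression_dataset(p)
        nm = log_normalize(m)
        table = find_markers(nm, labels)
        hits = table[(table.p_adjusted < 0.05) & (table.log_fc > 0)]
        planted = {(g, k) for k, gs in truth.marker_genes.items() for g in gs}
        found = set(zip(hits.gene, hits.cluster))
        recall = len(planted & found) / len(planted)
        precision = len(planted & found) / len(found)
        assert recall == 1.0
        assert precision >= 0.9

    def test_permuted_labels_control_false_positives(self):
        m, labels, _ = generate_expression_dataset(
            ExprSimParams(n_clusters=3, cells_per_cluster=100, n_genes=200,
                          seed=13))
        nm = log_normalize(m)
        rng = np.random.default_rng(0)
        shuffled = pd.Series(rng.permutation(labels.to_numpy()),
                             index=labels.index)
        table = find_markers(nm, shuffled)
        n_fp = (table.p_adjusted < 0.05).sum() if len(table) else 0
        assert n_fp / nm.n_genes <= 0.05 + 0.03

    def test_single_cluster_rejected(self):
        nm = _noise_matrix(10, 6, seed=0)
        labels = pd.Series(0, index=nm.cell_ids)
        with pytest.raises(ValueError, match="2 clusters"):
            find_markers(nm, labels)
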