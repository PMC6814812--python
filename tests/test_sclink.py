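"""Single-cell stage: QC gates, normalization, markers, clonotype linking."""

import numpy as np
import pytest

from tcrshare import (
    QcConfig,
    ScDataset,
    cluster_composition,
    find_markers,
    link_clonotypes,
    log_normalize,
    qc_filter,
)
from tcrshare.sclink import read_sc_dataset, write_sc_dataset


def toy_dataset(counts, mito=(), clusters=None, clonotypes=None, strain="Sf"):
    counts = np.asarray(counts, dtype=int)
    n_genes, n_cells = counts.shape
    return ScDataset(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(n_genes)],
        barcodes=[f"c{j}" for j in range(n_cells)],
        mito_genes=set(mito),
        cluster_label=clusters,
        clonotype=clonotypes,
        strain=strain,
    )


class TestQcFilter:
    def test_gene_filter_boundary_three_cells(self):
        # gene 0 detected in 3 cells (kept), gene 1 in 2 cells (removed)
        counts = np.array([[1, 1, 1, 0], [1, 1, 0, 0], [5, 5, 5, 5]])
        cfg = QcConfig(min_genes_per_cell=1, max_genes_per_cell=10)
        out = qc_filter(toy_dataset(counts), cfg)
        assert out.gene_ids == ["g0", "g2"]

    def test_cell_gene_count_bounds_inclusive(self):
        rng = np.random.default_rng(0)
        n_genes = 3000
        counts = np.zeros((n_genes, 4), dtype=int)
        for j, n_detected in enumerate([200, 199, 2500, 2501]):
            genes = rng.choice(n_genes, size=n_detected, replace=False)
            counts[genes, j] = 1
        data = toy_dataset(counts)
        out = qc_filter(data, QcConfig(min_cells_per_gene=0))
        assert out.barcodes == ["c0", "c2"]  # 200 and 2500 kept; 199 and 2501 removed

    def test_mito_fraction_gate(self):
        # cell 1 has 1% mito reads -> removed at the 0.05% default cap
        counts = np.array([[0, 1], [100, 99], [100, 100], [100, 100]])
        data = toy_dataset(counts, mito=("g0",))
        cfg = QcConfig(min_cells_per_gene=0, min_genes_per_cell=1)
        out = qc_filter(data, cfg)
        assert out.barcodes == ["c0"]

    def test_zero_mito_dataset_noop(self):
        counts = np.ones((5, 3), dtype=int)
        cfg = QcConfig(min_cells_per_gene=0, min_genes_per_cell=1, max_genes_per_cell=10)
        out = qc_filter(toy_dataset(counts), cfg)
        assert out.n_cells == 3

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(1.0, size=(50, 20))
        cfg = QcConfig(min_genes_per_cell=5, max_genes_per_cell=45)
        once = qc_filter(toy_dataset(counts), cfg)
        twice = qc_filter(once, cfg)
        assert twice.barcodes == once.barcodes and twice.gene_ids == once.gene_ids

    def test_error_names_culprit_filter_when_all_cells_removed(self):
        counts = np.ones((10, 3), dtype=int)
        cfg = QcConfig(min_cells_per_gene=0, min_genes_per_cell=50,
                       max_genes_per_cell=100)
        with pytest.raises(ValueError, match="min_genes_per_cell"):
            qc_filter(toy_dataset(counts), cfg)


class TestLogNormalize:
    def test_single_gene_cell_formula(self):
        counts = np.array([[5, 2], [0, 2]])
        norm = log_normalize(toy_dataset(counts), scale_factor=10_000)
        assert norm[0, 0] == pytest.approx(np.log(10001))

    def test_per_cell_mass_equals_scale_factor(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(3.0, size=(40, 10)) + 1
        norm = log_normalize(toy_dataset(counts), scale_factor=10_000)
        assert np.allclose(np.expm1(norm).sum(axis=0), 10_000, rtol=1e-6)

    def test_depth_invariance(self):
        counts = np.array([[3, 1], [5, 7], [2, 2]])
        doubled = counts.copy()
        doubled[:, 0] *= 4
        a = log_normalize(toy_dataset(counts))
        b = log_normalize(toy_dataset(doubled))
        assert np.allclose(a, b)

    def test_zero_total_cell_rejected(self):
        counts = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="zero-total"):
            log_normalize(toy_dataset(counts))


class TestFindMarkers:
    def _norm_dataset(self, rng, n_genes=30, n_cells=60, shift_gene=0, fold=4.0):
        counts = rng.poisson(5.0, size=(n_genes, n_cells)) + 1
        clusters = ["a"] * (n_cells // 2) + ["b"] * (n_cells - n_cells // 2)
        if fold != 1.0:
            counts[shift_gene, : n_cells // 2] = rng.poisson(
                5.0 * fold, size=n_cells // 2) + 1
        data = toy_dataset(counts, clusters=clusters)
        return log_normalize(data), data

    def test_min_pct_boundary_inclusive(self, rng):
        # gene expressed in exactly 25% of cluster "a" cells and nowhere else
        n_cells = 40
        counts = rng.poisson(5.0, size=(10, n_cells)) + 1
        counts[0, :] = 0
        counts[0, :5] = 3  # 5/20 = 25% of cluster a
        counts[1, :] = 0
        counts[1, :4] = 3  # 4/20 = 20% -> ineligible on both sides
        clusters = ["a"] * 20 + ["b"] * 20
        norm = log_normalize(toy_dataset(counts, clusters=clusters))
        recs = find_markers(norm, [f"g{i}" for i in range(10)], clusters)
        genes_a = {r.gene_id for r in recs if r.group == "a"}
        assert "g0" in genes_a
        assert "g1" not in genes_a

    def test_flat_gene_scores_null(self, rng):
        counts = np.full((5, 30), 7)
        clusters = ["a"] * 15 + ["b"] * 15
        norm = log_normalize(toy_dataset(counts, clusters=clusters))
        recs = find_markers(norm, [f"g{i}" for i in range(5)], clusters)
        for r in recs:
            assert r.p_value == pytest.approx(1.0)
            assert r.log2_fold_change == pytest.approx(0.0)

    def test_planted_fold_change_detected(self, rng):
        norm, data = self._norm_dataset(rng, shift_gene=3, fold=4.0)
        recs = find_markers(norm, data.gene_ids, data.cluster_label)
        hit = [r for r in recs if r.gene_id == "g3" and r.group == "a"]
        assert hit and hit[0].fdr < 0.05 and hit[0].log2_fold_change > 0

    def test_small_cluster_skipped(self, rng):
        counts = rng.poisson(5.0, size=(10, 12)) + 1
        clusters = ["a"] * 10 + ["tiny"] * 2
        norm = log_normalize(toy_dataset(counts, clusters=clusters))
        recs = find_markers(norm, [f"g{i}" for i in range(10)], clusters)
        assert all(r.group != "tiny" for r in recs)

    def test_requires_two_clusters(self, rng):
        counts = rng.poisson(5.0, size=(5, 10)) + 1
        with pytest.raises(ValueError):
            find_markers(log_normalize(toy_dataset(counts)), [f"g{i}" for i in range(5)],
                         ["a"] * 10)


class TestClonotypeLinking:
    def test_shared_clonotype_report_counts_cells_per_strain(self):
        counts = np.ones((4, 3), dtype=int)
        a = toy_dataset(counts, clonotypes=["TGTGCA", "TGTGCA", "TGTTTT"], strain="Sf")
        b = toy_dataset(counts, clonotypes=["TGTGCA", "TGTAAA", None], strain="healthy")
        report = link_clonotypes([a, b])
        assert report.n_shared_tcrs == 1
        assert report.cells_per_strain == {"Sf": 2, "healthy": 1}
        assert report.summary == "1 TCRs, 1 nucleotide sequences, 3 cells: 2 + 1"

    def test_no_shared_clonotypes_empty_report(self):
        counts = np.ones((2, 2), dtype=int)
        a = toy_dataset(counts, clonotypes=["TGTGCA", "TGTGCA"], strain="Sf")
        b = toy_dataset(counts, clonotypes=["TGTAAA", "TGTAAA"], strain="healthy")
        report = link_clonotypes([a, b])
        assert report.n_shared_tcrs == 0 and len(report.table) == 0

    def test_synonymous_variants_counted_as_one_tcr(self):
        # TGTGCA and TGCGCA both encode CA
        counts = np.ones((2, 2), dtype=int)
        a = toy_dataset(counts, clonotypes=["TGTGCA", "TGTGCA"], strain="Sf")
        b = toy_dataset(counts, clonotypes=["TGCGCA", "TGCGCA"], strain="healthy")
        report = link_clonotypes([a, b])
        assert report.n_shared_tcrs == 1
        assert report.n_nt_variants == 2

    def test_missing_annotation_rejected(self):
        counts = np.ones((2, 2), dtype=int)
        a = toy_dataset(counts, clonotypes=["TGTGCA", "TGTGCA"])
        b = toy_dataset(counts)  # no clonotype annotation
        with pytest.raises(ValueError):
            link_clonotypes([a, b])


class TestClusterComposition:
    def test_single_cluster_single_column(self):
        counts = np.ones((2, 3), dtype=int)
        data = toy_dataset(counts, clusters=["c1"] * 3,
                           clonotypes=["TGTGCA", "TGTGCA", "TGTTTT"])
        tab = cluster_composition(data)
        assert list(tab.columns) == ["c1"]
        assert tab.to_numpy().sum() == 3

    def test_total_conserved_and_permutation_invariant(self):
        counts = np.ones((2, 4), dtype=int)
        clusters = ["c1", "c2", "c1", "c2"]
        clono = ["TGTGCA", "TGTGCA", "TGTTTT", None]
        data = toy_dataset(counts, clusters=clusters, clonotypes=clono)
        tab = cluster_composition(data)
        assert tab.to_numpy().sum() == 3  # one cell unannotated
        perm = [1, 3, 0, 2]
        data_p = toy_dataset(counts[:, perm], clusters=[clusters[i] for i in perm],
                             clonotypes=[clono[i] for i in perm])
        assert cluster_composition(data_p).equals(tab)


class TestScIo:
    def test_mtx_round_trip(self, tmp_path, rng):
        counts = rng.poisson(2.0, size=(8, 5))
        data = toy_dataset(counts, mito=("g0",), clusters=["a"] * 5,
                           clonotypes=["TGTGCA", None, "TGTTTT", "TGTGCA", None])
        write_sc_dataset(data, tmp_path)
        back = read_sc_dataset(tmp_path)
        assert np.array_equal(back.counts, data.counts)
        assert back.gene_ids == data.gene_ids
        assert back.clonotype == data.clonotype
        assert back.mito_genes == data.mito_genes
        assert back.strain == data.strain

    def test_to_anndata_shape_and_annotations(self):
        counts = np.ones((3, 2), dtype=int)
        data = toy_dataset(counts, mito=("g1",), clusters=["a", "b"],
                           clonotypes=["TGTGCA", None])
        adata = data.to_anndata()
        assert adata.shape == (2, 3)  # cells x genes
        assert list(adata.obs["cluster"]) == ["a", "b"]
        assert adata.var["mito"].sum() == 1
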