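import logging

import numpy as np
import pytest

from chromastrat.clustering import (
    NOISE,
    StageParams,
    assign_cell_types,
    cluster_density,
    derive_seed,
    project_umap,
    subcluster_by_type,
    subcluster_name,
)
from chromastrat.embedding import EmbeddingMatrix, NormalizedMatrix
from chromastrat.gene_panel import GenePanel, packaged_panel, restrict_to_panel

from .reference import dbscan_bruteforce, same_partition


def embedding_of(X):
    return EmbeddingMatrix(np.asarray(X, float), [f"c{i}" for i in range(len(X))])


def two_blobs(n=200, sigma=0.1, dist=10.0, seed=0, dim=2):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, sigma, size=(n, dim))
    b = rng.normal(0, sigma, size=(n, dim))
    b[:, 0] += dist
    return np.vstack([a, b])


class TestProjectUmap:
    def test_same_seed_identical_coordinates(self):
        emb = embedding_of(two_blobs(n=60, dim=5))
        p1 = project_umap(emb, seed=3, n_neighbors=10)
        p2 = project_umap(emb, seed=3, n_neighbors=10)
        np.testing.assert_array_equal(p1.values, p2.values)

    def test_output_has_two_columns(self):
        proj = project_umap(embedding_of(two_blobs(n=40, dim=5)), seed=0, n_neighbors=10)
        assert proj.values.shape == (80, 2)

    def test_separated_blobs_stay_separated(self):
        X = two_blobs(n=100, sigma=0.1, dist=10.0, dim=6, seed=1)
        proj = project_umap(embedding_of(X), seed=0, n_neighbors=15).values
        ca, cb = proj[:100].mean(axis=0), proj[100:].mean(axis=0)
        within_a = np.linalg.norm(proj[:100] - ca, axis=1).mean()
        within_b = np.linalg.norm(proj[100:] - cb, axis=1).mean()
        between = np.linalg.norm(ca - cb)
        assert between > within_a and between > within_b

    def test_fewer_than_three_cells_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            project_umap(embedding_of(np.zeros((2, 4))), seed=0)


class TestClusterDensity:
    def test_identical_points_single_cluster_no_noise(self):
        X = np.zeros((20, 2))
        labels = cluster_density(X, eps=0.5, min_samples=10)
        assert labels.n_clusters == 1
        assert labels.n_noise == 0

    def test_two_blobs_two_clusters(self):
        X = two_blobs(n=200, sigma=0.1, dist=10.0, seed=0)
        labels = cluster_density(X, eps=0.5, min_samples=10)
        assert labels.n_clusters == 2
        ref = dbscan_bruteforce(X, eps=0.5, min_samples=10)
        assert same_partition(labels.labels, ref)

    def test_tiny_eps_makes_everything_noise(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(50, 2)) * 100
        labels = cluster_density(X, eps=1e-9, min_samples=2)
        assert labels.n_noise == 50
        assert labels.n_clusters == 0

    def test_labels_renumbered_by_descending_size(self):
        X = np.vstack([np.zeros((30, 2)), np.full((10, 2), 50.0)])
        labels = cluster_density(X, eps=1.0, min_samples=3)
        sizes = np.bincount(labels.labels[labels.labels >= 0])
        assert list(sizes) == sorted(sizes, reverse=True)
        assert np.all(labels.labels[:30] == 0)

    def test_default_eps_is_positive_and_recovers_blobs(self):
        X = two_blobs(n=150, sigma=0.2, dist=15.0, seed=2)
        labels = cluster_density(X, min_samples=10)
        assert labels.eps > 0
        assert labels.n_clusters == 2

    @pytest.mark.parametrize("eps,min_samples,seed", [
        (0.3, 5, 0), (0.8, 10, 1), (2.0, 3, 2), (0.1, 2, 3),
    ])
    def test_matches_bruteforce_reference(self, eps, min_samples, seed):
        rng = np.random.default_rng(seed)
        X = np.vstack([
            rng.normal(0, 1.0, size=(120, 2)),
            rng.normal(6, 0.5, size=(80, 2)),
            rng.uniform(-5, 12, size=(50, 2)),
        ])
        labels = cluster_density(X, eps=eps, min_samples=min_samples)
        ref = dbscan_bruteforce(X, eps=eps, min_samples=min_samples)
        assert same_partition(labels.labels, ref)


class TestAssignCellTypes:
    @staticmethod
    def norm_of(values, genes):
        values = np.asarray(values, float)
        return NormalizedMatrix(values, genes, [f"c{i}" for i in range(values.shape[1])])

    @staticmethod
    def labels_of(labels):
        labels = np.asarray(labels)
        from chromastrat.clustering import ClusterLabels

        return ClusterLabels(labels, [f"c{i}" for i in range(len(labels))],
                             eps=1.0, min_samples=1)

    def test_single_cluster_single_marker(self):
        norm = self.norm_of([[1.0, 1.0]], ["ACTC1"])
        labels = self.labels_of([0, 0])
        res = assign_cell_types(norm, labels, {"cardiomyocyte": ("ACTC1",)})
        assert res.types == {0: "cardiomyocyte"}

    def test_marker_elevated_cluster_wins(self):
        # gene rows: ACTC1 high in cluster 0, COL1A1 high in cluster 1
        values = np.array([[5.0, 5.0, 0.1, 0.1], [0.1, 0.1, 5.0, 5.0]])
        norm = self.norm_of(values, ["ACTC1", "COL1A1"])
        labels = self.labels_of([0, 0, 1, 1])
        res = assign_cell_types(norm, labels, {
            "cardiomyocyte": ("ACTC1",), "fibroblast": ("COL1A1",)})
        assert res.types == {0: "cardiomyocyte", 1: "fibroblast"}
        assert res.margins[0] > 0

    def test_tie_breaks_lexicographically_with_warning(self, caplog):
        values = np.array([[5.0, 0.1], [5.0, 0.1]])
        norm = self.norm_of(values, ["ACTC1", "COL1A1"])
        labels = self.labels_of([0, 1])
        with caplog.at_level(logging.WARNING):
            res = assign_cell_types(norm, labels, {
                "cardiomyocyte": ("ACTC1",), "fibroblast": ("COL1A1",)})
        assert res.types[0] == "cardiomyocyte"  # lexicographic first
        assert any("tie" in r.message for r in caplog.records)

    def test_absent_markers_dropped_missing_type_excluded(self, caplog):
        norm = self.norm_of([[1.0, 2.0]], ["ACTC1"])
        labels = self.labels_of([0, 0])
        with caplog.at_level(logging.WARNING):
            res = assign_cell_types(norm, labels, {
                "cardiomyocyte": ("ACTC1", "MYH7"), "fibroblast": ("COL1A1",)})
        assert res.types == {0: "cardiomyocyte"}

    def test_planted_types_recovered_on_separable_cohort(self, separable_cohort):
        """Stage-1 chain maps every DBSCAN cluster to its majority planted
        type, on a cohort whose types carry a broad expression program."""
        from chromastrat.clustering import embed_project_cluster

        cfg, matrix, annotation, _ = separable_cohort
        labels, _, _, norm = embed_project_cluster(
            matrix, StageParams(seed=0, umap_neighbors=20, dbscan_min_samples=10))
        assert labels.n_clusters >= 2
        res = assign_cell_types(norm, labels, cfg.marker_map)
        truth_types = annotation.column("cell_type")
        for cid, assigned in res.types.items():
            members = truth_types[labels.labels == cid]
            values, counts = np.unique(members, return_counts=True)
            majority = values[np.argmax(counts)]
            assert assigned == majority

    def test_cardiomyocyte_cluster_recovered_on_default_cohort(self, small_cohort):
        """On the lineage-marker-only default cohort the dominant lineage
        (cardiomyocytes) forms a pure, correctly typed cluster even though
        single-marker rare types may merge."""
        from chromastrat.clustering import embed_project_cluster
        from chromastrat.synthetic_cohort import DEFAULT_MARKER_MAP

        _, matrix, annotation, _ = small_cohort
        labels, _, _, norm = embed_project_cluster(
            matrix, StageParams(seed=0, umap_neighbors=20, dbscan_min_samples=10))
        res = assign_cell_types(norm, labels, DEFAULT_MARKER_MAP)
        truth_types = annotation.column("cell_type")
        cm_clusters = [c for c, t in res.types.items() if t == "cardiomyocyte"]
        assert cm_clusters
        members = np.isin(labels.labels, cm_clusters)
        purity = np.mean(truth_types[members] == "cardiomyocyte")
        recall = np.mean(labels.labels[truth_types == "cardiomyocyte"] >= 0)
        assert purity > 0.9
        assert recall > 0.9


class TestSubclusterByType:
    def test_gene_restriction_delegates_to_panel_overlap(self, small_cohort):
        _, matrix, annotation, _ = small_cohort
        panel = packaged_panel()
        res = subcluster_by_type(
            matrix, annotation, panel,
            StageParams(seed=0, epochs=30, umap_neighbors=15),
            cell_types=["cardiomyocyte"],
        )
        cm_cells = np.flatnonzero(annotation.column("cell_type") == "cardiomyocyte")
        expected = restrict_to_panel(matrix.subset_cells(cm_cells), panel)
        assert res["cardiomyocyte"].panel_genes == expected.gene_symbols

    def test_type_with_too_few_cells_skipped(self, small_cohort, caplog):
        _, matrix, annotation, _ = small_cohort
        ann = annotation.table.copy()
        ann.loc[ann.index[:3], "cell_type"] = "rare_type"
        from chromastrat.io_formats import CellAnnotation

        with caplog.at_level(logging.WARNING):
            res = subcluster_by_type(
                matrix, CellAnnotation(ann), packaged_panel(),
                StageParams(seed=0, epochs=20, umap_neighbors=10),
                cell_types=["rare_type"],
            )
        assert "rare_type" not in res
        assert any("skipped" in r.message for r in caplog.records)

    def test_subcluster_names_are_namespaced(self):
        assert subcluster_name("cardiomyocyte", 0) == "CM1"
        assert subcluster_name("fibroblast", 2) == "FB3"
        assert subcluster_name("cardiomyocyte", NOISE) == "CM_noise"
        assert subcluster_name("unknown_type", 0) == "UT1"


class TestSeeds:
    def test_derived_seeds_stable_and_stage_specific(self):
        assert derive_seed(1, "umap") == derive_seed(1, "umap")
        assert derive_seed(1, "umap") != derive_seed(1, "autoencoder")
        assert derive_seed(1, "umap") != derive_seed(2, "umap")
        assert 0 <= derive_seed(123456, "stage") < 2**31
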