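import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from chromastrat.clustering import ClusterLabels
from chromastrat.embedding import NormalizedMatrix
from chromastrat.markers import (
    MarkerCriteria,
    _ranksum_p_matrix,
    log2fc_matrix,
    markers_to_frame,
    rank_sum_test,
    select_markers,
)

from .reference import ranksum_exact_bruteforce


def norm_of(values, genes=None):
    values = np.asarray(values, float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    return NormalizedMatrix(values, genes, [f"c{i}" for i in range(values.shape[1])])


def labels_of(labels):
    labels = np.asarray(labels)
    return ClusterLabels(labels, [f"c{i}" for i in range(len(labels))],
                         eps=1.0, min_samples=1)


class TestRankSumTest:
    def test_fully_separated_samples_exact(self):
        """x={1,2,3} vs y={4,5,6}: 2 of the 20 rank splits are as extreme."""
        t, p = rank_sum_test([1, 2, 3], [4, 5, 6], mode="exact")
        assert t == 6.0
        assert p == pytest.approx(0.1, abs=1e-15)

    def test_identical_samples_give_p_one(self):
        _, p = rank_sum_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0], mode="exact")
        assert p == 1.0

    def test_exact_refuses_huge_enumerations(self):
        x = np.arange(30.0)
        y = np.arange(30.0) + 0.5
        with pytest.raises(ValueError, match="use normal"):
            rank_sum_test(x, y, mode="exact")

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            rank_sum_test([], [1.0])

    def test_normal_close_to_exact_at_n30(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.3, 1, size=30)
        y = rng.normal(0.0, 1, size=30)
        _, p_norm = rank_sum_test(x, y, mode="normal")
        # Monte-Carlo permutation oracle
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        mu = 30 * (60 + 1) / 2
        t_obs = abs(ranks[:30].sum() - mu)
        perm = np.random.default_rng(0).permuted(
            np.tile(ranks, (400_000, 1)), axis=1)
        t_null = np.abs(perm[:, :30].sum(axis=1) - mu)
        p_mc = float(np.mean(t_null >= t_obs - 1e-9))
        assert abs(p_norm - p_mc) < 0.005

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n1=st.integers(1, 8), n2=st.integers(1, 8),
        data=st.data(),
    )
    def test_exact_equals_bruteforce_enumeration(self, n1, n2, data):
        """Property sweep: DP-based exact p equals full enumeration, with
        ties induced by drawing from a small integer support."""
        values = data.draw(st.lists(
            st.integers(0, 4), min_size=n1 + n2, max_size=n1 + n2))
        x, y = values[:n1], values[n1:]
        _, p = rank_sum_test(x, y, mode="exact")
        assert p == pytest.approx(ranksum_exact_bruteforce(x, y), abs=1e-12)

    def test_vectorized_normal_matches_scalar(self):
        rng = np.random.default_rng(4)
        values = rng.poisson(2.0, size=(20, 60)).astype(float)
        mask = np.zeros(60, dtype=bool)
        mask[:25] = True
        p_vec = _ranksum_p_matrix(values, mask)
        for g in range(20):
            _, p = rank_sum_test(values[g, mask], values[g, ~mask], mode="normal")
            assert p_vec[g] == pytest.approx(p, rel=1e-12)


class TestSelectMarkers:
    def build_toy(self):
        """Gene 0: mean ~10 in cluster A (50 cells, all nonzero) vs ~1
        elsewhere (150 cells). Gene 1: uniform. Gene 2: high mean but only
        10% of in-cluster cells expressing."""
        rng = np.random.default_rng(0)
        n_a, n_b = 50, 150
        g0 = np.concatenate([rng.normal(10, 1, n_a).clip(5), rng.normal(1, 0.3, n_b).clip(0.01)])
        g1 = rng.normal(2, 0.5, n_a + n_b).clip(0.1)
        g2 = np.zeros(n_a + n_b)
        g2[:5] = 100.0  # 10% of cluster A
        values = np.vstack([g0, g1, g2])
        labels = labels_of([0] * n_a + [1] * n_b)
        return norm_of(values, ["UP", "FLAT", "SPARSE"]), labels

    def test_strong_marker_selected_with_all_three_criteria(self):
        norm, labels = self.build_toy()
        records = select_markers(norm, labels)
        up = [r for r in records if r.cluster == 0]
        assert [r.gene for r in up] == ["UP"]
        r = up[0]
        # recompute the three criteria independently
        lin = np.expm1(norm.values[0])
        assert r.p_value < 1e-6
        assert r.fraction_in == np.mean(norm.values[0, :50] > 0)
        assert r.fold == pytest.approx(
            (lin[:50].mean() + 1e-9) / (lin[50:].mean() + 1e-9), rel=1e-12)
        assert r.fold >= 2.0
        assert r.log2fc == pytest.approx(np.log2(r.fold), abs=1e-12)

    def test_low_expressing_fraction_rejected_despite_fold(self):
        norm, labels = self.build_toy()
        records = select_markers(norm, labels)
        assert "SPARSE" not in {r.gene for r in records}

    def test_default_criteria_tuple(self):
        c = MarkerCriteria()
        assert (c.p_threshold, c.min_fraction, c.min_fold) == (1e-6, 0.20, 2.0)

    def test_needs_two_clusters(self):
        norm, _ = self.build_toy()
        with pytest.raises(ValueError, match="2 non-noise"):
            select_markers(norm, labels_of([0] * 200))

    def test_tiny_cluster_skipped(self, caplog):
        import logging

        norm, _ = self.build_toy()
        labels = labels_of([0] * 2 + [1] * 198)
        with caplog.at_level(logging.WARNING):
            records = select_markers(norm, labels)
        assert all(r.cluster != 0 for r in records)
        assert any("skipped" in r.message for r in caplog.records)

    def test_noise_cells_never_enter_tests(self):
        norm, labels = self.build_toy()
        # make 30 cells of cluster B noise with absurd values: results for
        # cluster A must not change
        values = norm.values.copy()
        values[:, 170:] = 1e6
        noisy = norm_of(values, norm.gene_symbols)
        lab = labels.labels.copy()
        lab[170:] = -1
        rec_a = [r for r in select_markers(noisy, labels_of(lab)) if r.cluster == 0]
        base = norm_of(norm.values[:, :170], norm.gene_symbols)
        rec_b = [r for r in select_markers(base, labels_of(lab[:170])) if r.cluster == 0]
        assert [(r.gene, r.p_value, r.fold) for r in rec_a] == [
            (r.gene, r.p_value, r.fold) for r in rec_b]

    def test_frame_columns_ordered(self):
        norm, labels = self.build_toy()
        df = markers_to_frame(select_markers(norm, labels))
        assert list(df.columns[:4]) == ["gene", "cluster", "p_value", "fraction_in"]


class TestLog2fcMatrix:
    def test_identical_means_give_zero_row(self):
        values = np.tile(np.linspace(1, 2, 6), (3, 2))  # both clusters identical
        out = log2fc_matrix(norm_of(values), labels_of([0] * 6 + [1] * 6))
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-9)

    def test_planted_effect_recovered(self):
        """A 2^1.5 multiplicative effect on linear-scale expression shows up
        as log2FC = 1.5 +- 0.2 at n=500 cells."""
        rng = np.random.default_rng(8)
        n = 500
        base = rng.gamma(4.0, 0.5, size=n)
        lab = np.array([0] * 250 + [1] * 250)
        lin = base * np.where(lab == 0, 2**1.5, 1.0)
        values = np.log1p(lin)[None, :]
        out = log2fc_matrix(norm_of(values), labels_of(lab))
        assert out.iloc[0, 0] == pytest.approx(1.5, abs=0.2)

    def test_matches_marker_records_exactly(self):
        t = TestSelectMarkers()
        norm, labels = t.build_toy()
        records = select_markers(norm, labels)
        mat = log2fc_matrix(norm, labels)
        for r in records:
            assert mat.loc[r.gene, r.cluster] == pytest.approx(r.log2fc, abs=1e-12)

    def test_absent_gene_rejected(self):
        values = np.ones((2, 8))
        with pytest.raises(ValueError, match="absent"):
            log2fc_matrix(norm_of(values), labels_of([0] * 4 + [1] * 4), genes=["NOPE"])
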