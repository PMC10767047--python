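import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from spatglia import preprocess, syndata
from spatglia.io import SpotDataset
from spatglia.preprocess import (NormalizedMatrix, annotate_clusters,
                                 cluster_spots, embed_pca, find_all_markers,
                                 hvg_statistics, log_normalize,
                                 replicate_correlation, scale_and_regress,
                                 select_hvg_vst, snn_graph,
                                 wilcoxon_rank_sum)


def _dataset_from_counts(counts):
    counts = np.asarray(counts)
    n_genes, n_spots = counts.shape
    positions = pd.DataFrame({
        "array_row": 0, "array_col": np.arange(n_spots),
        "x_px": np.arange(n_spots, dtype=float), "y_px": 0.0,
    }, index=pd.Index([f"s{i}" for i in range(n_spots)], name="barcode"))
    return SpotDataset(sp.csr_matrix(counts),
                       [f"g{i}" for i in range(n_genes)],
                       [f"s{i}" for i in range(n_spots)], positions)


class TestLogNormalize:
    def test_formula_values(self):
        # one spot of total 100: count 1 -> ln(101); count 0 -> 0
        counts = np.zeros((3, 2), dtype=int)
        counts[:, 0] = [1, 99, 0]
        counts[:, 1] = [100, 0, 0]
        norm = log_normalize(_dataset_from_counts(counts))
        x = norm.matrix.toarray()
        assert x[0, 0] == pytest.approx(np.log(101), abs=1e-10)
        assert x[2, 0] == 0.0
        # count 100, total 100 -> ln(1 + 100/100*1e4) = ln(10001)
        assert x[0, 1] == pytest.approx(np.log(10001), abs=1e-10)

    def test_invariant_to_doubling_a_spots_counts(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(2.0, size=(30, 5))
        counts[0] += 1   # no all-zero spot
        a = log_normalize(_dataset_from_counts(counts)).matrix.toarray()
        b = log_normalize(_dataset_from_counts(counts * 2)).matrix.toarray()
        assert np.allclose(a, b)

    def test_zero_total_spot_is_an_error_listing_spots(self):
        counts = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="s1"):
            log_normalize(_dataset_from_counts(counts))


class TestHvgVst:
    def test_constant_gene_ranks_last_with_zero_variance(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(3.0, size=(20, 200))
        counts[5] = 7   # constant gene
        stats = hvg_statistics(_dataset_from_counts(counts))
        row = stats[stats["gene"] == "g5"]
        assert row["variance_standardized"].iloc[0] == 0.0
        assert row.index[0] == len(stats) - 1

    def test_n_equal_to_gene_count_returns_all(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(3.0, size=(15, 100)) + 1
        got = select_hvg_vst(_dataset_from_counts(counts), n=15)
        assert len(got) == 15

    def test_overdispersed_gene_outranks_mean_matched_peers(self):
        # Poisson genes spanning means 2/5/12 plus one gene at mean 5 with
        # ~10x the variance of its mean-matched peers
        rng = np.random.default_rng(4)
        means = np.repeat([2.0, 5.0, 12.0], 17)
        counts = rng.poisson(means[:, None], size=(51, 500))
        counts[0] = rng.negative_binomial(5 / 9, 0.1, size=500)  # mean 5, var 50
        got = select_hvg_vst(_dataset_from_counts(counts), n=5)
        assert got[0] == "g0"

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            select_hvg_vst(_dataset_from_counts(np.eye(3, dtype=int)), n=0)


class TestScaleAndRegress:
    def test_plain_zscore_uses_population_sd(self):
        out = scale_and_regress(np.array([[1.0, 2.0, 3.0]]))
        assert np.allclose(out, [[-1.2247448, 0.0, 1.2247448]], atol=1e-6)

    def test_gene_linear_in_covariate_becomes_zero_row(self):
        cov = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.vstack([2 * cov + 1, [1.0, 5.0, 2.0, 7.0]])
        out = scale_and_regress(X, {"c": cov})
        assert np.allclose(out[0], 0.0, atol=1e-10)
        assert out[1].std() > 0

    def test_extreme_value_clips_at_ten(self):
        x = np.ones(400)
        x[0] = 1000.0
        out = scale_and_regress(x[None, :])
        assert out.max() == pytest.approx(10.0)

    def test_constant_covariate_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = scale_and_regress(np.array([[1.0, 2.0, 3.0]]),
                                    {"c": np.ones(3)})
        assert np.allclose(out, [[-1.2247448, 0.0, 1.2247448]], atol=1e-6)


class TestEmbedPca:
    def test_rank_one_matrix_explained_by_pc1(self, rng):
        u = rng.normal(size=50)
        v = rng.normal(size=200)
        X = np.outer(u, v)
        emb = embed_pca(X, n_pcs=3)
        assert emb.explained_variance_ratio[0] > 0.999

    def test_loadings_are_orthonormal(self, rng):
        X = rng.normal(size=(40, 300))
        emb = embed_pca(X, n_pcs=10)
        gram = emb.loadings.T @ emb.loadings
        assert np.abs(gram - np.eye(10)).max() < 1e-8

    def test_two_blob_data_separated_with_fixed_sign(self, rng):
        # blob means differ along all genes; PC1 must split them, and the
        # sign convention (largest-|loading| gene positive) fixes direction
        X = rng.normal(size=(20, 100))
        X[:, 50:] += 6.0
        emb = embed_pca(X - X.mean(axis=1, keepdims=True), n_pcs=2)
        s = emb.scores[:, 0]
        assert (s[:50].mean() < 0) != (s[50:].mean() < 0)
        top = np.argmax(np.abs(emb.loadings[:, 0]))
        assert emb.loadings[top, 0] > 0

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError, match="n_pcs"):
            embed_pca(rng.normal(size=(5, 30)), n_pcs=10)


class TestClusterSpots:
    def test_two_separated_blobs_recovered_exactly(self, rng):
        emb = rng.normal(size=(200, 5))
        emb[100:, 0] += 10.0
        truth = np.repeat([0, 1], 100)
        res = cluster_spots(emb, k_neighbors=15, resolution=0.2, seed=0)
        assert res.n_clusters == 2
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_identical_spots_form_one_cluster(self):
        emb = np.zeros((60, 3))
        res = cluster_spots(emb, k_neighbors=10, resolution=0.2, seed=0)
        assert res.n_clusters == 1

    def test_k_neighbors_must_be_below_n_spots(self):
        with pytest.raises(ValueError, match="k_neighbors"):
            cluster_spots(np.zeros((10, 2)), k_neighbors=10)

    def test_cluster_count_non_decreasing_in_resolution(self, rng):
        # four blobs arranged as two super-pairs on a fixed graph
        centers = np.array([[0, 0], [3, 0], [40, 0], [43, 0]], dtype=float)
        emb = np.vstack([c + rng.normal(scale=0.4, size=(50, 2))
                         for c in centers])
        counts = [cluster_spots(emb, k_neighbors=12, resolution=r,
                                seed=3).n_clusters
                  for r in (0.05, 0.2, 1.0)]
        assert counts == sorted(counts)

    def test_fixed_seed_is_deterministic(self, rng):
        emb = rng.normal(size=(150, 4))
        emb[75:, 1] += 8
        a = cluster_spots(emb, seed=7, k_neighbors=12)
        b = cluster_spots(emb, seed=7, k_neighbors=12)
        assert np.array_equal(a.labels, b.labels)

    def test_labels_are_size_ranked_from_zero(self, rng):
        emb = rng.normal(size=(150, 3))
        emb[:40, 0] += 12
        res = cluster_spots(emb, k_neighbors=12, seed=1)
        sizes = np.bincount(res.labels)
        assert res.labels.min() == 0
        assert list(sizes) == sorted(sizes, reverse=True)


class TestMarkers:
    def test_exact_wilcoxon_small_sample(self):
        # {1,2,3} vs {4,5,6}: 1 extreme table of C(6,3)=20 -> p = 2/20
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6],
                                 method="exact") == pytest.approx(0.1)

    def test_spiked_gene_reported_for_its_cluster(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(2.0, size=(50, 300))
        clusters = np.repeat([0, 1, 2], 100)
        counts[7, clusters == 1] = rng.poisson(8.0, size=100)
        norm = log_normalize(_dataset_from_counts(counts))
        table = find_all_markers(norm, clusters)
        hit = table[(table["cluster"] == 1) & (table["gene"] == "g7")]
        assert len(hit) == 1
        assert hit["logfc"].iloc[0] > 0.3

    def test_tiny_cluster_skipped_with_warning(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(2.0, size=(20, 103))
        clusters = np.array([0] * 50 + [1] * 51 + [2] * 2)
        norm = log_normalize(_dataset_from_counts(counts))
        with pytest.warns(UserWarning, match="cluster 2"):
            table = find_all_markers(norm, clusters)
        assert 2 not in set(table["cluster"])

    def test_single_cluster_rejected(self):
        norm = log_normalize(_dataset_from_counts(np.ones((5, 10),
                                                          dtype=int)))
        with pytest.raises(ValueError, match=">= 2 clusters"):
            find_all_markers(norm, np.zeros(10, dtype=int))


class TestReplicateCorrelation:
    def _norm(self, counts):
        return log_normalize(_dataset_from_counts(counts))

    def test_sample_against_itself_is_one(self):
        rng = np.random.default_rng(10)
        norm = self._norm(rng.poisson(3.0, (20, 40)) + 1)
        labels = np.repeat(["a", "b"], 20)
        r = replicate_correlation(norm, labels, [("a", "a")])
        assert r[("a", "a")] == pytest.approx(1.0)

    def test_anticorrelated_means_give_minus_one(self):
        mat = NormalizedMatrix(sp.csr_matrix(np.array(
            [[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])),
            np.array(["g1", "g2", "g3"], dtype=object),
            np.array(["s1", "s2"], dtype=object))
        r = replicate_correlation(mat, np.array(["a", "b"]), [("a", "b")])
        assert r[("a", "b")] == pytest.approx(-1.0)

    def test_seeded_replicates_correlate_strongly(self, small_study):
        norm = log_normalize(small_study.data)
        labels = small_study.data.meta["sample"].to_numpy()
        pairs = [("WT-3M-rep1", "WT-3M-rep2"), ("AD-7M-rep1", "AD-7M-rep2")]
        r = replicate_correlation(norm, labels, pairs)
        assert (r > 0.95).all()

    def test_single_gene_rejected(self):
        mat = NormalizedMatrix(sp.csr_matrix(np.ones((1, 4))),
                               np.array(["g"], dtype=object),
                               np.array(list("abcd"), dtype=object))
        with pytest.raises(ValueError, match="2 genes"):
            replicate_correlation(mat, np.array(["a", "a", "b", "b"]),
                                  [("a", "b")])


class TestRegionRecovery:
    def test_snn_graph_is_symmetric_with_unit_self_free_diagonal(self, rng):
        W = snn_graph(rng.normal(size=(80, 4)), k_neighbors=10)
        assert (W != W.T).nnz == 0
        assert W.diagonal().max() == 0

    def test_scaled_down_study_recovers_regions(self, small_study):
        data = small_study.data
        norm = log_normalize(data)
        hvg = select_hvg_vst(data, n=400)
        scaled = scale_and_regress(norm.matrix[norm.gene_index(hvg)],
                                   preprocess.spot_covariates(data))
        emb = embed_pca(scaled, n_pcs=30)
        res = cluster_spots(emb, resolution=0.2, seed=0)
        ari = adjusted_rand_score(data.meta["region"], res.labels)
        assert ari >= 0.8
        annotation = annotate_clusters(res.labels,
                                       data.meta["region"].to_numpy())
        assert set(annotation.values()) == set(syndata.REGIONS)
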