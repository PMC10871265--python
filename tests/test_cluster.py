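"""Distance selection, grid tuning, and graph community clustering."""

import numpy as np
import pytest

from conftest import make_graph
from cryoclust.cluster import (
    BINARY_MEASURES,
    MEASURES,
    GridTunedClusterer,
    MeasureUndefinedError,
    SearchSpace,
    distance_matrix,
    graph_cluster,
    select_distance,
    tune_and_fit,
)
from cryoclust.metrics import NOISE


class TestDistanceMatrix:
    def test_twenty_two_candidates(self):
        assert len(MEASURES) == 22

    def test_each_measure_evaluates_or_skips_cleanly(self, rng):
        X = rng.normal(size=(12, 5))
        defined = 0
        for m in MEASURES:
            try:
                D = distance_matrix(X, m)
            except MeasureUndefinedError:
                continue
            assert D.shape == (12, 12)
            assert np.all(np.isfinite(D))
            assert np.allclose(np.diag(D), 0)
            defined += 1
        assert defined >= 15

    def test_binary_measures_use_sign_pattern(self, rng):
        X = rng.normal(size=(8, 6))
        X[np.abs(X) < 0.5] = 0
        scaled = X * 7.5  # same nonzero pattern
        for m in sorted(BINARY_MEASURES):
            try:
                assert np.allclose(distance_matrix(X, m),
                                   distance_matrix(scaled, m)), m
            except MeasureUndefinedError:
                pass

    def test_kulsinski_hand_computed(self):
        u = np.array([[1, 1, 0, 1, 0]], dtype=float)
        v = np.array([[1, 0, 0, 1, 1]], dtype=float)
        X = np.vstack([u, v])
        # ctt=2, ctf=1, cft=1, n=5 -> (1+1-2+5)/(1+1+5) = 5/7
        D = distance_matrix(X, "kulsinski")
        assert np.isclose(D[0, 1], 5 / 7)

    def test_sokalmichener_hand_computed(self):
        u = np.array([[1, 1, 0, 0]], dtype=float)
        v = np.array([[1, 0, 1, 0]], dtype=float)
        X = np.vstack([u, v])
        # R = ctf+cft = 2, S = ctt+cff = 2 -> 2R/(S+2R) = 4/6
        D = distance_matrix(X, "sokalmichener")
        assert np.isclose(D[0, 1], 4 / 6)

    def test_jensenshannon_undefined_on_negatives(self, rng):
        with pytest.raises(MeasureUndefinedError):
            distance_matrix(rng.normal(size=(5, 4)), "jensenshannon")

    def test_mahalanobis_singular_covariance_skipped(self, rng):
        X = np.tile(rng.normal(size=(6, 1)), (1, 4))  # rank-1
        with pytest.raises(MeasureUndefinedError):
            distance_matrix(X, "mahalanobis")


class TestSelectDistance:
    def test_separated_blobs_good_silhouette(self, blobs):
        from sklearn.metrics import silhouette_score

        X, y = blobs
        m = select_distance(X, np.arange(len(X)), y)
        D = distance_matrix(X, m)
        assert silhouette_score(D, y, metric="precomputed") > 0.5

    def test_deterministic(self, blobs):
        X, y = blobs
        idx = np.arange(len(X))
        assert select_distance(X, idx, y) == select_distance(X, idx, y)

    def test_constant_embedding_errors(self):
        with pytest.raises(ValueError):
            select_distance(np.ones((10, 3)), np.arange(10),
                            np.repeat([0, 1], 5))


class TestSearchSpace:
    def test_grid_sizes_as_printed(self):
        sp = SearchSpace()
        assert len(sp.grid_points("dbscan")) == 12 * 9
        assert len(sp.grid_points("optics")) == 12 * 9
        assert len(sp.grid_points("birch")) == 10 * 10
        assert len(sp.grid_points("affinity")) == 6

    def test_grid_bounds_inclusive(self):
        sp = SearchSpace()
        assert sp.dbscan_eps[0] == 0.25 and sp.dbscan_eps[-1] == 3.0
        assert sp.birch_threshold[-1] == 1.0
        assert sp.affinity_damping == [0.5, 0.6, 0.7, 0.8, 0.9, 1.0]


class TestTuneAndFit:
    @pytest.mark.parametrize("algo", ["dbscan", "optics", "birch",
                                      "affinity"])
    def test_three_blobs_recovered(self, algo, blobs):
        X, y = blobs
        a = tune_and_fit(X, algo, None, "euclidean", np.arange(len(X)), y)
        if algo != "optics":  # xi-method OPTICS may split a tight blob
            assert a.meta["train_fmmf"] == 1.0
        assert a.meta["train_fmmf"] >= 0.5

    def test_perfect_grid_point_exists_for_dbscan(self, blobs):
        X, y = blobs
        a = tune_and_fit(X, "dbscan", None, "euclidean", np.arange(len(X)),
                         y)
        assert a.meta["train_fmmf"] == 1.0 and a.n_clusters == 3

    def test_returned_params_in_printed_grid(self, blobs):
        X, y = blobs
        sp = SearchSpace()
        for algo in ("dbscan", "birch", "affinity"):
            a = tune_and_fit(X, algo, sp, "euclidean", np.arange(len(X)), y)
            assert a.params in sp.grid_points(algo)

    def test_labels_cover_every_point_once(self, blobs):
        X, y = blobs
        a = tune_and_fit(X, "dbscan", None, "cosine", np.arange(len(X)), y)
        assert a.labels.shape == (len(X),)

    def test_missing_truth_errors(self, blobs):
        X, _ = blobs
        with pytest.raises(ValueError, match="train_truth"):
            tune_and_fit(X, "dbscan")


class TestGridTunedClusterer:
    def test_sklearn_interface(self, blobs):
        X, y = blobs
        est = GridTunedClusterer(algorithm="dbscan", measure="auto")
        est.fit(X, y)
        assert est.labels_.shape == (len(X),)
        assert est.measure_ in MEASURES
        assert est.best_params_ in SearchSpace().grid_points("dbscan")
        # params roundtrip through get/set
        est2 = GridTunedClusterer(**est.get_params())
        assert est2.get_params() == est.get_params()


class TestGraphCluster:
    def test_wcc_two_triangles(self):
        g = make_graph([0, 1, 2, 3, 4, 5], [1, 2, 0, 4, 5, 3], 6)
        assert graph_cluster(g, "wcc").n_clusters == 2

    def test_scc_reachability_oracle(self):
        # directed 3-cycle {0,1,2}; reciprocal pair {3,4}
        g = make_graph([0, 1, 2, 3, 4], [1, 2, 0, 4, 3], 5)
        labels = graph_cluster(g, "scc").labels
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] != labels[0]

    def test_label_prop_async_two_cliques_stable_over_seeds(self):
        src, dst = [], []
        for base in (0, 5):
            for i in range(5):
                for j in range(5):
                    if i != j:
                        src.append(base + i)
                        dst.append(base + j)
        src.append(4)
        dst.append(5)  # bridge
        g = make_graph(src, dst, 10)
        counts = {graph_cluster(g, "label_prop_async", seed=s).n_clusters
                  for s in range(10)}
        assert counts == {2}

    @pytest.mark.parametrize("method", ["walktrap", "edge_betweenness",
                                        "greedy_modularity"])
    def test_disjoint_cliques_recovered_exactly(self, method,
                                                two_cliques_graph):
        labels = graph_cluster(two_cliques_graph, method).labels
        assert len(set(labels[:6])) == 1
        assert len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_k_clique_nonmembers_become_singletons(self):
        # a triangle plus a dangling pendant node
        g = make_graph([0, 1, 2, 2], [1, 2, 0, 3], 4, directed=False)
        a = graph_cluster(g, "k_clique")
        assert a.labels[0] == a.labels[1] == a.labels[2]
        assert a.labels[3] != a.labels[0]

    def test_semisync_label_propagation(self, two_cliques_graph):
        a = graph_cluster(two_cliques_graph, "label_prop_semisync")
        assert a.n_clusters == 2

    def test_every_node_labelled_once(self, two_cliques_graph):
        for method in ("wcc", "walktrap", "greedy_modularity", "k_clique"):
            labels = graph_cluster(two_cliques_graph, method).labels
            assert labels.shape == (12,)
            assert np.all(labels != NOISE)

    def test_unknown_method_errors(self, two_cliques_graph):
        with pytest.raises(ValueError, match="unknown"):
            graph_cluster(two_cliques_graph, "louvain")
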