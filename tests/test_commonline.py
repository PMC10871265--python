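"""Line projections, common-line pair scoring, similarity-graph building."""

import numpy as np
import pytest

from cryoclust.commonline import (
    CommonLineGraph,
    build_similarity_graph,
    line_projection_stack,
    line_projections,
    pair_score,
    read_graph_tsv,
    score_all_pairs,
    symmetrize,
    write_graph_tsv,
)


def naive_measure(x, y, measure):
    if measure == "L1":
        return float(np.sum(np.abs(x - y)))
    if measure == "L2":
        return float(np.sqrt(np.sum((x - y) ** 2)))
    if measure == "cosine":
        return float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y)))
    raise ValueError(measure)


def naive_pair_score(lp_i, lp_j, measure, angles):
    """Independent reference: explicit double loop, manual formulas."""
    best = None
    for a in range(len(lp_i)):
        for b in range(len(lp_j)):
            s = naive_measure(lp_i[a], lp_j[b], measure)
            if best is None or (s > best[0] if measure == "cosine"
                                else s < best[0]):
                best = (s, float(angles[a]), float(angles[b]))
    return best


def assert_matches_naive(stack, i, j, measure, tol=1e-9):
    """Optimal score agrees with the reference to ``tol``; the returned
    angle pair achieves that optimum (ties between angle pairs within
    float noise are allowed to resolve either way)."""
    got = pair_score(stack.signals[i], stack.signals[j], measure,
                     stack.angles)
    exp = naive_pair_score(stack.signals[i], stack.signals[j], measure,
                           stack.angles)
    assert abs(got[0] - exp[0]) <= tol
    ai = np.flatnonzero(stack.angles == got[1])[0]
    aj = np.flatnonzero(stack.angles == got[2])[0]
    at_angles = naive_measure(stack.signals[i][ai], stack.signals[j][aj],
                              measure)
    assert abs(at_angles - exp[0]) <= tol


class TestLineProjections:
    def test_theta_zero_is_column_sums(self):
        sig, ang = line_projections(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert ang[0] == 0
        assert np.allclose(np.trim_zeros(sig[0]), [4.0, 6.0])

    def test_mass_conserved_every_angle(self, rng):
        img = rng.random((8, 8))
        sig, _ = line_projections(img)
        assert np.abs(sig.sum(axis=1) - img.sum()).max() <= 1e-2 * img.sum()

    def test_rot90_oracle(self, rng):
        # rotating the image by 90 degrees shifts the projection angle by
        # 90 degrees; wrapping past 180 reverses the signal direction
        img = rng.random((8, 8))
        s_rot, ang = line_projections(np.rot90(img))
        s, _ = line_projections(img)
        A = len(ang)
        for t in range(A):
            tgt = (t + A // 2) % A
            expect = s[tgt] if t + A // 2 < A else s[tgt][::-1]
            assert np.abs(s_rot[t] - expect).max() < 1e-9

    def test_non_square_errors(self):
        with pytest.raises(ValueError, match="square"):
            line_projections(np.ones((4, 6)))

    def test_bad_step_errors(self):
        with pytest.raises(ValueError):
            line_projections(np.ones((4, 4)), angle_step_deg=7.0)


class TestPairScore:
    def test_identity_L2_zero_at_equal_angles(self, rng):
        sig, ang = line_projections(rng.random((8, 8)))
        score, ai, aj = pair_score(sig, sig, "L2", ang)
        assert score == 0.0 and ai == aj

    def test_constant_images_L1_closed_form(self):
        # constant c over an H=W=4 image: every column sum is 4c
        s1, ang = line_projections(np.full((4, 4), 2.0))
        s2, _ = line_projections(np.full((4, 4), 5.0))
        score, ai, aj = pair_score(s1[:1], s2[:1], "L1", ang[:1])
        assert np.isclose(score, 16 * abs(2.0 - 5.0))
        assert ai == aj == 0.0

    @pytest.mark.parametrize("measure", ["L1", "L2", "cosine"])
    def test_matches_naive_oracle(self, measure, rng):
        imgs = rng.random((8, 8, 8))
        stack = line_projection_stack(imgs)
        for i in range(4):
            for j in range(i + 1, 5):
                assert_matches_naive(stack, i, j, measure)

    def test_zero_variance_correlation_skipped(self):
        flat = np.vstack([np.full(10, 3.0), np.arange(10.0)])
        varying = np.vstack([np.arange(10.0), np.arange(10.0)[::-1]])
        score, _, _ = pair_score(flat, varying, "correlation")
        assert np.isfinite(score)
        # all-degenerate case scores similarity 0
        allflat = np.full((2, 10), 1.0)
        assert pair_score(allflat, allflat, "correlation")[0] == 0.0

    def test_wasserstein_runs_and_zero_mass_errors(self, rng):
        a = rng.random((3, 12))
        assert np.isfinite(pair_score(a, a + 0.3, "wasserstein")[0])
        with pytest.raises(ValueError, match="zero-mass"):
            pair_score(np.zeros((2, 5)), a[:2, :5], "wasserstein")


class TestBuildGraph:
    def test_nearest_neighbour_k1(self):
        d = np.array([[0.0, 1.0, 9.0], [1.0, 0.0, 5.0], [9.0, 5.0, 0.0]])
        g = build_similarity_graph(d, measure="L2", k=1)
        e = dict(zip(g.src.tolist(), g.dst.tolist()))
        assert e[0] == 1

    def test_k_equal_n_minus_1_complete(self, rng):
        d = rng.random((5, 5))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        g = build_similarity_graph(d, measure="L2", k=4)
        assert g.n_edges == 5 * 4

    def test_k_too_large_warns_keeps_all(self, rng):
        d = rng.random((4, 4))
        np.fill_diagonal(d, 0)
        with pytest.warns(UserWarning, match="keeping all edges"):
            g = build_similarity_graph(d, measure="L2", k=10)
        assert g.n_edges == 4 * 3

    def test_topk_neighbours_match_sort_oracle(self, rng):
        d = rng.random((6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        g = build_similarity_graph(d, measure="L2", k=2)
        for i in range(6):
            got = set(g.dst[g.src == i].tolist())
            cand = [(d[i, j], j) for j in range(6) if j != i]
            expect = {j for _, j in sorted(cand)[:2]}
            assert got == expect

    def test_per_node_zscores_standardised(self, rng):
        d = rng.random((7, 7))
        np.fill_diagonal(d, 0)
        g = build_similarity_graph(d, measure="L2", k=6)
        for i in range(7):
            z = -g.weight[g.src == i]  # distances were negated
            assert abs(z.mean()) < 1e-9
            assert abs(z.std() - 1) < 1e-9

    def test_similarity_measure_not_negated(self):
        s = np.array([[0.0, 0.9, 0.1], [0.9, 0.0, 0.5], [0.1, 0.5, 0.0]])
        g = build_similarity_graph(s, measure="cosine", k=1)
        # node 0's best neighbour has the *largest* similarity
        assert dict(zip(g.src.tolist(), g.dst.tolist()))[0] == 1

    def test_top_m_edges_mode(self, rng):
        d = rng.random((6, 6))
        np.fill_diagonal(d, 0)
        g = build_similarity_graph(d, measure="L2", mode="top_m_edges", m=7)
        assert g.n_edges == 7

    def test_zero_variance_row_warns(self):
        d = np.ones((4, 4))
        np.fill_diagonal(d, 0)
        with pytest.warns(UserWarning, match="zero variance"):
            g = build_similarity_graph(d, measure="L2", k=2)
        assert np.all(g.weight == 0)


class TestSymmetrize:
    def test_single_directed_edge(self):
        from conftest import make_graph

        g = make_graph([0], [1], 3, weight=[0.4])
        u = symmetrize(g)
        assert not u.directed and u.n_edges == 1
        assert u.weight[0] == 0.4

    def test_reciprocal_edges_max_rule(self):
        from conftest import make_graph

        g = make_graph([0, 1], [1, 0], 2, weight=[0.2, 0.7])
        u = symmetrize(g)
        assert u.n_edges == 1 and u.weight[0] == 0.7

    def test_idempotent(self):
        from conftest import make_graph

        g = make_graph([0, 1, 2], [1, 2, 0], 3, weight=[0.1, 0.2, 0.3])
        u = symmetrize(g)
        assert symmetrize(u) is u


class TestCommonLineGraphEstimator:
    def test_duplicated_images_mutual_nearest_neighbours(self, rng):
        imgs = rng.random((5, 8, 8))
        imgs = np.concatenate([imgs, imgs[:1]])  # image 5 duplicates image 0
        est = CommonLineGraph(measure="L2", k=1).fit(imgs)
        e = dict(zip(est.graph_.src.tolist(), est.graph_.dst.tolist()))
        assert e[0] == 5 and e[5] == 0

    def test_scores_symmetric_with_swapped_angles(self, rng):
        stack = line_projection_stack(rng.random((4, 8, 8)))
        s, a_src, a_dst = score_all_pairs(stack, "L2")
        assert np.allclose(s, s.T)
        assert np.allclose(a_src, a_dst.T)

    def test_graph_tsv_roundtrip(self, rng, tmp_path):
        imgs = rng.random((4, 8, 8))
        g = CommonLineGraph(measure="L2", k=2).fit_transform(imgs)
        p = tmp_path / "g.tsv"
        write_graph_tsv(p, g)
        h = read_graph_tsv(p)
        assert h.n_nodes == g.n_nodes and h.directed == g.directed
        assert np.array_equal(h.src, g.src)
        assert np.allclose(h.weight, g.weight)
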