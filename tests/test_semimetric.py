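import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from semiconn.core import ConnectomeError, RegionTable, WeightedConnectome
from semiconn.semimetric import (
    ABSENT,
    METRIC,
    SEMI_METRIC,
    all_pairs_shortest_paths,
    analyze_subject,
    distance_transform,
    semimetric_profile,
    smp_scales,
    smr_matrix,
    smr_scales,
)
from semiconn.synthetic import make_toy_network

from conftest import random_connected_connectome
from oracles import brute_force_shortest_paths


def _connectome(w, hemis):
    n = w.shape[0]
    return WeightedConnectome(
        w, RegionTable(tuple(f"r{i}" for i in range(n)), tuple(hemis)), "t"
    )


def random_dyadic_distance_graph(rng, n, density=0.7):
    """Distance matrix with dyadic entries (k/64) so path sums are float-exact."""
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    order = rng.permutation(n)
    for a, b in zip(order, np.roll(order, 1)):
        v = rng.integers(1, 129) / 64.0
        d[a, b] = d[b, a] = v
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        if not np.isfinite(d[i, j]) and rng.random() < density:
            v = rng.integers(1, 129) / 64.0
            d[i, j] = d[j, i] = v
    return d


class TestDistanceTransform:
    def test_pointwise_values(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.4
        w[1, 2] = w[2, 1] = 1.0
        d = distance_transform(_connectome(w, "LLR"))
        assert d[0, 1] == pytest.approx(1.5)
        assert d[1, 2] == 0.0
        assert np.isinf(d[0, 2])
        assert np.all(np.diagonal(d) == 0)

    def test_rejects_weight_above_one(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 1.5
        with pytest.raises(ConnectomeError, match="normalized"):
            distance_transform(_connectome(w, "LR"))


class TestShortestPaths:
    def test_matches_enumeration_and_second_method_exactly(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 9))
            d = random_dyadic_distance_graph(rng, n)
            dt = all_pairs_shortest_paths(d)
            brute = brute_force_shortest_paths(d)
            fw = floyd_warshall(np.where(np.isfinite(d), d, 0.0))
            np.testing.assert_array_equal(dt, brute)
            # floyd_warshall treats 0 as absent; only compare where d has no
            # zero-length edges (dyadic entries are >= 1/64, diagonal aside)
            np.testing.assert_array_equal(dt, fw)

    def test_three_node_detour(self):
        # weights A-B 0.1, A-C 0.8, C-B 0.8 -> distances 9, 0.25, 0.25
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.1
        w[0, 2] = w[2, 0] = 0.8
        w[1, 2] = w[2, 1] = 0.8
        d = distance_transform(_connectome(w, "LLR"))
        dt = all_pairs_shortest_paths(d)
        assert d[0, 1] == pytest.approx(9.0)
        assert dt[0, 1] == pytest.approx(0.5)

    def test_toy_direct_edge_is_shortest(self):
        toy = make_toy_network()
        d = distance_transform(toy)
        dt = all_pairs_shortest_paths(d)
        assert dt[0, 1] == pytest.approx(1.5)  # 1/0.4 - 1, direct route wins

    def test_tree_distances_equal_unique_path(self, rng):
        n = 7
        w = np.zeros((n, n))
        for j in range(1, n):
            i = int(rng.integers(0, j))
            w[i, j] = w[j, i] = rng.uniform(0.2, 1)
        d = distance_transform(_connectome(w, "LLLLRRR"))
        dt = all_pairs_shortest_paths(d)
        finite = np.isfinite(d) & (d > 0)
        np.testing.assert_allclose(dt[finite], d[finite])


class TestSMRMatrix:
    def test_detour_ratio_and_classification(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.1
        w[0, 2] = w[2, 0] = 0.8
        w[1, 2] = w[2, 1] = 0.8
        d = distance_transform(_connectome(w, "LLR"))
        s = smr_matrix(d, all_pairs_shortest_paths(d))
        assert s.smr[0, 1] == pytest.approx(18.0)
        assert s.edge_class[0, 1] == SEMI_METRIC
        assert s.edge_class[0, 2] == METRIC

    def test_tree_all_metric(self, rng):
        n = 8
        w = np.zeros((n, n))
        for j in range(1, n):
            i = int(rng.integers(0, j))
            w[i, j] = w[j, i] = rng.uniform(0.2, 1)
        d = distance_transform(_connectome(w, "LLLL" + "RRRR"))
        s = smr_matrix(d, all_pairs_shortest_paths(d))
        exist = s.edge_class != ABSENT
        assert np.all(s.edge_class[exist] == METRIC)
        np.testing.assert_allclose(s.smr[exist], 1.0)

    def test_complete_equal_weights_all_metric(self):
        w = (np.ones((5, 5)) - np.eye(5)) * 0.5
        d = distance_transform(_connectome(w, "LLLRR"))
        s = smr_matrix(d, all_pairs_shortest_paths(d))
        assert np.all(s.edge_class[s.edge_class != ABSENT] == METRIC)

    def test_ratio_at_least_one_on_random_graphs(self, rng):
        for _ in range(500):
            n = int(rng.integers(5, 12))
            c = random_connected_connectome(rng, n, density=0.5)
            d = distance_transform(c)
            s = smr_matrix(d, all_pairs_shortest_paths(d))
            vals = s.smr[s.edge_class != ABSENT]
            assert np.all(vals >= 1.0)

    def test_raising_edge_weight_never_raises_its_smr(self, rng):
        for _ in range(20):
            c = random_connected_connectome(rng, 8, density=0.6)
            d = distance_transform(c)
            s = smr_matrix(d, all_pairs_shortest_paths(d))
            iu, ju = np.triu_indices(8, k=1)
            cand = [(i, j) for i, j in zip(iu, ju) if 0 < c.weights[i, j] < 0.66]
            if not cand:
                continue
            i, j = cand[int(rng.integers(len(cand)))]
            w2 = c.weights.copy()
            w2[i, j] = w2[j, i] = w2[i, j] * 1.5
            d2 = distance_transform(c.with_weights(w2))
            s2 = smr_matrix(d2, all_pairs_shortest_paths(d2))
            assert s2.smr[i, j] <= s.smr[i, j] + 1e-9

    def test_zero_shortest_path_with_positive_direct_flags_corruption(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        dt = np.zeros((2, 2))
        with pytest.raises(ConnectomeError, match="zero shortest path"):
            smr_matrix(d, dt)


class TestScales:
    def _profile(self, c):
        return semimetric_profile(c)

    def test_mirror_symmetric_network_has_unit_bai(self, rng):
        # build a left block with a detour structure, mirror it, bridge with
        # one homotopic edge per node
        h = 4
        wl = np.zeros((h, h))
        wl[0, 1] = wl[1, 0] = 0.1
        wl[0, 2] = wl[2, 0] = 0.9
        wl[1, 2] = wl[2, 1] = 0.9
        wl[2, 3] = wl[3, 2] = 0.8
        n = 2 * h
        w = np.zeros((n, n))
        w[:h, :h] = wl
        w[h:, h:] = wl
        for k in range(h):
            w[k, h + k] = w[h + k, k] = 0.7
        c = _connectome(w, "L" * h + "R" * h)
        s, summary = self._profile(c)
        assert summary.smr_left == summary.smr_right
        assert summary.bai == pytest.approx(1.0)
        assert summary.smp_left == pytest.approx(summary.smp_right)

    def test_hand_counted_hemispheric_fractions(self):
        # 2L/2R; intra-left edges: one semi-metric of two; intra-right: two
        # metric edges -> right fraction 0, BAI undefined
        w = np.zeros((6, 6))
        w[0, 1] = w[1, 0] = 0.1  # weak direct left edge
        w[0, 2] = w[2, 0] = 0.9
        w[1, 2] = w[2, 1] = 0.9
        w[3, 4] = w[4, 3] = 0.9
        w[4, 5] = w[5, 4] = 0.9
        w[0, 3] = w[3, 0] = 0.5  # interhemispheric bridge
        c = _connectome(w, "LLLRRR")
        d = distance_transform(c)
        s = smr_matrix(d, all_pairs_shortest_paths(d))
        with pytest.raises(ConnectomeError, match="BAI undefined"):
            smr_scales(s, c.regions)
        scales = smr_scales(s, c.regions, zero_right="nan")
        assert scales["smr_left"] == pytest.approx(1 / 3)
        assert scales["smr_right"] == 0
        assert np.isnan(scales["bai"])

    def test_smp_tree_is_zero_at_all_scales(self, rng):
        n = 8
        w = np.zeros((n, n))
        for j in range(1, n):
            i = int(rng.integers(0, j))
            w[i, j] = w[j, i] = rng.uniform(0.2, 1)
        c = _connectome(w, "LLLL" + "RRRR")
        d = distance_transform(c)
        s = smr_matrix(d, all_pairs_shortest_paths(d))
        smp_node, smp_global, smp_left, smp_right = smp_scales(s, c.regions)
        assert np.all(smp_node == 0)
        assert smp_global == smp_left == smp_right == 0

    def test_smp_star_with_weak_rim_edge(self):
        # star around node 0 with strong spokes; one weak rim edge 1-2 is
        # semi-metric; its endpoints have smp 1/degree
        n = 5
        w = np.zeros((n, n))
        for j in range(1, n):
            w[0, j] = w[j, 0] = 0.9
        w[1, 2] = w[2, 1] = 0.05
        c = _connectome(w, "LLLRR")
        d = distance_transform(c)
        s = smr_matrix(d, all_pairs_shortest_paths(d))
        smp_node, smp_global, _, _ = smp_scales(s, c.regions)
        assert s.edge_class[1, 2] == SEMI_METRIC
        assert smp_node[1] == pytest.approx(1 / 2)
        assert smp_node[2] == pytest.approx(1 / 2)
        assert smp_node[0] == 0

    def test_relabeling_equivariance(self, rng):
        c = random_connected_connectome(rng, 10, density=0.5)
        d = distance_transform(c)
        s = smr_matrix(d, all_pairs_shortest_paths(d))
        smp_node, *_ = smp_scales(s, c.regions)
        perm = rng.permutation(10)
        wp = c.weights[np.ix_(perm, perm)]
        regions_p = RegionTable(
            tuple(np.asarray(c.regions.names)[perm]),
            tuple(np.asarray(c.regions.hemispheres)[perm]),
        )
        cp = WeightedConnectome(wp, regions_p, "t")
        dp = distance_transform(cp)
        sp = smr_matrix(dp, all_pairs_shortest_paths(dp))
        np.testing.assert_allclose(
            sp.smr[np.ix_(range(10), range(10))],
            s.smr[np.ix_(perm, perm)],
            equal_nan=True,
        )
        smp_p, *_ = smp_scales(sp, regions_p)
        np.testing.assert_allclose(smp_p, smp_node[perm])
        # hemisphere-respecting permutation leaves all scale summaries intact
        summary = smr_scales(s, c.regions)
        summary_p = smr_scales(sp, regions_p)
        for k in summary:
            assert summary_p[k] == pytest.approx(summary[k])

    def test_disconnected_input_rejected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        w[2, 3] = w[3, 2] = 0.5
        with pytest.raises(ConnectomeError, match="disconnected"):
            analyze_subject(_connectome(w, "LLRR"))

    def test_summary_bounds(self, make_random_connectome):
        c = make_random_connectome(12, density=0.5)
        summary = analyze_subject(c)
        row = summary.as_row()
        for k in ("smr_global", "smr_left", "smr_right", "smr_inter",
                  "smp_global", "smp_left", "smp_right"):
            assert 0.0 <= row[k] <= 1.0
        assert summary.bai > 0
        assert summary.smp_global == pytest.approx(summary.smp_node.mean())
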