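"""Muscle networks: thresholding contract, strength/BC oracles, group analysis."""

import itertools

import numpy as np
import pytest

from musclenet.coherence import BandDefinition, CoherenceConfig
from musclenet.network import (
    BandNetwork,
    betweenness,
    build_adjacency,
    edge_list,
    group_network_analysis,
    node_strength,
    node_strength_mean,
    proportional_threshold,
)

NODES = ("SCM-L", "SCM-R", "SC-L", "SC-R", "UT-L", "UT-R")


def random_symmetric(rng, n=6, density=1.0):
    W = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    w = rng.uniform(0.05, 1.0, size=len(iu))
    keep = rng.uniform(size=len(iu)) < density
    W[iu[keep], ju[keep]] = w[keep]
    return W + W.T


def brute_force_betweenness(W):
    """Exhaustive simple-path enumeration oracle (edge length = 1/weight)."""
    n = W.shape[0]
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        # enumerate all simple s-t paths
        best = np.inf
        shortest_paths = []
        others = [v for v in range(n) if v not in (s, t)]
        for r in range(len(others) + 1):
            for mid in itertools.permutations(others, r):
                path = (s, *mid, t)
                length = 0.0
                ok = True
                for a, b in zip(path[:-1], path[1:]):
                    if W[a, b] <= 0:
                        ok = False
                        break
                    length += 1.0 / W[a, b]
                if not ok:
                    continue
                if length < best:
                    best = length
                    shortest_paths = [path]
                elif length == best:
                    shortest_paths.append(path)
        if not shortest_paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            frac = sum(v in p for p in shortest_paths) / len(shortest_paths)
            bc[v] += frac
    return bc / ((n - 1) * (n - 2) / 2.0)


class TestProportionalThreshold:
    def test_p_one_is_identity(self):
        W = random_symmetric(np.random.default_rng(0))
        np.testing.assert_array_equal(proportional_threshold(W, 1.0), W)

    @pytest.mark.parametrize("p,expected", [(0.2, 3), (0.4, 6), (0.6, 9), (0.8, 12)])
    def test_retained_edge_count(self, p, expected):
        W = random_symmetric(np.random.default_rng(1))
        Wt = proportional_threshold(W, p)
        assert np.count_nonzero(np.triu(Wt, k=1)) == expected

    def test_density_identical_across_scales(self):
        rng = np.random.default_rng(2)
        W = random_symmetric(rng)
        for scale in (0.01, 1.0, 50.0):
            Wt = proportional_threshold(scale * W, 0.4)
            assert np.count_nonzero(np.triu(Wt, k=1)) == 6

    def test_weights_retained_not_binarized(self):
        W = random_symmetric(np.random.default_rng(3))
        Wt = proportional_threshold(W, 0.4)
        kept = Wt[Wt > 0]
        assert np.all(np.isin(kept, W))

    def test_ties_broken_lexicographically(self):
        W = np.ones((6, 6)) - np.eye(6)
        Wt = proportional_threshold(W, 0.2)  # keep 3 of 15 equal edges
        iu, ju = np.nonzero(np.triu(Wt, k=1))
        assert list(zip(iu, ju)) == [(0, 1), (0, 2), (0, 3)]

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError):
            proportional_threshold(np.zeros((6, 6)), 0.0)

    def test_thresholding_never_increases_strength(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            W = random_symmetric(rng)
            for p in (0.2, 0.5, 0.8):
                assert np.all(
                    node_strength(proportional_threshold(W, p))
                    <= node_strength(W) + 1e-12
                )


class TestNodeMetrics:
    def test_complete_uniform_strength(self):
        W = 0.9 * (np.ones((6, 6)) - np.eye(6))
        np.testing.assert_allclose(node_strength(W), 4.5)

    def test_empty_graph(self):
        assert np.all(node_strength(np.zeros((6, 6))) == 0)
        assert np.all(betweenness(np.zeros((6, 6))) == 0)

    def test_strength_equals_row_sums(self):
        W = random_symmetric(np.random.default_rng(5))
        np.testing.assert_allclose(node_strength(W), W.sum(axis=1))

    def test_strength_mean_is_single_edge_scale(self):
        W = 0.9 * (np.ones((6, 6)) - np.eye(6))
        np.testing.assert_allclose(node_strength_mean(W), 0.9)

    def test_complete_uniform_bc_is_zero(self):
        W = 0.7 * (np.ones((6, 6)) - np.eye(6))
        np.testing.assert_allclose(betweenness(W), 0.0, atol=1e-12)

    def test_three_node_path(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.5
        bc = betweenness(W)
        np.testing.assert_allclose(bc, [0.0, 1.0, 0.0])

    def test_bc_scale_invariant(self):
        W = random_symmetric(np.random.default_rng(6), density=0.7)
        np.testing.assert_allclose(betweenness(W), betweenness(10.0 * W), atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_bc_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        W = random_symmetric(rng, density=rng.uniform(0.3, 1.0))
        np.testing.assert_allclose(
            betweenness(W), brute_force_betweenness(W), atol=1e-9
        )


class TestBuildAdjacency:
    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        trials = [rng.standard_normal((6, 2000))]
        net = build_adjacency(
            trials, 1000.0, NODES, BandDefinition("beta", 12, 25), subject="S1",
            task="curvilinear",
        )
        assert net.W.shape == (6, 6)
        np.testing.assert_array_equal(net.W, net.W.T)
        assert np.all(np.diag(net.W) == 0)
        assert np.all((net.W >= 0) & (net.W <= 1))

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        trials = [rng.standard_normal((6, 2000))]
        band = BandDefinition("beta", 12, 25)
        net = build_adjacency(trials, 1000.0, NODES, band)
        perm = [5, 0, 3, 1, 4, 2]
        net_p = build_adjacency(
            [trials[0][perm]], 1000.0, tuple(NODES[i] for i in perm), band
        )
        np.testing.assert_allclose(net_p.W, net.W[np.ix_(perm, perm)], atol=1e-12)

    def test_within_side_only_disconnects_sides(self):
        rng = np.random.default_rng(2)
        trials = [rng.standard_normal((6, 2000))]
        net = build_adjacency(
            trials, 1000.0, NODES, BandDefinition("beta", 12, 25),
            within_side_only=True,
        )
        for i, a in enumerate(NODES):
            for j, b in enumerate(NODES):
                if a.rsplit("-", 1)[1] != b.rsplit("-", 1)[1]:
                    assert net.W[i, j] == 0.0


class TestGroupAnalysis:
    def _networks(self, values_by_subject):
        nets = []
        for idx, (subject, scale) in enumerate(sorted(values_by_subject.items())):
            rng = np.random.default_rng(1000 + idx)
            W = scale * random_symmetric(rng)
            W = np.clip(W, 0, 1)
            nets.append(
                BandNetwork(subject, "curvilinear", "delta", NODES, W)
            )
        return nets

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(3)
        W = np.clip(random_symmetric(rng), 0, 1)
        nets = [
            BandNetwork(s, "curvilinear", "delta", NODES, W)
            for s in ("A1", "A2", "B1", "B2")
        ]
        groups = {"A1": "CNP", "A2": "CNP", "B1": "control", "B2": "control"}
        res = group_network_analysis(nets, groups, p=0.5, metric="strength")
        assert res["test"].p_value == pytest.approx(1.0)
        assert res["group_means"]["CNP"] == pytest.approx(
            res["group_means"]["control"]
        )

    def test_planted_difference_recovered_directionally(self):
        vals = {f"A{i}": 0.3 for i in range(4)} | {f"B{i}": 0.9 for i in range(4)}
        nets = self._networks(vals)
        groups = {s: ("CNP" if s.startswith("A") else "control") for s in vals}
        res = group_network_analysis(nets, groups, p=0.5, metric="strength")
        assert res["group_means"]["CNP"] < res["group_means"]["control"]
        assert res["test"].p_value < 0.05

    def test_small_group_rejected(self):
        nets = self._networks({"A1": 1.0, "B1": 1.0, "B2": 1.0})
        groups = {"A1": "CNP", "B1": "control", "B2": "control"}
        with pytest.raises(ValueError, match="fewer than 2"):
            group_network_analysis(nets, groups)

    def test_unknown_metric_rejected(self):
        nets = self._networks({"A1": 1.0, "A2": 1.0, "B1": 1.0, "B2": 1.0})
        groups = {"A1": "CNP", "A2": "CNP", "B1": "control", "B2": "control"}
        with pytest.raises(ValueError, match="unknown metric"):
            group_network_analysis(nets, groups, metric="clustering")

    def test_edge_list_round_trip(self):
        W = np.zeros((6, 6))
        W[0, 1] = W[1, 0] = 0.5
        W[2, 5] = W[5, 2] = 0.25
        el = edge_list(W, NODES)
        assert len(el) == 2
        assert set(zip(el["node_a"], el["node_b"])) == {
            ("SCM-L", "SCM-R"),
            ("SC-L", "UT-R"),
        }
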