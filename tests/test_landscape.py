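"""MST phenotype landscape and PCA group ellipsoids."""

import math
from itertools import product

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dmvstates import landscape, states


def frame_from_points(points, prefix="s"):
    """Samples as columns; coordinates play the role of gene Z scores."""
    pts = np.asarray(points, dtype=float)
    return pd.DataFrame(
        pts.T,
        index=[f"g{i}" for i in range(pts.shape[1])],
        columns=[f"{prefix}{j}" for j in range(pts.shape[0])],
    )


def brute_force_mst_length(d: np.ndarray) -> float:
    """Minimum total length over all labelled spanning trees (Pruefer codes)."""
    n = d.shape[0]
    best = np.inf
    for code in product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in code:
            degree[v] += 1
        code_list = list(code)
        total = 0.0
        deg = degree[:]
        avail = sorted(i for i in range(n) if deg[i] == 1)
        code_iter = code_list + []
        # standard Pruefer decode
        import heapq
        heap = [i for i in range(n) if deg[i] == 1]
        heapq.heapify(heap)
        for v in code_iter:
            leaf = heapq.heappop(heap)
            total += d[leaf, v]
            deg[v] -= 1
            if deg[v] == 1:
                heapq.heappush(heap, v)
        u = heapq.heappop(heap)
        w = heapq.heappop(heap)
        total += d[u, w]
        best = min(best, total)
    return best


class TestBuildMst:
    def test_collinear_points_form_path(self):
        tree = landscape.build_mst(frame_from_points([[0.0], [1.0], [2.5]]))
        degrees = sorted(d for _, d in tree.graph.degree())
        assert degrees == [1, 1, 2]
        assert tree.graph.has_edge("s0", "s1")
        assert tree.graph.has_edge("s1", "s2")

    def test_matches_exhaustive_spanning_tree_minimum(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 10, size=(6, 3))
        z = frame_from_points(pts)
        tree = landscape.build_mst(z)
        diff = pts[:, None, :] - pts[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        assert tree.total_length == pytest.approx(brute_force_mst_length(d))

    def test_duplicated_sample_keeps_zero_length_edge(self):
        tree = landscape.build_mst(frame_from_points([[0.0], [0.0], [5.0]]))
        lengths = sorted(d["length"] for _, _, d in tree.graph.edges(data=True))
        assert lengths[0] == pytest.approx(0.0)
        assert tree.graph.number_of_edges() == 2
        assert nx.is_connected(tree.graph)

    def test_total_length_invariant_under_sample_permutation(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 4))
        t1 = landscape.build_mst(frame_from_points(pts))
        perm = rng.permutation(10)
        z2 = frame_from_points(pts[perm])
        t2 = landscape.build_mst(z2)
        assert t1.total_length == pytest.approx(t2.total_length)


class TestTreeDistance:
    def path_tree(self, n=5):
        pts = [[float(i)] for i in range(n)]
        return landscape.build_mst(frame_from_points(pts))

    def test_adjacent_nodes_one_hop(self):
        tree = self.path_tree()
        assert landscape.tree_distance(tree, "s0", "s1", metric="edges") == 1

    def test_path_ends(self):
        tree = self.path_tree(5)
        assert landscape.tree_distance(tree, "s0", "s4", metric="edges") == 4
        assert landscape.tree_distance(tree, "s0", "s4", metric="length") == pytest.approx(4.0)

    def test_matches_bfs_oracle(self):
        rng = np.random.default_rng(10)
        pts = rng.uniform(0, 5, size=(9, 3))
        tree = landscape.build_mst(frame_from_points(pts))
        for a in tree.samples:
            oracle = nx.single_source_shortest_path_length(tree.graph, a)
            for b in tree.samples:
                assert landscape.tree_distance(tree, a, b, "edges") == oracle[b]

    def test_path_additivity(self):
        tree = self.path_tree(6)
        d = landscape.tree_distance
        assert d(tree, "s0", "s5", "length") == pytest.approx(
            d(tree, "s0", "s2", "length") + d(tree, "s2", "s5", "length")
        )

    def test_unknown_node_rejected(self):
        tree = self.path_tree()
        with pytest.raises(KeyError):
            landscape.tree_distance(tree, "s0", "nope")


class TestClassifyBranches:
    def partition(self, labels):
        return states.StatePartition(states=pd.Series(labels))

    def test_path_middle_state_transitional(self):
        # states A-A-A - B-B-B - C-C-C along a line
        pts = [[float(i)] for i in range(9)]
        tree = landscape.build_mst(frame_from_points(pts))
        labels = {f"s{i}": "ABC"[i // 3] for i in range(9)}
        calls = landscape.classify_branches(tree, self.partition(labels))
        assert calls.loc["A", "call"] == "terminal"
        assert calls.loc["B", "call"] == "transitional"
        assert calls.loc["C", "call"] == "terminal"

    def test_star_hub_state_transitional(self):
        # hub state H at origin-ish, three pure arms
        pts = [[0.0, 0.0], [0.9, 0.0], [-0.5, 0.8], [-0.5, -0.8],
               [2.0, 0.0], [3.0, 0.0],
               [-1.2, 1.9], [-1.9, 3.0],
               [-1.2, -1.9], [-1.9, -3.0]]
        tree = landscape.build_mst(frame_from_points(pts))
        labels = {"s0": "H", "s1": "H", "s2": "H", "s3": "H",
                  "s4": "X", "s5": "X", "s6": "Y", "s7": "Y",
                  "s8": "Z", "s9": "Z"}
        calls = landscape.classify_branches(tree, self.partition(labels))
        assert calls.loc["H", "call"] == "transitional"
        for arm in "XYZ":
            assert calls.loc[arm, "call"] == "terminal"

    def test_singleton_state_terminal_and_flagged(self):
        pts = [[0.0], [1.0], [2.0]]
        tree = landscape.build_mst(frame_from_points(pts))
        labels = {"s0": "A", "s1": "A", "s2": "B"}
        calls = landscape.classify_branches(tree, self.partition(labels))
        assert calls.loc["B", "call"] == "terminal"
        assert calls.loc["B", "singleton"]

    def test_planted_trajectory_middle_states_transitional(self):
        """Linear state ordering recovered as terminal-transitional-terminal
        in nearly all seeded runs."""
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            centers = {"A": 0.0, "B": 6.0, "C": 12.0}
            pts, labels = [], {}
            i = 0
            for state, c in centers.items():
                for _ in range(12):
                    pts.append([c + rng.normal(0, 0.8), rng.normal(0, 0.8)])
                    labels[f"s{i}"] = state
                    i += 1
            tree = landscape.build_mst(frame_from_points(pts))
            calls = landscape.classify_branches(tree, self.partition(labels))
            ok = (calls.loc["B", "call"] == "transitional"
                  and calls.loc["A", "call"] == "terminal"
                  and calls.loc["C", "call"] == "terminal")
            hits += ok
        assert hits / n_runs >= 0.9


class TestPcaEllipsoids:
    def test_isotropic_group_volume_near_closed_form(self):
        rng = np.random.default_rng(15)
        z = frame_from_points(rng.normal(size=(500, 3)))
        groups = pd.Series("all", index=z.columns)
        out = landscape.pca_ellipsoids(z, groups, n_pc=3, radius_sd=2.0)
        expected = (4 / 3) * math.pi * 2.0**3
        assert abs(out.volumes["all"] - expected) / expected < 0.15

    def test_identical_groups_volume_ratio_near_one(self):
        rng = np.random.default_rng(16)
        pts = rng.normal(size=(400, 5))
        z = frame_from_points(pts)
        groups = pd.Series(["a", "b"] * 200, index=z.columns)
        out = landscape.pca_ellipsoids(z, groups)
        ratio = out.volumes["a"] / out.volumes["b"]
        assert 0.7 < ratio < 1.4

    def test_constrained_group_volume_ratio(self):
        """Scaling each axis SD by 0.5 shrinks the 3D volume ~8-fold."""
        rng = np.random.default_rng(17)
        broad = rng.normal(size=(600, 3))
        tight = 0.5 * rng.normal(size=(600, 3))
        z = frame_from_points(np.vstack([broad, tight]))
        groups = pd.Series(["broad"] * 600 + ["tight"] * 600, index=z.columns)
        out = landscape.pca_ellipsoids(z, groups)
        ratio = out.volumes["tight"] / out.volumes["broad"]
        assert abs(ratio - 0.125) < 0.05

    def test_nested_group_containment(self):
        """A constrained group's points sit inside the broad ellipsoid at
        least as often as nominal 2-SD coverage."""
        rng = np.random.default_rng(18)
        broad = rng.normal(size=(500, 3))
        tight = 0.4 * rng.normal(size=(500, 3))
        z = frame_from_points(np.vstack([broad, tight]))
        groups = pd.Series(["broad"] * 500 + ["tight"] * 500, index=z.columns)
        out = landscape.pca_ellipsoids(z, groups, radius_sd=2.0)
        # chi-3 coverage at 2 SD is ~0.739; nested tight points should beat it
        assert out.containment.loc["tight", "broad"] >= 0.739

    def test_degenerate_group_flagged(self):
        pts = np.zeros((10, 3))
        pts[:5] = np.random.default_rng(0).normal(size=(5, 3))
        z = frame_from_points(pts)
        groups = pd.Series(["a"] * 5 + ["flat"] * 5, index=z.columns)
        out = landscape.pca_ellipsoids(z, groups)
        assert out.degenerate["flat"]
        assert out.volumes["flat"] == 0.0

    def test_too_small_group_rejected(self):
        z = frame_from_points(np.random.default_rng(1).normal(size=(6, 4)))
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=z.columns)
        with pytest.raises(ValueError, match="too small"):
            landscape.pca_ellipsoids(z, groups, n_pc=3)
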