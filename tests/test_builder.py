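import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spherecon as sc
from spherecon.builder import streamline_length
from spherecon.io import DenseConnectome, ValidationError
from spherecon.parcellation import NodeAssignment


class TestStreamlineLength:
    def test_345_triangle(self):
        assert streamline_length([(0, 0, 0), (3, 4, 0)]) == pytest.approx(5.0)

    def test_two_unit_segments(self):
        assert streamline_length(
            [(0, 0, 0), (1, 0, 0), (1, 1, 0)]) == pytest.approx(2.0)

    def test_single_point_rejected(self):
        with pytest.raises(ValidationError):
            streamline_length([(0, 0, 0)])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 12))
    def test_matches_pairwise_sum_oracle(self, seed, npts):
        poly = np.random.default_rng(seed).normal(size=(npts, 3)) * 30
        oracle = sum(float(np.linalg.norm(poly[i + 1] - poly[i]))
                     for i in range(npts - 1))
        assert streamline_length(poly) == pytest.approx(oracle, rel=1e-12)


class TestFilterByLength:
    def test_zero_threshold_keeps_all(self, rng):
        lines = sc.StreamlineSet([rng.normal(size=(3, 3)) for _ in range(5)])
        kept, rep = sc.filter_by_length(lines, 0.0)
        assert rep.n_kept == 5 and rep.n_removed == 0

    def test_boundary_case(self):
        lines = sc.StreamlineSet([[(0, 0, 0), (4, 0, 0)],
                                  [(0, 0, 0), (6, 0, 0)]])
        kept, rep = sc.filter_by_length(lines, 5.0)
        assert rep.n_kept == 1 and rep.n_removed == 1
        assert streamline_length(kept[0]) == pytest.approx(6.0)

    def test_negative_threshold_rejected(self, rng):
        lines = sc.StreamlineSet([rng.normal(size=(2, 3))])
        with pytest.raises(ValidationError):
            sc.filter_by_length(lines, -1.0)

    def test_matches_brute_force_filter(self, rng):
        lines = sc.StreamlineSet([
            rng.normal(size=(rng.integers(2, 8), 3)) * rng.uniform(1, 10)
            for _ in range(100)])
        kept, rep = sc.filter_by_length(lines, 15.0)
        oracle = [s for s in lines if streamline_length(s) >= 15.0]
        assert rep.n_input == 100 and len(kept) == len(oracle)
        for a, b in zip(kept, oracle):
            np.testing.assert_array_equal(a, b)


class TestDenseConnectome:
    def surface(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0], [30, 0, 0],
                        [40, 0, 0], [0, 10, 0], [0, 20, 0], [0, 30, 0],
                        [0, 40, 0], [0, 0, 10]], dtype=float)
        return sc.SurfacePointCloud(pts)

    def test_endpoints_on_surface_points(self):
        surf = self.surface()
        lines = sc.StreamlineSet([[surf.points[4], [20, 20, 20],
                                   surf.points[9]]])
        dense = sc.build_dense_connectome(lines, surf, 2.0)
        assert dense.counts == {(4, 9): 1}

    def test_same_point_both_endpoints_skipped(self):
        surf = self.surface()
        lines = sc.StreamlineSet([[[0.5, 0, 0], [5, 5, 5], [0, 0.5, 0]]])
        dense = sc.build_dense_connectome(lines, surf, 2.0)
        assert dense.counts == {} and dense.n_unmapped == 1

    def test_out_of_radius_endpoint_skipped(self):
        surf = self.surface()
        lines = sc.StreamlineSet([[[100, 100, 100], surf.points[2]]])
        dense = sc.build_dense_connectome(lines, surf, 2.0)
        assert dense.counts == {} and dense.n_unmapped == 1

    def test_matches_exhaustive_scan_oracle(self, rng):
        surf = sc.SurfacePointCloud(rng.normal(size=(40, 3)) * 30)
        lines = []
        for _ in range(50):
            a, b = rng.integers(0, 40, size=2)
            jitter = rng.normal(scale=0.5, size=(2, 3))
            lines.append([surf.points[a] + jitter[0], [0, 0, 0],
                          surf.points[b] + jitter[1]])
        dense = sc.build_dense_connectome(sc.StreamlineSet(lines), surf, 2.0)
        oracle: dict = {}
        skipped = 0
        for line in lines:
            pair = []
            for end in (line[0], line[2]):
                d = np.linalg.norm(surf.points - end, axis=1)
                k = int(np.argmin(d))
                pair.append(k if d[k] <= 2.0 else None)
            i, j = pair
            if i is None or j is None or i == j:
                skipped += 1
                continue
            key = (min(i, j), max(i, j))
            oracle[key] = oracle.get(key, 0) + 1
        assert dense.counts == oracle
        assert dense.n_unmapped == skipped


class TestDownscale:
    def test_intra_node_pairs_discarded(self):
        dense = DenseConnectome(n_points=4, counts={(0, 1): 2, (2, 3): 1})
        assignment = NodeAssignment(labels=[0, 0, 1, 1], N=3)
        net = sc.downscale(dense, assignment)
        assert net.nnz == 0

    def test_counts_summed_across_nodes(self):
        dense = DenseConnectome(n_points=4, counts={(0, 2): 3, (1, 3): 2})
        assignment = NodeAssignment(labels=[2, 2, 7, 7], N=8)
        net = sc.downscale(dense, assignment)
        assert net.weights[2, 7] == 5 and net.adjacency[2, 7] == 1
        assert net.n_edges == 1

    def test_label_coverage_checked(self):
        dense = DenseConnectome(n_points=4, counts={(0, 3): 1})
        assignment = NodeAssignment(labels=[0, 1], N=2)
        with pytest.raises(ValidationError, match="not covered"):
            sc.downscale(dense, assignment)

    def test_nnz_is_twice_edge_count(self, rng):
        dense = DenseConnectome(
            n_points=30,
            counts={(int(i), int(j)): 1
                    for i, j in rng.integers(0, 30, size=(40, 2)) if i < j})
        assignment = NodeAssignment(labels=rng.integers(0, 6, size=30), N=6)
        net = sc.downscale(dense, assignment)
        assert net.nnz == 2 * net.n_edges
        assert net.nnz == np.count_nonzero(net.adjacency)

    def test_commutes_with_merging_duplicate_pairs(self):
        labels = NodeAssignment(labels=[0, 1, 2, 2], N=3)
        split = DenseConnectome(n_points=4, counts={(0, 1): 1, (0, 2): 2,
                                                    (0, 3): 1})
        merged = DenseConnectome(n_points=4, counts={(0, 1): 1, (0, 2): 3})
        a = sc.downscale(split, labels)
        # (0,2) and (0,3) both span nodes 0-2, so merging them changes nothing
        np.testing.assert_array_equal(a.weights,
                                      sc.downscale(merged, labels).weights)


class TestNodeSplittingDiscretization:
    def test_straddling_bundle_doubles_binary_connections(self):
        """A coherent bundle on a node border yields two binary connections
        to a third node; contained within one node, only one."""
        # surface points: bundle origin region at x ~ 0/1, target at x = 30
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [30.0, 0, 0],
                        [0, 30.0, 0]])
        surf = sc.SurfacePointCloud(pts)
        dense = sc.build_dense_connectome(sc.StreamlineSet([
            [pts[0], [15, 5, 0], pts[2]],
            [pts[1], [15, -5, 0], pts[2]],
        ]), surf, 2.0)
        # bundle contained in one node -> one binary connection
        contained = sc.downscale(dense, NodeAssignment([0, 0, 1, 2], N=3))
        assert contained.n_edges == 1
        assert contained.weights[0, 1] == 2
        # boundary splits the bundle's node -> two binary connections
        split = sc.downscale(dense, NodeAssignment([0, 1, 2, 3], N=4))
        assert split.n_edges == 2
        assert split.adjacency[0, 2] == 1 and split.adjacency[1, 2] == 1
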