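import numpy as np
import pytest

import spherecon as sc
from spherecon.alignment import (ConstantTriangleError, exhaustive_align,
                                 lower_triangle)
from spherecon.io import ValidationError
from spherecon.phantom import make_cohort, make_ground_truth_network


def permuted_copy(net, seed):
    perm = np.random.default_rng(seed).permutation(net.N)
    return sc.BinaryNetwork(adjacency=net.adjacency[np.ix_(perm, perm)]), perm


def near_distinct_degree_net(n):
    """Threshold-style graph: i ~ j iff i + j < n; degrees n-1, n-2, ...
    with a single tied pair — as distinctive as a simple graph allows."""
    A = (np.add.outer(np.arange(n), np.arange(n)) < n).astype(int)
    np.fill_diagonal(A, 0)
    return sc.BinaryNetwork(adjacency=A)


class TestPearsonLowerTriangle:
    def test_element_counts(self):
        assert len(lower_triangle(np.zeros((100, 100)))) == 4950
        assert len(lower_triangle(np.zeros((95, 95)))) == 4465

    def test_self_correlation(self, small_net):
        assert sc.pearson_lower_triangle(small_net, small_net) == \
            pytest.approx(1.0)

    def test_complement_anticorrelates(self, small_net):
        comp = 1 - small_net.adjacency
        np.fill_diagonal(comp, 0)
        other = sc.BinaryNetwork(adjacency=comp)
        assert sc.pearson_lower_triangle(small_net, other) == \
            pytest.approx(-1.0)

    def test_size_mismatch(self, small_net):
        other = make_ground_truth_network(9, 2, 0.8, 0.2, seed=0)
        with pytest.raises(ValidationError, match="mismatch"):
            sc.pearson_lower_triangle(small_net, other)

    def test_constant_triangle_undefined(self, small_net):
        empty = sc.BinaryNetwork(adjacency=np.zeros((8, 8), dtype=int))
        with pytest.raises(ConstantTriangleError):
            sc.pearson_lower_triangle(small_net, empty)

    def test_invariant_under_shared_permutation(self, rng):
        A = make_ground_truth_network(20, 2, 0.7, 0.2, seed=1)
        B = make_ground_truth_network(20, 2, 0.7, 0.2, seed=2)
        r0 = sc.pearson_lower_triangle(A, B)
        p = rng.permutation(20)
        r1 = sc.pearson_lower_triangle(
            sc.BinaryNetwork(adjacency=A.adjacency[np.ix_(p, p)]),
            sc.BinaryNetwork(adjacency=B.adjacency[np.ix_(p, p)]))
        assert r1 == pytest.approx(r0, abs=1e-12)


class TestSaAlign:
    def test_identical_networks_align_trivially(self, small_net):
        res = sc.sa_align(small_net, small_net, restarts=5, iterations=20,
                          seed=0)
        assert res.cost == 0 and res.r_after == pytest.approx(1.0)

    def test_matches_exhaustive_on_permuted_copy(self):
        net = make_ground_truth_network(7, 2, 0.8, 0.15, seed=3)
        moved, _ = permuted_copy(net, 4)
        ex = exhaustive_align(net, moved)
        res = sc.sa_align(net, moved, restarts=20, iterations=50, seed=5)
        assert ex.cost == 0
        assert res.cost == 0 and res.r_after == pytest.approx(1.0)

    def test_never_worse_than_identity(self):
        A = make_ground_truth_network(20, 2, 0.6, 0.3, seed=6)
        B = make_ground_truth_network(20, 2, 0.6, 0.3, seed=7)
        res = sc.sa_align(A, B, restarts=10, iterations=40, seed=8)
        id_cost = float(np.abs(A.adjacency - B.adjacency).sum())
        assert res.cost <= id_cost
        assert res.r_after >= res.r_before

    def test_deterministic_given_seed(self):
        A = make_ground_truth_network(15, 3, 0.7, 0.2, seed=9)
        B = make_ground_truth_network(15, 3, 0.7, 0.2, seed=10)
        r1 = sc.sa_align(A, B, restarts=5, iterations=30, seed=42)
        r2 = sc.sa_align(A, B, restarts=5, iterations=30, seed=42)
        np.testing.assert_array_equal(r1.permutation, r2.permutation)
        assert r1.cost == r2.cost and r1.r_after == r2.r_after

    def test_permutation_recovery_distinct_degrees(self):
        net = near_distinct_degree_net(30)
        for seed in range(5):
            moved, _ = permuted_copy(net, 100 + seed)
            res = sc.sa_align(net, moved, restarts=10, iterations=50,
                              seed=seed)
            assert res.cost == 0
            assert res.r_after == pytest.approx(1.0)

    def test_size_mismatch_rejected(self, small_net):
        other = make_ground_truth_network(9, 2, 0.8, 0.2, seed=0)
        with pytest.raises(ValidationError):
            sc.sa_align(small_net, other)


class TestGroupAlignment:
    def test_identical_cohort_all_ones(self, small_net):
        group = sc.pairwise_align_group([small_net, small_net], restarts=3,
                                        iterations=10, seed=0)
        np.testing.assert_allclose(group.r_matrix, 1.0)

    def test_permuted_cohort_recovers_unity(self):
        """Subjects that are node permutations of one distinctive-degree
        network align back to perfect correlation."""
        truth = near_distinct_degree_net(20)
        subjects = [s.network for s in make_cohort(
            truth, n_subjects=4, edge_flip_rate=0.0, permute_nodes=True,
            seed=13)]
        group = sc.pairwise_align_group(subjects, restarts=20, iterations=80,
                                        seed=14)
        np.testing.assert_allclose(group.r_matrix, 1.0, atol=1e-9)

    def test_needs_two_subjects(self, small_net):
        with pytest.raises(ValidationError):
            sc.pairwise_align_group([small_net])

    def test_diagonal_is_one(self):
        nets = [make_ground_truth_network(12, 2, 0.7, 0.2, seed=s)
                for s in range(3)]
        group = sc.pairwise_align_group(nets, restarts=3, iterations=15,
                                        seed=1)
        np.testing.assert_array_equal(np.diag(group.r_matrix), 1.0)


class TestSelectReference:
    def test_planted_typical_member_wins(self):
        """Three perturbed copies of one base network: the base has the
        highest mean correlation and is selected."""
        base = make_ground_truth_network(20, 4, 0.9, 0.05, seed=15)
        rng = np.random.default_rng(16)
        subjects = [base]
        for _ in range(3):
            A = base.adjacency.copy()
            ii, jj = np.tril_indices(20, k=-1)
            flip = rng.random(len(ii)) < 0.05
            for i, j in zip(ii[flip], jj[flip]):
                A[i, j] = A[j, i] = 1 - A[i, j]
            subjects.append(sc.BinaryNetwork(adjacency=A))
        group = sc.pairwise_align_group(subjects, restarts=5, iterations=30,
                                        seed=17)
        ref = sc.select_reference(group)
        # verify against a brute-force mean-r comparison
        off = group.r_matrix.copy()
        np.fill_diagonal(off, np.nan)
        assert ref == int(np.nanargmax(np.nanmean(off, axis=1)))
        assert ref == 0

    def test_tie_breaks_to_lowest_index(self, small_net):
        group = sc.pairwise_align_group([small_net] * 3, restarts=2,
                                        iterations=5, seed=0)
        assert sc.select_reference(group) == 0


class TestSumNetwork:
    def test_identical_cohort_counts_all_or_nothing(self, small_net):
        group = sc.pairwise_align_group([small_net] * 4, restarts=2,
                                        iterations=5, seed=0)
        sc.select_reference(group)
        summed = sc.sum_network(group)
        assert set(np.unique(summed.counts)) <= {0, 4}
        np.testing.assert_array_equal((summed.counts == 4).astype(int),
                                      small_net.adjacency)

    def test_permuted_cohort_counts_all_or_nothing(self):
        truth = near_distinct_degree_net(20)
        subjects = [s.network for s in make_cohort(
            truth, n_subjects=4, edge_flip_rate=0.0, permute_nodes=True,
            seed=19)]
        group = sc.pairwise_align_group(subjects, restarts=20, iterations=80,
                                        seed=20)
        sc.select_reference(group)
        summed = sc.sum_network(group)
        assert set(np.unique(summed.counts)) <= {0, 4}

    def test_requires_reference(self, small_net):
        group = sc.pairwise_align_group([small_net] * 2, restarts=2,
                                        iterations=5, seed=0)
        with pytest.raises(ValidationError, match="reference"):
            sc.sum_network(group)


@pytest.fixture(scope="module")
def phantom_subject():
    spec = sc.phantom.PhantomSpec(n_true=30, n_modules=3, p_in=0.8,
                                  p_out=0.1, n_surface_points=1500,
                                  streamlines_per_edge=2, seed=30)
    return sc.phantom.make_subject(spec)


class TestRotationAnalysis:
    def test_table_layout_and_baseline(self, phantom_subject):
        sub = phantom_subject
        table = sc.rotation_analysis(
            sub.surface, sub.streamlines, n_nodes=30,
            restarts=5, iterations=30, n_random=5, rewires_per_edge=5,
            seed=31)
        assert len(table) == 7  # baseline + 6 rotations
        base = table[table.rotation == (0, 0, 0)].iloc[0]
        assert base.r_after == 1.0
        assert {"nnz", "n_components", "Cr", "Lr", "Q",
                "r_after", "connected"} <= set(table.columns)

    def test_rotation_changes_discretization(self, phantom_subject):
        """Rotating the parcellation shifts node boundaries and changes
        the binary connection count (node-discretization error)."""
        sub = phantom_subject
        table = sc.rotation_analysis(
            sub.surface, sub.streamlines, n_nodes=30,
            angles=[(0, 0, 0), (0, 0, 25)],
            restarts=5, iterations=30, n_random=5, rewires_per_edge=5,
            seed=32)
        nnz = table.set_index("rotation").nnz
        assert nnz[(0, 0, 25)] != nnz[(0, 0, 0)]

    def test_grid_must_include_baseline(self, phantom_subject):
        sub = phantom_subject
        with pytest.raises(ValidationError):
            sc.rotation_analysis(sub.surface, sub.streamlines, n_nodes=30,
                                 angles=[(10, 0, 0)])
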