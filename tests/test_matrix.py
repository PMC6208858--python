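"""Distance-matrix construction and metric-axiom checks."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import treemetrics as tm
from treemetrics.matrix import DistanceMatrix, DistanceMatrixError


class TestConstruction:
    def test_validates_shape_diagonal_symmetry_sign(self):
        with pytest.raises(DistanceMatrixError):
            DistanceMatrix(["a", "b", "c"], np.zeros((2, 2)))
        with pytest.raises(DistanceMatrixError):
            DistanceMatrix(["a", "b"], [[1.0, 1.0], [1.0, 0.0]])
        with pytest.raises(DistanceMatrixError):
            DistanceMatrix(["a", "b"], [[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(DistanceMatrixError):
            DistanceMatrix(["a", "b"], [[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(DistanceMatrixError):
            DistanceMatrix(["a", "a"], np.zeros((2, 2)))

    def test_pseudometric_zero_offdiagonal_is_representable(self):
        # M1 is a check, not a constructor requirement
        D = DistanceMatrix(["a", "b", "c"],
                           [[0, 0, 1], [0, 0, 1], [1, 1, 0]])
        m1, m3 = tm.check_metric(D)
        assert not m1.holds and m3.holds

    def test_permute_and_get(self, eq3):
        P = eq3.permute(("y", "x", "v", "u"))
        assert P.get("u", "y") == eq3.get("y", "u") == 0.753


class TestCheckMetric:
    def test_worked_matrix_is_a_metric(self, eq3):
        assert all(r.holds for r in tm.check_metric(eq3))

    def test_discrete_two_point_metric(self):
        D = DistanceMatrix(["a", "b"], [[0, 1], [1, 0]])
        assert all(r.holds for r in tm.check_metric(D))
        assert tm.check_four_point(D).holds
        assert tm.check_ultrametric(D).holds

    def test_triangle_violation_magnitude_and_witness(self):
        D = DistanceMatrix(["x", "y", "z"], [[0, 5, 10], [5, 0, 1], [10, 1, 0]])
        m1, m3 = tm.check_metric(D)
        assert m1.holds
        assert not m3.holds
        assert m3.worst_violation == pytest.approx(4.0)
        assert set(m3.witnesses) == {"x", "y", "z"}


class TestFourPoint:
    def test_tree_metrics_pass(self, random_tree_factory):
        for seed in (0, 1, 2):
            T = random_tree_factory(8, seed)
            assert tm.check_four_point(T.distance_matrix(), tol=1e-9).holds

    def test_worked_matrix_quartet_sums(self, eq3):
        # pair sums 1.054, 1.144, 1.012 -> excess of largest over middle 0.090
        rep = tm.check_four_point(eq3, tol=0.01)
        assert not rep.holds
        assert rep.worst_violation == pytest.approx(0.090, abs=1e-12)
        assert tm.check_four_point(eq3, tol=0.1).holds

    def test_inverse_transform_restores_additivity_to_rounding(self, eq3, saturating10):
        T = saturating10.invert_matrix(eq3)
        assert tm.check_four_point(T, tol=0.05).holds
        assert not tm.check_four_point(T, tol=1e-6).holds

    def test_small_matrices_trivially_additive(self):
        D = DistanceMatrix(["a", "b", "c"], [[0, 2, 3], [2, 0, 4], [3, 4, 0]])
        assert tm.check_four_point(D).holds


class TestUltrametric:
    def test_clock_tree_is_ultrametric_and_additive(self):
        # two cherries hanging at equal depth from the root
        adj = {
            0: {4: 1.0}, 1: {4: 1.0}, 2: {5: 1.5}, 3: {5: 1.5},
            4: {0: 1.0, 1: 1.0, 6: 1.0}, 5: {2: 1.5, 3: 1.5, 6: 0.5},
            6: {4: 1.0, 5: 0.5},
        }
        T = tm.PhyloTree(adj, {0: "a", 1: "b", 2: "c", 3: "d"})
        D = T.distance_matrix()
        assert tm.check_ultrametric(D).holds
        assert tm.check_four_point(D, tol=1e-9).holds  # MU implies MA

    def test_worked_matrix_is_not_ultrametric(self, eq3):
        rep = tm.check_ultrametric(eq3)
        assert not rep.holds and rep.worst_violation > 0

    def test_two_point_matrix(self):
        D = DistanceMatrix(["a", "b"], [[0, 3], [3, 0]])
        assert tm.check_ultrametric(D).holds


class TestQuadruple:
    def test_worked_matrix_calls_wrong_pairing(self, eq3):
        call = tm.quadruple(eq3, "u", "v", "x", "y")
        assert call.topology == "uy|vx"
        assert call.sums["uv|xy"] == pytest.approx(1.054)
        assert call.sums["ux|vy"] == pytest.approx(1.144)
        assert call.sums["uy|vx"] == pytest.approx(1.012)

    def test_inverse_transform_flips_the_call(self, eq3, saturating10):
        T = saturating10.invert_matrix(eq3)
        assert tm.quadruple(T, "u", "v", "x", "y").topology == "uv|xy"

    def test_perfect_tie_is_unresolved(self):
        D = DistanceMatrix(list("abcd"), np.ones((4, 4)) - np.eye(4))
        assert tm.quadruple(D, "a", "b", "c", "d").topology == "unresolved"

    def test_duplicate_labels_rejected(self, eq3):
        with pytest.raises(ValueError):
            tm.quadruple(eq3, "u", "u", "x", "y")

    @settings(derandomize=True, max_examples=30)
    @given(perm=st.permutations(range(4)))
    def test_invariant_under_matrix_permutation(self, perm):
        D = tm.worked_example()
        order = [D.labels[i] for i in perm]
        P = D.permute(order)
        a = tm.quadruple(D, "u", "v", "x", "y")
        b = tm.quadruple(P, "u", "v", "x", "y")
        assert a.topology == b.topology
        assert a.sums == pytest.approx(b.sums)


class TestMonotoneConsistency:
    def test_scaling_preserves_both_modes(self, eq3):
        D2 = DistanceMatrix(eq3.labels, 2.0 * eq3.values)
        assert tm.check_monotone_consistency(eq3, D2, "m0").holds
        assert tm.check_monotone_consistency(eq3, D2, "m1").holds

    def test_strictly_increasing_transform_preserves_strong_form(self, eq3):
        Z = tm.StretchedExponential(a=1.0, b=0.7, c=0.9)
        assert tm.check_monotone_consistency(eq3, Z.apply(eq3), "m1").holds

    def test_single_rank_swap_is_caught(self, random_tree_factory):
        T = random_tree_factory(6, 5).distance_matrix()
        v = T.values.copy()
        iu = list(zip(*np.triu_indices(T.n, k=1)))
        order = sorted(iu, key=lambda ij: v[ij])
        (i1, j1), (i2, j2) = order[0], order[1]
        v[i1, j1] = v[j1, i1] = T.values[i2, j2]
        v[i2, j2] = v[j2, i2] = T.values[i1, j1]
        D2 = DistanceMatrix(T.labels, v)
        rep = tm.check_monotone_consistency(T, D2, "m1")
        assert not rep.holds and rep.n_violations >= 1

    def test_label_mismatch_rejected(self, eq3):
        other = DistanceMatrix(["p", "q"], [[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            tm.check_monotone_consistency(eq3, other)
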