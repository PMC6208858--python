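"""Transform families: inverses, preservation properties, combinations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import treemetrics as tm
from treemetrics.matrix import DistanceMatrix


class TestForwardAndInverse:
    def test_amenability_every_family_is_zero_at_zero(self):
        for z in (
            tm.Affine(alpha=2.0, beta=0.3),
            tm.StretchedExponential(a=0.75, b=4 / 3, c=1.0),
            tm.JukesCantor(4),
            tm.NegLogSaturation(s=10, m=1),
        ):
            assert float(z(0.0)) == 0.0

    def test_saturating_inverse_of_worked_entry(self):
        z = tm.NegLogSaturation(s=10, m=1)
        assert float(z.inverse(0.503)) == pytest.approx(6.9917, abs=5e-4)

    def test_jukes_cantor_saturates_at_three_quarters(self):
        z = tm.JukesCantor(4)
        assert float(z(1e6)) == pytest.approx(0.75)
        assert z.range_sup == 0.75

    def test_jukes_cantor_equals_matching_stretched_exponential(self):
        z1, z2 = tm.JukesCantor(4), tm.StretchedExponential(a=0.75, b=4 / 3, c=1.0)
        t = np.linspace(0, 5, 50)
        assert np.allclose(z1(t), z2(t), atol=1e-15)

    @settings(derandomize=True, max_examples=50)
    @given(
        t=st.lists(st.floats(0.0, 5.0), min_size=1, max_size=8),
        a=st.floats(0.5, 2.0),
        b=st.floats(0.5, 2.0),
        c=st.floats(0.5, 1.5),
    )
    def test_roundtrip_identity_on_valid_range(self, t, a, b, c):
        z = tm.StretchedExponential(a=a, b=b, c=c)
        t = np.asarray(t)
        assert np.allclose(z.inverse(z(t)), t, atol=1e-10, rtol=1e-10)

    def test_matrix_roundtrip(self, random_tree_factory):
        T = random_tree_factory(8, 11).distance_matrix()
        z = tm.StretchedExponential(a=3.0, b=0.5, c=0.8)
        back = z.invert_matrix(z.apply(T))
        assert back.allclose(T, atol=1e-10)

    def test_inversion_at_saturation_errors_with_pairs(self):
        z = tm.StretchedExponential(a=0.75, b=1.0, c=1.0)
        D = DistanceMatrix(["a", "b", "c"],
                           [[0, 0.75, 0.2], [0.75, 0, 0.2], [0.2, 0.2, 0]])
        with pytest.raises(tm.SaturationError) as exc:
            z.invert_matrix(D)
        assert ("a", "b") in exc.value.pairs

    def test_affine_inverse_respects_offset(self):
        z = tm.Affine(alpha=2.0, beta=0.5)
        assert float(z.inverse(z(3.0))) == pytest.approx(3.0)
        assert float(z.inverse(0.0)) == 0.0

    def test_custom_numerical_inverse(self):
        z = tm.CustomTransform(lambda t: t / (1 + t), name="bounded", range_sup=1.0)
        assert float(z.inverse(0.5)) == pytest.approx(1.0, abs=1e-9)


class TestPreservationCheck:
    def test_concave_saturating_family_passes(self):
        rep = tm.check_preserving(tm.StretchedExponential(a=0.75, b=4 / 3, c=1.0))
        assert rep.all_hold

    def test_identity_passes(self):
        rep = tm.check_preserving(tm.Affine(alpha=1.0, beta=0.0))
        assert rep.all_hold

    def test_square_fails_subadditivity_with_witness(self):
        rep = tm.check_preserving(tm.CustomTransform(lambda t: t * t, name="square"))
        holds, worst, witness = rep.properties["Z2"]
        assert not holds and worst > 0
        t, u = witness
        assert (t + u) ** 2 - (t**2 + u**2) == pytest.approx(worst)

    def test_concave_transform_of_a_metric_is_a_metric(self, random_tree_factory):
        # c <= 1 makes the curve concave + amenable, hence metric-preserving
        for seed in (0, 1, 2):
            D = random_tree_factory(7, seed).distance_matrix()
            z = tm.StretchedExponential(a=1.0, b=2.0, c=0.8)
            assert all(r.holds for r in tm.check_metric(z.apply(D)))


class TestAdditivityInteraction:
    def test_affine_preserves_four_point(self, random_tree_factory):
        T = random_tree_factory(9, 7).distance_matrix()
        z = tm.Affine(alpha=2.5, beta=0.4)
        assert tm.check_four_point(z.apply(T), tol=1e-9).holds

    def test_monotone_transform_preserves_rank_consistency(self, random_tree_factory):
        T = random_tree_factory(7, 3).distance_matrix()
        z = tm.JukesCantor(4)
        assert tm.check_monotone_consistency(T, z.apply(T), "m1").holds

    def test_nonlinear_distortion_flips_a_quartet(self, eq3, saturating10):
        # an additive matrix whose image under a smooth concave transform
        # calls the opposite quartet: the distance analogue of long-branch
        # attraction
        T = saturating10.invert_matrix(eq3)
        before = tm.quadruple(T, "u", "v", "x", "y").topology
        after = tm.quadruple(saturating10.apply(T), "u", "v", "x", "y").topology
        assert before == "uv|xy" and after == "uy|vx"


class TestCombineMetrics:
    def test_single_matrix_identity(self, eq3):
        ct = tm.CombinedTransform((1.0,), (0.0,))
        assert tm.combine_metrics([eq3], ct).allclose(eq3)

    def test_two_additive_matrices_from_one_tree_stay_additive(
        self, random_tree_factory
    ):
        T = random_tree_factory(8, 2).distance_matrix()
        T2 = DistanceMatrix(T.labels, 3.0 * T.values)
        ct = tm.CombinedTransform((1.0, 1.0), (0.0, 0.0))
        out = tm.combine_metrics([T, T2], ct)
        assert tm.check_four_point(out, tol=1e-9).holds

    def test_pure_discrete_combination(self, eq3):
        ct = tm.CombinedTransform((0.0, 0.0), (1.0, 1.0))
        out = tm.combine_metrics([eq3, eq3], ct)
        off = out.offdiag()
        assert np.all(off == 2.0)

    def test_all_zero_weights_for_a_feature_rejected(self):
        with pytest.raises(ValueError):
            tm.CombinedTransform((0.0, 1.0), (0.0, 1.0))

    def test_label_mismatch_rejected(self, eq3):
        other = DistanceMatrix(["p", "q", "r", "s"], eq3.values)
        ct = tm.CombinedTransform((1.0, 1.0), (0.0, 0.0))
        with pytest.raises(ValueError):
            tm.combine_metrics([eq3, other], ct)

    def test_transform_spec_parsing_roundtrip(self):
        z = tm.parse_transform_spec("stretched_exp a=0.75 b=1.0 c=1.0")
        assert z.family == "stretched_exp"
        assert z.params == {"a": 0.75, "b": 1.0, "c": 1.0}
        with pytest.raises(ValueError):
            tm.parse_transform_spec("no_such_family a=1")
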