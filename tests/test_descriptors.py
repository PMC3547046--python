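"""Feature mappings and covariance descriptors: frozen toy values, a naive
accumulation oracle, and the invariances the normalisation is for."""

import numpy as np
import pytest

import cellcov as cc
from cellcov import Subwindow


def brute_force_covariance(planes, window):
    """Per-pixel accumulation with explicit loops (divisor n-1)."""
    d = planes.shape[0]
    rs, cs = window.slices()
    vecs = []
    for r in range(rs.start, rs.stop):
        for c in range(cs.start, cs.stop):
            vecs.append([planes[f, r, c] for f in range(d)])
    vecs = np.array(vecs)
    mu = vecs.mean(axis=0)
    C = np.zeros((d, d))
    for v in vecs:
        C += np.outer(v - mu, v - mu)
    return C / (len(vecs) - 1)


def random_feature_map(rng, d=4, size=16):
    return cc.FeatureMap(rng.random((d, size, size)), "F1")


class TestRegionCovariance:
    def test_constant_window_gives_zero_matrix(self):
        fm = cc.FeatureMap(np.full((3, 8, 8), 0.7), "F1")
        cd = cc.region_covariance(fm, Subwindow(0, 0, 8))
        np.testing.assert_allclose(cd.matrix, 0.0, atol=1e-15)

    def test_two_point_toy_example(self):
        # two feature vectors (0,0) and (2,2): mean (1,1), each deviation
        # outer product is [[1,1],[1,1]], summed and divided by n-1 = 1
        z = np.array([[0.0, 2.0], [0.0, 2.0]])
        np.testing.assert_allclose(cc.sample_covariance(z), [[2, 2], [2, 2]])

    def test_single_sample_is_degenerate(self):
        with pytest.raises(cc.DegenerateInputError):
            cc.sample_covariance(np.zeros((3, 1)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_accumulation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        fm = random_feature_map(rng, d=5, size=16)
        w = Subwindow(int(rng.integers(0, 8)), int(rng.integers(0, 8)), 8)
        got = cc.region_covariance(fm, w).matrix
        want = brute_force_covariance(fm.planes, w)
        assert np.abs(got - want).max() <= 1e-10
        # symmetry and positive semidefiniteness
        assert np.abs(got - got.T).max() <= 1e-12
        assert np.linalg.eigvalsh(got).min() >= -1e-10

    def test_window_outside_map_rejected(self, rng):
        fm = random_feature_map(rng)
        with pytest.raises(cc.ValidationError):
            cc.region_covariance(fm, Subwindow(12, 0, 8))

    def test_invariant_to_adding_a_constant_to_a_plane(self, rng):
        fm = random_feature_map(rng, d=4)
        w = Subwindow(2, 3, 8)
        base = cc.region_covariance(fm, w).matrix
        shifted = fm.planes.copy()
        shifted[2] += 5.0
        moved = cc.region_covariance(cc.FeatureMap(shifted, "F1"), w).matrix
        assert np.abs(base - moved).max() <= 1e-10


class TestNormalization:
    def test_perfectly_correlated_features_have_unit_correlation(self):
        t = np.linspace(0, 1, 64).reshape(8, 8)
        fm = cc.FeatureMap(np.stack([t, 3.0 * t]), "F1")
        cd = cc.normalize_covariance(cc.region_covariance(fm, Subwindow(0, 0, 8)))
        assert cd.matrix[0, 1] == pytest.approx(1.0)

    def test_zero_matrix_passes_through(self):
        cd = cc.CovarianceDescriptor(np.zeros((4, 4)), normalized=False)
        np.testing.assert_array_equal(cc.normalize_covariance(cd).matrix, 0.0)

    def test_off_diagonals_bounded_and_diagonal_kept(self, rng):
        for _ in range(100):
            fm = random_feature_map(rng, d=6)
            w = Subwindow(int(rng.integers(0, 8)), int(rng.integers(0, 8)), 8)
            plain = cc.region_covariance(fm, w)
            norm = cc.normalize_covariance(plain)
            off = norm.matrix[~np.eye(6, dtype=bool)]
            assert np.all(off >= -1.0 - 1e-12) and np.all(off <= 1.0 + 1e-12)
            np.testing.assert_allclose(np.diag(norm.matrix), np.diag(plain.matrix))

    def test_off_diagonals_invariant_to_positive_feature_rescaling(self, rng):
        fm = random_feature_map(rng, d=4)
        w = Subwindow(1, 1, 10)
        norm1 = cc.normalize_covariance(cc.region_covariance(fm, w)).matrix
        scaled = fm.planes.copy()
        scaled[1] *= 37.5
        norm2 = cc.normalize_covariance(
            cc.region_covariance(cc.FeatureMap(scaled, "F1"), w)).matrix
        off = ~np.eye(4, dtype=bool)
        assert np.abs(norm1[off] - norm2[off]).max() <= 1e-10

    def test_double_normalisation_rejected(self):
        cd = cc.CovarianceDescriptor(np.eye(3), normalized=True)
        with pytest.raises(cc.ValidationError):
            cc.normalize_covariance(cd)


class TestVectorisation:
    def test_upper_triangle_order_and_length(self):
        cd = cc.CovarianceDescriptor(np.array([[1.0, 2.0], [2.0, 3.0]]), False)
        np.testing.assert_array_equal(cc.vectorize_descriptor(cd).values, [1, 2, 3])
        d15 = cc.CovarianceDescriptor(np.eye(15), False)
        assert len(cc.vectorize_descriptor(d15).values) == 120

    def test_round_trip_is_exact(self, rng):
        A = rng.random((7, 7))
        M = A + A.T
        cd = cc.CovarianceDescriptor(M, False)
        back = cc.matrix_from_vector(cc.vectorize_descriptor(cd).values, 7)
        np.testing.assert_array_equal(back, M)

    def test_asymmetric_matrix_rejected(self):
        M = np.zeros((3, 3))
        M[0, 2] = 1.0
        with pytest.raises(cc.ContractError):
            cc.vectorize_descriptor(cc.CovarianceDescriptor(M, False))

    def test_diagonal_only_vector(self):
        M = np.diag(np.arange(1.0, 16.0))
        cd = cc.CovarianceDescriptor(M, False)
        v = cc.diagonal_only(cd).values
        assert len(v) == 15
        np.testing.assert_array_equal(v, np.arange(1.0, 16.0))
        zero = cc.CovarianceDescriptor(np.zeros((5, 5)), False)
        np.testing.assert_array_equal(cc.diagonal_only(zero).values, 0.0)


class TestFeatureMaps:
    def _stacks(self, rng, shape=(24, 24)):
        avg = cc.AverageImage(rng.random(shape))
        mags = cc.MagnitudeStack(rng.random((6,) + shape))
        stacks = {a: cc.DirectionalScoreStack(rng.random((8,) + shape), a)
                  for a in cc.AGGREGATORS}
        return avg, mags, stacks

    def test_f1_has_fifteen_planes_with_intensity_first(self, rng):
        avg, mags, stacks = self._stacks(rng)
        fm = cc.build_feature_map(avg, mags, scores_median=stacks["median"],
                                  mapping="F1")
        assert fm.d == 15
        np.testing.assert_array_equal(fm.planes[0], avg.pixels)
        np.testing.assert_array_equal(fm.planes[1:7], mags.magnitudes)
        np.testing.assert_array_equal(fm.planes[7:], stacks["median"].scores)

    @pytest.mark.parametrize("mapping,agg", [("F2", "max"), ("F3", "mean")])
    def test_f2_f3_select_their_aggregator(self, rng, mapping, agg):
        avg, mags, stacks = self._stacks(rng)
        kw = {"scores_max": stacks["max"], "scores_mean": stacks["mean"]}
        fm = cc.build_feature_map(avg, mags, **kw, mapping=mapping)
        np.testing.assert_array_equal(fm.planes[7:], stacks[agg].scores)

    def test_f4_derivatives_of_constant_are_zero(self):
        fm = cc.build_feature_map(cc.AverageImage(np.full((16, 16), 0.4)),
                                  mapping="F4")
        assert fm.d == 5
        np.testing.assert_allclose(fm.planes[1:], 0.0, atol=1e-15)

    def test_f4_on_a_column_ramp(self):
        ramp = np.tile(np.arange(20.0), (20, 1))
        fm = cc.build_feature_map(cc.AverageImage(ramp / 20), mapping="F4")
        interior = (slice(2, -2), slice(2, -2))
        np.testing.assert_allclose(fm.planes[1][interior], 1 / 20, atol=1e-12)
        np.testing.assert_allclose(fm.planes[3][interior], 0.0, atol=1e-12)

    def test_size_mismatch_rejected(self, rng):
        avg, mags, stacks = self._stacks(rng)
        small = cc.MagnitudeStack(rng.random((6, 12, 12)))
        with pytest.raises(cc.ValidationError):
            cc.build_feature_map(avg, small, scores_median=stacks["median"],
                                 mapping="F1")
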