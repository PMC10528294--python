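"""Distance-correlation core: exact small cases, oracle agreement and the
invariances the statistic must satisfy."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from dcforest import (
    InvalidInputError,
    dcor,
    dcor_profile,
    distance_matrix,
    distance_stats,
    double_center,
)


def brute_force_dcov2(x, y):
    """Literal nested-loop evaluation of the squared distance covariance:

        S1 = n^-2 sum_jk a_jk b_jk
        S2 = (n^-2 sum a)(n^-2 sum b)
        S3 = n^-3 sum_j sum_k sum_l a_jk b_jl
        dCov2 = S1 + S2 - 2 S3

    Kept deliberately loop-based and separate from the package's
    double-centering implementation.
    """
    n = len(x)
    a = [[abs(x[j] - x[k]) for k in range(n)] for j in range(n)]
    b = [[abs(y[j] - y[k]) for k in range(n)] for j in range(n)]
    s1 = sum(a[j][k] * b[j][k] for j in range(n) for k in range(n)) / n**2
    s2 = (sum(map(sum, a)) / n**2) * (sum(map(sum, b)) / n**2)
    s3 = (
        sum(
            sum(a[j][k] for k in range(n)) * sum(b[j][l] for l in range(n))
            for j in range(n)
        )
        / n**3
    )
    return s1 + s2 - 2 * s3


def brute_force_dcor(x, y):
    vxy = brute_force_dcov2(x, y)
    vxx = brute_force_dcov2(x, x)
    vyy = brute_force_dcov2(y, y)
    if vxx * vyy <= 0:
        return 0.0
    return np.sqrt(max(vxy, 0.0)) / (vxx * vyy) ** 0.25


finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


class TestDistanceMatrix:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([1, 3], [[0, 2], [2, 0]]),
            ([5, 5, 5], np.zeros((3, 3))),
            ([0, 1, 3], [[0, 1, 3], [1, 0, 2], [3, 2, 0]]),
        ],
    )
    def test_exact_small_cases(self, x, expected):
        np.testing.assert_allclose(distance_matrix(x), expected)

    def test_rejects_bad_input(self):
        with pytest.raises(InvalidInputError):
            distance_matrix([1.0, np.nan])
        with pytest.raises(InvalidInputError):
            distance_matrix([1.0])


class TestDoubleCenter:
    def test_zero_matrix_stays_zero(self):
        np.testing.assert_allclose(double_center(np.zeros((3, 3))), 0.0)

    def test_two_point_case(self):
        np.testing.assert_allclose(
            double_center([[0, 2], [2, 0]]), [[-1, 1], [1, -1]]
        )

    def test_row_and_column_sums_vanish(self, rng):
        d = distance_matrix(rng.normal(size=5))
        c = double_center(d)
        np.testing.assert_allclose(c.sum(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(c.sum(axis=1), 0.0, atol=1e-12)

    def test_rejects_non_square(self):
        with pytest.raises(InvalidInputError):
            double_center(np.zeros((2, 3)))


class TestDistanceStats:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=20)
        assert distance_stats(x, x).dcor == pytest.approx(1.0, abs=1e-12)

    def test_constant_sample_gives_zero_by_convention(self):
        s = distance_stats([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert s.dcor == 0.0
        assert s.dvar2_y == 0.0

    def test_matches_brute_force_on_quadratic_example(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 4.0, 9.0, 16.0]
        assert dcor(x, y) == pytest.approx(brute_force_dcor(x, y), abs=1e-12)

    def test_matches_brute_force_on_random_samples(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 31))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            s = distance_stats(x, y)
            assert s.dcov2 == pytest.approx(brute_force_dcov2(x, y), rel=1e-10, abs=1e-12)
            assert s.dcor == pytest.approx(brute_force_dcor(x, y), rel=1e-10, abs=1e-12)

    def test_internal_consistency_of_components(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        s = distance_stats(x, y)
        assert s.dcor**2 * np.sqrt(s.dvar2_x * s.dvar2_y) == pytest.approx(
            s.dcov2, rel=1e-9
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            distance_stats([1, 2, 3], [1, 2])

    @given(
        arrays(float, st.integers(3, 25), elements=finite_floats),
        st.integers(0, 2**31 - 1),
    )
    def test_range_and_symmetry(self, x, seed):
        y = np.random.default_rng(seed).normal(size=x.size)
        r = dcor(x, y)
        assert 0.0 <= r <= 1.0
        assert r == pytest.approx(dcor(y, x), abs=1e-12)

    @given(
        st.integers(0, 2**31 - 1),
        st.floats(-50, 50).filter(lambda a: abs(a) > 1e-3),
        st.floats(-50, 50).filter(lambda c: abs(c) > 1e-3),
        st.floats(-100, 100),
        st.floats(-100, 100),
    )
    def test_affine_invariance(self, seed, a, c, b, d):
        g = np.random.default_rng(seed)
        x = g.normal(size=12)
        y = g.normal(size=12) + x
        assert dcor(a * x + b, c * y + d) == pytest.approx(dcor(x, y), abs=1e-9)


class TestDcorProfile:
    def test_identical_column_scores_one(self, rng):
        y = rng.normal(size=30)
        X = np.column_stack([y, rng.normal(size=30)])
        prof = dcor_profile(X, y)
        assert prof.scores[0] == pytest.approx(1.0, abs=1e-12)
        assert prof.method == "DC"

    def test_constant_column_scores_zero(self, rng):
        y = rng.normal(size=25)
        X = np.column_stack([np.full(25, 3.0), y])
        prof = dcor_profile(X, y)
        assert prof.scores[0] == 0.0

    def test_independent_noise_scores_shrink_with_n(self, rng):
        # consistency under independence: larger samples push scores to 0
        scores = {}
        for n in (50, 1000):
            X = rng.normal(size=(n, 5))
            y = rng.normal(size=n)
            scores[n] = dcor_profile(X, y).scores.mean()
        assert scores[1000] < scores[50]
        assert scores[1000] < 0.1

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            dcor_profile(rng.normal(size=(10, 2)), rng.normal(size=9))
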