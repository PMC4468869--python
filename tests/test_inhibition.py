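"""Distance/orientation weighting and the two surround-inhibition terms."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import ns_inhibition_oracle, os_inhibition_oracle
from v1contour.gabor import OrientationMap
from v1contour.inhibition import (
    SurroundParams,
    distance_weight,
    ns_inhibition,
    ns_response,
    orientation_weight,
    os_inhibition,
    os_response,
)


def _dog(x, y, sigma, k):
    ks2, s2 = (k * sigma) ** 2, sigma**2
    r2 = x**2 + y**2
    return math.exp(-r2 / (2 * ks2)) / (2 * math.pi * ks2) - math.exp(
        -r2 / (2 * s2)
    ) / (2 * math.pi * s2)


class TestDistanceWeight:
    @pytest.mark.parametrize("sigma", [1.2, 1.6, 2.0, 2.4, 4.0])
    def test_normalised_annulus(self, sigma):
        sp = SurroundParams(sigma=sigma, k=4.0)
        w = distance_weight(sp)
        h = sp.half_width
        assert w[h, h] == 0.0  # DOG is negative at the centre for k > 1
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_pointwise_dog(self):
        sp = SurroundParams(sigma=4.0, k=4.0)
        w = distance_weight(sp)
        h = sp.half_width
        raw = np.array(
            [
                [max(_dog(x, y, sp.sigma, sp.k), 0.0) for x in range(-h, h + 1)]
                for y in range(-h, h + 1)
            ]
        )
        np.testing.assert_allclose(w, raw / raw.sum(), rtol=1e-12)
        # the rectified annulus starts outside the CRF core
        ys, xs = np.nonzero(w)
        r = np.hypot(ys - h, xs - h)
        assert r.min() > sp.sigma

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SurroundParams(sigma=2.0, k=0.5)
        with pytest.raises(ValueError):
            SurroundParams(sigma=2.0, alpha=-1.0)


class TestOrientationWeight:
    def test_equal_angles_give_one(self):
        assert orientation_weight(0.3, 0.3) == pytest.approx(1.0)

    def test_wraparound(self):
        # 10 vs 170 degrees is a 20-degree contrast, not 160
        w_wrap = orientation_weight(math.radians(10), math.radians(170))
        w_direct = orientation_weight(math.radians(10), math.radians(30))
        assert w_wrap == pytest.approx(w_direct)

    def test_orthogonal_value(self):
        w = orientation_weight(0.0, math.pi / 2, sigma_delta=math.pi / 6)
        assert w == pytest.approx(math.exp(-4.5), rel=1e-12)
        assert w == pytest.approx(0.011109, abs=1e-6)

    @given(
        a=st.floats(0, math.pi, exclude_max=True),
        b=st.floats(0, math.pi, exclude_max=True),
    )
    def test_symmetric_and_bounded(self, a, b):
        w_ab = orientation_weight(a, b)
        w_ba = orientation_weight(b, a)
        assert w_ab == pytest.approx(w_ba)
        assert math.exp(-4.5) - 1e-12 <= w_ab <= 1.0


def _random_maps(rng, shape, n_orientations=12):
    e = rng.random(shape)
    idx = rng.integers(0, n_orientations, size=shape)
    values = np.arange(n_orientations) * math.pi / n_orientations
    return e, OrientationMap(index=idx, orientation_values=values)


class TestInhibitionTerms:
    def test_os_matches_triple_loop_oracle(self, rng):
        sp = SurroundParams(sigma=0.5, k=4.0)
        e, theta = _random_maps(rng, (9, 9))
        np.testing.assert_allclose(
            os_inhibition(e, theta, sp),
            os_inhibition_oracle(e, theta.index, theta.orientation_values, sp),
            rtol=1e-10,
        )

    def test_ns_matches_weighted_sum_oracle(self, rng):
        sp = SurroundParams(sigma=0.8, k=4.0)
        e = rng.random((16, 16))
        np.testing.assert_allclose(
            ns_inhibition(e, sp), ns_inhibition_oracle(e, sp), rtol=1e-10
        )

    def test_uniform_orientation_reduces_to_ns(self, rng):
        # constant theta~: W_dtheta = 1 everywhere, so OS == NS
        sp = SurroundParams(sigma=0.6, k=4.0)
        e = rng.random((12, 12))
        values = np.arange(12) * math.pi / 12
        theta = OrientationMap(
            index=np.full((12, 12), 3), orientation_values=values
        )
        np.testing.assert_allclose(
            os_inhibition(e, theta, sp), ns_inhibition(e, sp), rtol=1e-10
        )

    def test_orthogonal_surround_scales_by_exp(self, rng):
        # centre pixel at 0 degrees, everything else at 90 degrees:
        # at the centre, I_os = exp(-4.5) * I_ns
        sp = SurroundParams(sigma=0.5, k=4.0)
        e = rng.random((11, 11))
        values = np.arange(12) * math.pi / 12
        idx = np.full((11, 11), 6)  # 90 degrees
        idx[5, 5] = 0
        theta = OrientationMap(index=idx, orientation_values=values)
        i_os = os_inhibition(e, theta, sp)
        i_ns = ns_inhibition(e, sp)
        # the centre pixel's own energy does not enter (W_d centre is 0,
        # and no other surround pixel shares its orientation)
        assert i_os[5, 5] == pytest.approx(math.exp(-4.5) * i_ns[5, 5], rel=1e-9)

    def test_ns_zero_and_constant(self):
        sp = SurroundParams(sigma=0.5, k=4.0)
        assert (ns_inhibition(np.zeros((15, 15)), sp) == 0).all()
        np.testing.assert_allclose(
            ns_inhibition(np.full((15, 15), 3.7), sp), 3.7, rtol=1e-12
        )

    def test_dimension_mismatch(self, rng):
        sp = SurroundParams(sigma=0.5)
        e, theta = _random_maps(rng, (9, 9))
        with pytest.raises(ValueError):
            os_inhibition(e[:5], theta, sp)


class TestResponses:
    def test_direct_substitution(self):
        assert os_response(np.array([[1.0]]), np.array([[0.4]]), 1.8)[0, 0] == pytest.approx(0.28)
        assert ns_response(np.array([[0.5]]), np.array([[0.6]]), 1.2)[0, 0] == 0.0
        e = np.array([[0.3, 0.9]])
        np.testing.assert_array_equal(os_response(e, np.ones_like(e), 0.0), e)

    def test_bounded_by_energy(self, rng):
        e = rng.random((8, 8))
        i = rng.random((8, 8))
        r = os_response(e, i, 1.3)
        assert (r >= 0).all()
        assert (r <= e).all()

    @given(alphas=st.tuples(st.floats(0, 5), st.floats(0, 5)))
    def test_monotone_in_alpha(self, alphas):
        rng = np.random.default_rng(7)
        e = rng.random((6, 6))
        i = rng.random((6, 6))
        lo, hi = sorted(alphas)
        assert (os_response(e, i, hi) <= os_response(e, i, lo) + 1e-12).all()
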