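"""Orientation-saliency maps and the two integrated models."""

import math

import numpy as np
import pytest

from v1contour._conv import convolve2d_reflect
from v1contour.gabor import (
    EnergyStack,
    GaborParams,
    OrientationMap,
    gabor_energy,
    max_energy_and_orientation,
)
from v1contour.inhibition import (
    SurroundParams,
    distance_weight,
    ns_inhibition,
    ns_response,
    os_inhibition,
    os_response,
)
from v1contour.saliency import (
    SaliencySpec,
    bos_map,
    model1_response,
    model2_response,
    orientation_saliency_ratio,
    ros_map,
)

PARAMS = GaborParams(sigma=1.0, n_orientations=12)


def _stack(arr):
    return EnergyStack(np.asarray(arr, dtype=float), PARAMS)


class TestRosRatio:
    def test_equal_energies(self):
        raw = orientation_saliency_ratio(_stack(np.full((4, 4, 12), 0.3)))
        np.testing.assert_allclose(raw, 1 / 12)

    def test_single_orientation(self):
        e = np.zeros((3, 3, 12))
        e[..., 5] = 2.0
        np.testing.assert_allclose(orientation_saliency_ratio(_stack(e)), 1.0)

    def test_zero_energy_pixel(self):
        e = np.zeros((2, 2, 12))
        e[0, 0, 0] = 1.0
        raw = orientation_saliency_ratio(_stack(e))
        assert raw[0, 0] == 1.0
        assert raw[1, 1] == 0.0

    def test_matches_brute_force(self, rng):
        e = rng.random((8, 8, 12))
        raw = orientation_saliency_ratio(_stack(e))
        for i in range(8):
            for j in range(8):
                assert raw[i, j] == pytest.approx(e[i, j].max() / e[i, j].sum())

    def test_range(self, rng):
        raw = orientation_saliency_ratio(_stack(rng.random((8, 8, 12)) + 0.01))
        assert (raw >= 1 / 12 - 1e-12).all()
        assert (raw <= 1.0).all()


class TestRosMap:
    def test_normalised_to_unit_interval(self, rng):
        mu = ros_map(_stack(rng.random((16, 16, 12))), SaliencySpec(smoothing_sigma=1.0))
        assert mu.min() == 0.0
        assert mu.max() == 1.0

    def test_constant_map_degenerates_to_zero(self):
        mu = ros_map(_stack(np.full((8, 8, 12), 0.5)), SaliencySpec(smoothing_sigma=1.0))
        assert (mu == 0).all()


class TestBosMap:
    def test_threshold_semantics(self):
        mu = np.array([[0.5, 0.39, 0.4]])
        np.testing.assert_array_equal(bos_map(mu, 0.4), [[1.0, 0.0, 1.0]])

    def test_tiny_threshold_keeps_all_positive(self, rng):
        mu = rng.random((5, 5))
        assert (bos_map(mu, 1e-12) == 1).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bos_map(np.array([[1.5]]), 0.4)
        with pytest.raises(ValueError):
            SaliencySpec(th=0.0)


def _pipeline_maps(rng, shape=(24, 24), sigma=1.0):
    img = rng.random(shape)
    gp = GaborParams(sigma=sigma, n_orientations=8)
    sp = SurroundParams(sigma=sigma)
    stack = gabor_energy(img, gp)
    e, theta = max_energy_and_orientation(stack)
    return img, stack, e, theta, sp


class TestModel1:
    def test_reduces_to_os_when_all_salient(self, rng):
        _, _, e, theta, sp = _pipeline_maps(rng)
        i_os = os_inhibition(e, theta, sp)
        i_ns = ns_inhibition(e, sp)
        r = model1_response(e, i_os, i_ns, np.ones_like(e), 1.7, 1.1)
        np.testing.assert_array_equal(r, os_response(e, i_os, 1.7))

    def test_reduces_to_ns_when_none_salient(self, rng):
        _, _, e, theta, sp = _pipeline_maps(rng)
        i_os = os_inhibition(e, theta, sp)
        i_ns = ns_inhibition(e, sp)
        r = model1_response(e, i_os, i_ns, np.zeros_like(e), 1.7, 1.1)
        np.testing.assert_array_equal(r, ns_response(e, i_ns, 1.1))

    def test_dimension_mismatch(self, rng):
        e = rng.random((6, 6))
        with pytest.raises(ValueError):
            model1_response(e, e, e, np.ones((5, 5)), 1.0, 1.0)


class TestModel2:
    def test_reduces_to_os_stage_when_ros_one(self, rng):
        _, _, e, theta, sp = _pipeline_maps(rng)
        i_os = os_inhibition(e, theta, sp)
        r = model2_response(e, theta, np.ones_like(e), sp, 1.6, 2.56)
        np.testing.assert_allclose(r, np.maximum(e - 1.6 * i_os, 0.0), rtol=1e-12)

    def test_reduces_to_ns_model_when_ros_zero(self, rng):
        _, _, e, theta, sp = _pipeline_maps(rng)
        w_d = distance_weight(sp)
        r = model2_response(e, theta, np.zeros_like(e), sp, 1.6, 2.56)
        expected = np.maximum(e - 2.56 * convolve2d_reflect(e, w_d), 0.0)
        np.testing.assert_allclose(r, expected, rtol=1e-12)

    def test_cascade_is_contractive(self, rng):
        _, _, e, theta, sp = _pipeline_maps(rng)
        mu = rng.random(e.shape)
        i_os = os_inhibition(e, theta, sp)
        r_os = np.maximum(e - 1.6 * mu * i_os, 0.0)
        r2 = model2_response(e, theta, mu, sp, 1.6, 2.56, i_os=i_os)
        assert (r2 <= r_os + 1e-15).all()
        assert (r_os <= e + 1e-15).all()
        assert (r2 >= 0).all()


class TestHomogeneity:
    @pytest.mark.parametrize("detector", ["model1", "model2"])
    def test_intensity_scaling_scales_output(self, rng, detector):
        # every stage is 1-homogeneous and the saliency maps are
        # scale-invariant, so scaling the image scales the response.
        # A power-of-two factor keeps the float scaling exact, so the
        # winner-take-all tie-breaks are not perturbed.
        img = rng.random((32, 32))
        c = 2.0
        outs = []
        for im in (img, c * img):
            gp = GaborParams(sigma=1.2, n_orientations=8)
            sp = SurroundParams(sigma=1.2)
            stack = gabor_energy(im, gp)
            e, theta = max_energy_and_orientation(stack)
            spec = SaliencySpec(smoothing_sigma=2.4)
            mu = ros_map(stack, spec)
            if detector == "model1":
                r = model1_response(
                    e,
                    os_inhibition(e, theta, sp),
                    ns_inhibition(e, sp),
                    bos_map(mu, 0.4),
                    1.8,
                    2.16,
                )
            else:
                r = model2_response(e, theta, mu, sp, 1.8, 2.16)
            outs.append(r)
        np.testing.assert_allclose(outs[1], c * outs[0], rtol=1e-9, atol=1e-12)


class TestStimulusLevelBehaviour:
    def test_ros_classifies_texture_types(self, stimulus, v1_maps):
        """ROS is high on the grating and on isolated lines, low on the
        random-bar texture."""
        mu = v1_maps["mu_ros"]
        th = 0.4
        assert mu[stimulus.region_masks["grating"]].mean() > th
        assert mu[stimulus.line_masks["isolated_lines"]].mean() > th
        assert mu[stimulus.region_masks["random_bars"]].mean() < th

    def test_stage_order_matters(self, stimulus, v1_maps):
        """Applying non-selective inhibition before the orientation-
        selective stage destroys the pop-out of the line embedded in the
        uniformly oriented grating."""
        e, theta = v1_maps["e_tilde"], v1_maps["theta_tilde"]
        sp, w_d = v1_maps["sp"], v1_maps["w_d"]
        mu = v1_maps["mu_ros"]
        a1, a2 = 1.6, 2.56
        line = stimulus.line_mask("grating")
        bg = stimulus.background_mask("grating")
        proper = model2_response(
            e, theta, mu, sp, a1, a2, i_os=v1_maps["i_os"], w_d=w_d
        )
        assert proper[line].mean() > np.percentile(proper[bg], 95)
        # swapped cascade: NS stage (weighted by 1 - mu) first, then the
        # OS stage (weighted by mu) on its output
        r_ns = np.maximum(e - a2 * (1 - mu) * convolve2d_reflect(e, w_d), 0.0)
        i_os_sw = os_inhibition(r_ns, theta, sp, w_d=w_d)
        swapped = np.maximum(r_ns - a1 * mu * i_os_sw, 0.0)
        assert swapped[line].mean() < np.percentile(swapped[bg], 95)
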