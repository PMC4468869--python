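"""Shared fixtures and independent brute-force oracles.

The oracles implement the defining sums/set algebra directly (Python
loops, explicit set comparisons) and are deliberately independent of the
vectorised production code paths they are used to check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from v1contour.gabor import GaborParams, gabor_energy, max_energy_and_orientation
from v1contour.inhibition import (
    SurroundParams,
    distance_weight,
    ns_inhibition,
    orientation_weight,
    os_inhibition,
)
from v1contour.saliency import SaliencySpec, bos_map, ros_map
from v1contour.stimuli import StimulusSpec, generate_four_region_image

settings.register_profile("deterministic", derandomize=True, max_examples=25)
settings.load_profile("deterministic")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# brute-force oracles


def conv2d_reflect_oracle(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct double-loop convolution sum with mirror padding."""
    h, w = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(image, ((h, h), (w, w)), mode="reflect")
    out = np.zeros_like(image, dtype=float)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            acc = 0.0
            for u in range(-h, h + 1):
                for v in range(-w, w + 1):
                    acc += kernel[u + h, v + w] * padded[i + h - u, j + w - v]
            out[i, j] = acc
    return out


def os_inhibition_oracle(
    e_tilde: np.ndarray,
    idx: np.ndarray,
    orientation_values: np.ndarray,
    sp: SurroundParams,
) -> np.ndarray:
    """Literal weighted-sum definition of the OS inhibition term."""
    w_d = distance_weight(sp)
    h = sp.half_width
    ep = np.pad(e_tilde, h, mode="reflect")
    ip = np.pad(idx, h, mode="reflect")
    out = np.zeros_like(e_tilde, dtype=float)
    for i in range(e_tilde.shape[0]):
        for j in range(e_tilde.shape[1]):
            theta_c = orientation_values[idx[i, j]]
            acc = 0.0
            for m in range(-h, h + 1):
                for n in range(-h, h + 1):
                    theta_s = orientation_values[ip[i + h + m, j + h + n]]
                    acc += (
                        orientation_weight(theta_c, theta_s, sp.sigma_delta)
                        * w_d[m + h, n + h]
                        * ep[i + h + m, j + h + n]
                    )
            out[i, j] = acc
    return out


def ns_inhibition_oracle(e_tilde: np.ndarray, sp: SurroundParams) -> np.ndarray:
    """Literal weighted-sum definition of the NS inhibition term."""
    w_d = distance_weight(sp)
    h = sp.half_width
    ep = np.pad(e_tilde, h, mode="reflect")
    out = np.zeros_like(e_tilde, dtype=float)
    for i in range(e_tilde.shape[0]):
        for j in range(e_tilde.shape[1]):
            out[i, j] = float(
                (w_d * ep[i : i + 2 * h + 1, j : j + 2 * h + 1]).sum()
            )
    return out


def chebyshev_eval_oracle(
    detected: np.ndarray, ground_truth: np.ndarray, radius: int = 2
) -> tuple[int, int, int]:
    """Match detected/ground-truth pixel sets by Chebyshev distance <= radius.

    Returns (|E|, |E_FP|, |E_FN|) via explicit O(|D| * |GT|) set scans.
    """
    d_pix = [tuple(p) for p in np.argwhere(detected)]
    g_pix = [tuple(p) for p in np.argwhere(ground_truth)]

    def near(p, qs):
        return any(
            max(abs(p[0] - q[0]), abs(p[1] - q[1])) <= radius for q in qs
        )

    e = sum(near(p, g_pix) for p in d_pix)
    e_fp = len(d_pix) - e
    e_fn = sum(not near(g, d_pix) for g in g_pix)
    return e, e_fp, e_fn


# ---------------------------------------------------------------------------
# shared heavy fixture: the canonical stimulus at sigma = 4


@pytest.fixture(scope="session")
def stimulus():
    return generate_four_region_image(StimulusSpec())


@pytest.fixture(scope="session")
def v1_maps(stimulus):
    """Front-end, inhibition and saliency maps of the canonical stimulus.

    Computed once per session at sigma = 4, N_theta = 12 and shared by
    the qualitative-reproduction tests.
    """
    gp = GaborParams(sigma=4.0, n_orientations=12)
    sp = SurroundParams(sigma=4.0)
    stack = gabor_energy(stimulus.image, gp)
    e_tilde, theta_tilde = max_energy_and_orientation(stack)
    w_d = distance_weight(sp)
    i_os = os_inhibition(e_tilde, theta_tilde, sp, w_d=w_d)
    i_ns = ns_inhibition(e_tilde, sp, w_d=w_d)
    spec = SaliencySpec(smoothing_sigma=2 * 4.0, th=0.4)
    mu_ros = ros_map(stack, spec)
    mu_bos = bos_map(mu_ros, spec.th)
    return {
        "stack": stack,
        "e_tilde": e_tilde,
        "theta_tilde": theta_tilde,
        "sp": sp,
        "w_d": w_d,
        "i_os": i_os,
        "i_ns": i_ns,
        "mu_ros": mu_ros,
        "mu_bos": mu_bos,
    }
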