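"""Surround (non-classical receptive field) inhibition operators.

Two types of surround inhibition observed in V1 are modelled:

* **Non-selective (NS, isotropic)**: the suppression a neuron receives
  from its surround depends only on the distance of the surround
  stimulus, through the rectified difference-of-Gaussians weight W_d.
* **Orientation-selective (OS, anisotropic)**: the suppression
  additionally decays with the orientation contrast between the centre
  and surround stimuli, through a Gaussian weight W_dtheta of the
  (pi-wrapped) orientation difference.

The post-inhibition response of either neuron type is the halfwave
rectified difference H(E~ - alpha * I), where E~ is the maximum Gabor
energy and alpha scales the inhibition strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._conv import convolve2d_reflect
from .gabor import OrientationMap

__all__ = [
    "SurroundParams",
    "distance_weight",
    "orientation_weight",
    "orientation_weight_table",
    "os_inhibition",
    "ns_inhibition",
    "os_response",
    "ns_response",
]


@dataclass(frozen=True)
class SurroundParams:
    """Geometry and strength of the surround-inhibition operators.

    ``sigma`` is the CRF scale (shared with the Gabor bank); ``k`` the
    nCRF/CRF size ratio (physiologically 2-5, default 4); ``sigma_delta``
    the width of the orientation-contrast tuning in radians; ``alpha``
    a default inhibition strength.
    """

    sigma: float
    k: float = 4.0
    sigma_delta: float = math.pi / 6
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.k <= 1:
            raise ValueError("k must exceed 1 (nCRF larger than CRF)")
        if self.sigma_delta <= 0:
            raise ValueError("sigma_delta must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")

    @property
    def half_width(self) -> int:
        """Half-width of the W_d support, ceil(3 k sigma)."""
        return math.ceil(3.0 * self.k * self.sigma)


def distance_weight(sp: SurroundParams) -> np.ndarray:
    """Distance weighting W_d: rectified, L1-normalised DOG annulus.

    W_d = H(DOG_{sigma,k}) / ||H(DOG_{sigma,k})||_1 with
    DOG(x, y) = G_{k sigma}(x, y) - G_{sigma}(x, y).  The rectification H
    zeroes the central (CRF) lobe where the DOG is negative, so only the
    annular surround contributes; the L1 normalisation makes the weights
    sum to one.
    """
    h = sp.half_width
    y, x = np.mgrid[-h : h + 1, -h : h + 1].astype(float)
    r2 = x**2 + y**2
    s2, ks2 = sp.sigma**2, (sp.k * sp.sigma) ** 2
    dog = np.exp(-r2 / (2 * ks2)) / (2 * math.pi * ks2) - np.exp(
        -r2 / (2 * s2)
    ) / (2 * math.pi * s2)
    w = np.maximum(dog, 0.0)
    return w / w.sum()


def orientation_weight(
    theta_crf: np.ndarray | float,
    theta_ncrf: np.ndarray | float,
    sigma_delta: float = math.pi / 6,
) -> np.ndarray | float:
    """Orientation-contrast weighting W_dtheta in (0, 1].

    The orientation contrast theta_d is the absolute difference of the
    two orientations wrapped to [0, pi/2] (orientations are axial: 10 and
    170 degrees differ by 20 degrees).  The weight exp(-theta_d^2 /
    (2 sigma_delta^2)) is maximal (1) for iso-oriented centre and
    surround and decays with increasing contrast.
    """
    d = np.abs(np.asarray(theta_crf, dtype=float) - np.asarray(theta_ncrf, dtype=float))
    d = np.where(d >= math.pi / 2, math.pi - d, d)
    w = np.exp(-(d**2) / (2 * sigma_delta**2))
    return float(w) if np.isscalar(theta_crf) and np.isscalar(theta_ncrf) else w


def orientation_weight_table(
    orientation_values: np.ndarray, sigma_delta: float
) -> np.ndarray:
    """W_dtheta evaluated on the discrete N_theta x N_theta orientation grid."""
    t = np.asarray(orientation_values, dtype=float)
    return orientation_weight(t[:, None], t[None, :], sigma_delta)


def os_inhibition(
    e_tilde: np.ndarray,
    theta_tilde: OrientationMap,
    sp: SurroundParams,
    w_d: np.ndarray | None = None,
) -> np.ndarray:
    """Orientation-selective inhibition term I_os.

    I_os(x, y) = sum_{(m,n) in nCRF} W_dtheta(theta~(x, y), theta~(x+m, y+n))
                 * W_d(m, n) * E~(x+m, y+n).

    Because theta~ only takes N_theta discrete values, the sum decomposes
    exactly into N_theta convolutions: the energy map is split into
    per-orientation bins E~ * 1[theta~ = theta_j], each bin is convolved
    with W_d, and the bins are recombined with the table weight
    W_dtheta(theta~(x, y), theta_j).  This is the production path; the
    direct weighted sum serves as a test oracle.
    """
    e_tilde = np.asarray(e_tilde, dtype=float)
    if e_tilde.shape != theta_tilde.index.shape:
        raise ValueError("energy and orientation maps must share dimensions")
    if w_d is None:
        w_d = distance_weight(sp)
    table = orientation_weight_table(theta_tilde.orientation_values, sp.sigma_delta)
    idx = theta_tilde.index
    out = np.zeros_like(e_tilde)
    for j in range(theta_tilde.n_orientations):
        binned = np.where(idx == j, e_tilde, 0.0)
        if not binned.any():
            continue
        out += table[idx, j] * convolve2d_reflect(binned, w_d)
    return out


def ns_inhibition(
    e_tilde: np.ndarray, sp: SurroundParams, w_d: np.ndarray | None = None
) -> np.ndarray:
    """Non-selective inhibition term I_ns = E~ * W_d (convolution)."""
    if w_d is None:
        w_d = distance_weight(sp)
    return convolve2d_reflect(np.asarray(e_tilde, dtype=float), w_d)


def _rectified_response(e_tilde: np.ndarray, inhibition: np.ndarray, alpha: float) -> np.ndarray:
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    return np.maximum(np.asarray(e_tilde, dtype=float) - alpha * inhibition, 0.0)


def os_response(e_tilde: np.ndarray, i_os: np.ndarray, alpha: float) -> np.ndarray:
    """Response of the orientation-selective neuron, H(E~ - alpha I_os)."""
    return _rectified_response(e_tilde, i_os, alpha)


def ns_response(e_tilde: np.ndarray, i_ns: np.ndarray, alpha: float) -> np.ndarray:
    """Response of the non-selective neuron, H(E~ - alpha I_ns)."""
    return _rectified_response(e_tilde, i_ns, alpha)
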