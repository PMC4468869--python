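"""Orientation-saliency maps and the two integrated inhibition models.

A location dominated by a single orientation (a line, an edge, a
uniformly oriented grating) is *orientation salient*; a location covered
by randomly oriented clutter is not.  The real-valued orientation
saliency (ROS) quantifies this as the ratio of the maximum hypercolumn
response to the sum of responses across all N_theta orientations — a
winner-take-all numerator over a divisive-normalisation denominator.
The binary orientation saliency (BOS) thresholds the ROS map.

The two integrated models route each location through the two surround
inhibition types according to its orientation saliency:

* **Model 1** (hard selection): orientation-salient locations
  (BOS = 1) are processed by neurons with orientation-selective
  inhibition, the rest by neurons with non-selective inhibition.
* **Model 2** (soft cascade): every location is processed first by
  orientation-selective inhibition scaled by ROS, then by non-selective
  inhibition scaled by (1 - ROS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ._conv import convolve2d_reflect
from .gabor import EnergyStack, OrientationMap
from .inhibition import SurroundParams, distance_weight, os_inhibition

__all__ = [
    "SaliencySpec",
    "orientation_saliency_ratio",
    "ros_map",
    "bos_map",
    "model1_response",
    "model2_response",
]


@dataclass(frozen=True)
class SaliencySpec:
    """Smoothing scale and BOS threshold for the saliency maps.

    ``smoothing_sigma`` is the scale (pixels) of the Gaussian that
    smooths the raw ROS ratio; the saliency field should vary at nCRF
    rather than pixel scale, so twice the CRF sigma is a sensible value.
    ``th`` is the BOS threshold in (0, 1).
    """

    smoothing_sigma: float = 4.0
    th: float = 0.4

    def __post_init__(self) -> None:
        if not (0 < self.th < 1):
            raise ValueError("th must lie in (0, 1)")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be nonnegative")


def orientation_saliency_ratio(stack: EnergyStack) -> np.ndarray:
    """Raw ROS ratio max_i E(x, y; theta_i) / sum_i E(x, y; theta_i).

    Lies in [1/N_theta, 1] wherever the total energy is positive: 1 when
    a single orientation carries all the energy, 1/N_theta when all
    orientations respond equally.  Pixels with zero total energy (blank
    ground) are assigned 0 — no stimulus, no orientation salience.
    """
    e = stack.energies
    total = e.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = e.max(axis=2) / total
    ratio[total == 0] = 0.0
    return ratio


def ros_map(stack: EnergyStack, spec: SaliencySpec) -> np.ndarray:
    """Real-valued orientation-saliency map, smoothed and normalised.

    The raw max/sum ratio is smoothed with a Gaussian of scale
    ``spec.smoothing_sigma`` (reflect boundary) and the whole map is
    min-max normalised to [0, 1].  A degenerate constant map (no
    orientation-salient structure at all) normalises to all zeros.
    """
    raw = orientation_saliency_ratio(stack)
    if spec.smoothing_sigma > 0:
        smooth = gaussian_filter(raw, spec.smoothing_sigma, mode="reflect")
    else:
        smooth = raw
    lo, hi = smooth.min(), smooth.max()
    if hi - lo == 0:
        return np.zeros_like(smooth)
    return (smooth - lo) / (hi - lo)


def bos_map(mu_ros: np.ndarray, th: float = 0.4) -> np.ndarray:
    """Binary orientation-saliency map: 1 where mu_ros >= th, else 0."""
    mu_ros = np.asarray(mu_ros, dtype=float)
    if mu_ros.min() < 0 or mu_ros.max() > 1:
        raise ValueError("mu_ros must lie in [0, 1]")
    return (mu_ros >= th).astype(float)


def model1_response(
    e_tilde: np.ndarray,
    i_os: np.ndarray,
    i_ns: np.ndarray,
    mu_bos: np.ndarray,
    alpha1: float,
    alpha2: float,
) -> np.ndarray:
    """Model 1: hard selection of the inhibition type by the BOS map.

    r_1 = H(E~ - alpha1 I_os) where mu_bos = 1,
          H(E~ - alpha2 I_ns) where mu_bos = 0.
    """
    e_tilde = np.asarray(e_tilde, dtype=float)
    for m in (i_os, i_ns, mu_bos):
        if np.shape(m) != e_tilde.shape:
            raise ValueError("all maps must share dimensions")
    if alpha1 < 0 or alpha2 < 0:
        raise ValueError("alpha1 and alpha2 must be nonnegative")
    r_os = np.maximum(e_tilde - alpha1 * i_os, 0.0)
    r_ns = np.maximum(e_tilde - alpha2 * i_ns, 0.0)
    return np.where(np.asarray(mu_bos) >= 0.5, r_os, r_ns)


def model2_response(
    e_tilde: np.ndarray,
    theta_tilde: OrientationMap,
    mu_ros: np.ndarray,
    sp: SurroundParams,
    alpha1: float,
    alpha2: float,
    i_os: np.ndarray | None = None,
    w_d: np.ndarray | None = None,
) -> np.ndarray:
    """Model 2: ROS-weighted cascade of the two inhibition types.

    Stage 1 (orientation-selective, scaled by the orientation saliency):
        R_os = H(E~ - alpha1 * mu_ros * I_os)
    Stage 2 (non-selective, scaled by the orientation *non*-saliency,
    applied to the stage-1 output):
        R_ns = R_os * W_d   (convolution)
        r_2  = H(R_os - alpha2 * (1 - mu_ros) * R_ns)

    The OS stage must come first: non-selective inhibition applied to the
    raw energy would extinguish contours embedded in uniformly oriented
    backgrounds before the orientation contrast could save them.

    ``i_os`` and ``w_d`` may be passed in to reuse precomputed maps.
    """
    e_tilde = np.asarray(e_tilde, dtype=float)
    mu_ros = np.asarray(mu_ros, dtype=float)
    if mu_ros.shape != e_tilde.shape:
        raise ValueError("all maps must share dimensions")
    if alpha1 < 0 or alpha2 < 0:
        raise ValueError("alpha1 and alpha2 must be nonnegative")
    if w_d is None:
        w_d = distance_weight(sp)
    if i_os is None:
        i_os = os_inhibition(e_tilde, theta_tilde, sp, w_d=w_d)
    r_os = np.maximum(e_tilde - alpha1 * mu_ros * i_os, 0.0)
    r_ns = convolve2d_reflect(r_os, w_d)
    return np.maximum(r_os - alpha2 * (1.0 - mu_ros) * r_ns, 0.0)
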