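"""Binarization of response maps into one-pixel-wide contour maps.

The standard thinning/binarization pair of edge detection: non-maxima
suppression across the contour normal guided by the optimal-orientation
map, followed by hysteresis thresholding.  The high threshold t_Bh is
set from the distribution of candidate (positive, post-suppression)
pixels so that a fraction p of them survives it; the low threshold is
fixed at t_Bl = 0.5 t_Bh.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .gabor import OrientationMap

__all__ = [
    "BinarizationParams",
    "non_maxima_suppression",
    "hysteresis_threshold",
    "binarize",
]


@dataclass(frozen=True)
class BinarizationParams:
    """``p``: target fraction of candidate edge pixels above the high
    hysteresis threshold.  ``low_high_ratio``: t_Bl / t_Bh, fixed at 0.5."""

    p: float = 0.5
    low_high_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.p < 1):
            raise ValueError("p must lie in (0, 1)")
        if not (0 < self.low_high_ratio <= 1):
            raise ValueError("low_high_ratio must lie in (0, 1]")


def non_maxima_suppression(
    response: np.ndarray, theta_tilde: OrientationMap
) -> np.ndarray:
    """Zero every pixel that is not a local maximum across its contour.

    The comparison direction is the contour *normal*: with theta the
    preferred contour orientation measured from vertical, the normal is
    the direction at angle theta from the x-axis, quantized to the
    nearest of the 4 axial/diagonal neighbor pairs.  A pixel survives if
    its response strictly exceeds one neighbor and is at least equal to
    the other; the asymmetric rule breaks constant plateaus
    deterministically so surviving ridges are at most one pixel wide
    transversally.  Pixels outside the image count as zero.
    """
    r = np.asarray(response, dtype=float)
    if r.shape != theta_tilde.index.shape:
        raise ValueError("response and orientation maps must share dimensions")
    angles = np.mod(theta_tilde.angles, math.pi)
    # sector s covers normals near s*45deg; neighbor offsets (drow, dcol)
    sector = np.rint(angles / (math.pi / 4)).astype(int) % 4
    offsets = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}
    padded = np.pad(r, 1, mode="constant")
    out = np.zeros_like(r)
    for s, (dr, dc) in offsets.items():
        n_plus = padded[1 + dr : 1 + dr + r.shape[0], 1 + dc : 1 + dc + r.shape[1]]
        n_minus = padded[1 - dr : 1 - dr + r.shape[0], 1 - dc : 1 - dc + r.shape[1]]
        keep = (sector == s) & (r > n_plus) & (r >= n_minus)
        out[keep] = r[keep]
    out[r <= 0] = 0.0
    return out


def hysteresis_threshold(nms: np.ndarray, params: BinarizationParams) -> np.ndarray:
    """Two-threshold binarization of a thinned response map.

    t_Bh is the (1 - p)-quantile (linear interpolation) of the strictly
    positive suppressed responses, so about a fraction p of the
    candidates exceeds it; t_Bl = low_high_ratio * t_Bh.  A pixel is kept
    if it is connected (8-connectivity) through pixels >= t_Bl to at
    least one pixel >= t_Bh.  An all-zero input yields an empty map.
    """
    nms = np.asarray(nms, dtype=float)
    candidates = nms[nms > 0]
    out = np.zeros(nms.shape, dtype=bool)
    if candidates.size == 0:
        return out
    t_bh = float(np.quantile(candidates, 1.0 - params.p))
    t_bl = params.low_high_ratio * t_bh
    weak = (nms >= t_bl) & (nms > 0)
    strong = nms >= t_bh
    labels, n = ndimage.label(weak, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return out
    keep = np.zeros(n + 1, dtype=bool)
    keep[np.unique(labels[strong])] = True
    keep[0] = False
    return keep[labels]


def binarize(
    response: np.ndarray, theta_tilde: OrientationMap, params: BinarizationParams
) -> np.ndarray:
    """Non-maxima suppression followed by hysteresis thresholding."""
    return hysteresis_threshold(non_maxima_suppression(response, theta_tilde), params)
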