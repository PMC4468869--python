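"""Classical-receptive-field front end: Gabor filter bank and Gabor energy.

The classical receptive field (CRF) of a V1 simple cell is modelled by a
2-D Gabor filter

    g(x, y; theta, phi) = 1/(2 pi sigma^2)
                          * exp(-(xt^2 + gamma^2 yt^2) / (2 sigma^2))
                          * cos(2 pi xt / lambda + phi)

with xt = x cos(theta) + y sin(theta), yt = -x sin(theta) + y cos(theta).
``theta`` is the direction of the carrier modulation measured from the
image x-axis; equivalently it is the preferred *contour* orientation
measured from the vertical (a filter with theta = 0 responds maximally to
a vertical line).  A complex cell is simulated by the Gabor energy model:
the quadrature pair (phi = 0, phi = pi/2) is applied at every orientation
of a hypercolumn and the two responses are combined as a Euclidean
magnitude, giving a phase-invariant, nonnegative response.

Coordinate convention used throughout the package: arrays are indexed
(row, column) = (y, x), x grows to the right, y grows downwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._conv import convolve2d_reflect

__all__ = [
    "GaborParams",
    "EnergyStack",
    "OrientationMap",
    "gabor_kernel",
    "gabor_energy",
    "max_energy_and_orientation",
]


@dataclass(frozen=True)
class GaborParams:
    """Parameters of the oriented Gabor filter bank.

    Parameters
    ----------
    sigma : float
        Spatial scale of the CRF Gaussian envelope, in pixels.
    sigma_over_lambda : float
        Ratio sigma/lambda fixing the spatial-frequency bandwidth;
        0.56 corresponds to a bandwidth of about one octave.
    gamma : float
        Spatial aspect ratio of the Gaussian envelope (elongation of the
        receptive field along the preferred contour).
    n_orientations : int
        Number of preferred orientations N_theta of a hypercolumn; the
        orientations theta_i = (i-1) * pi / N_theta span 180 degrees.
    phases : tuple of float
        Phase offsets of the quadrature pair.
    """

    sigma: float = 2.0
    sigma_over_lambda: float = 0.56
    gamma: float = 0.5
    n_orientations: int = 12
    phases: tuple[float, ...] = (0.0, math.pi / 2)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must lie in (0, 1]")
        if self.n_orientations < 2:
            raise ValueError("need at least 2 orientations")
        if self.sigma_over_lambda <= 0:
            raise ValueError("sigma_over_lambda must be positive")

    @property
    def wavelength(self) -> float:
        """Carrier wavelength lambda = sigma / (sigma/lambda)."""
        return self.sigma / self.sigma_over_lambda

    @property
    def half_width(self) -> int:
        """Half-width of the square kernel support, ceil(3 sigma / gamma).

        The envelope decays below exp(-4.5) at the support border even
        along its most elongated axis.
        """
        return math.ceil(3.0 * self.sigma / self.gamma)

    def orientations(self) -> np.ndarray:
        """The N_theta preferred orientations theta_i in [0, pi)."""
        n = self.n_orientations
        return np.arange(n) * math.pi / n


def gabor_kernel(params: GaborParams, theta: float, phi: float) -> np.ndarray:
    """Sample a 2-D Gabor filter on its square support.

    Returns an array of shape (2h+1, 2h+1) with h = ``params.half_width``,
    centred at the origin.
    """
    if not (0 <= theta < math.pi):
        raise ValueError("theta must lie in [0, pi)")
    h = params.half_width
    y, x = np.mgrid[-h : h + 1, -h : h + 1].astype(float)
    ct, st = math.cos(theta), math.sin(theta)
    xt = x * ct + y * st
    yt = -x * st + y * ct
    sigma2 = params.sigma**2
    envelope = np.exp(-(xt**2 + params.gamma**2 * yt**2) / (2 * sigma2))
    carrier = np.cos(2 * math.pi * xt / params.wavelength + phi)
    return envelope * carrier / (2 * math.pi * sigma2)


@dataclass
class EnergyStack:
    """Per-pixel, per-orientation complex-cell (Gabor energy) responses.

    ``energies`` has shape (H, W, N_theta) and is nonnegative.
    """

    energies: np.ndarray
    params: GaborParams

    @property
    def shape(self) -> tuple[int, int]:
        return self.energies.shape[:2]

    def orientations(self) -> np.ndarray:
        return self.params.orientations()


@dataclass
class OrientationMap:
    """Winner-take-all optimal orientation per pixel.

    ``index`` holds the arg-max orientation index i in [0, N_theta);
    ``orientation_values`` the N_theta discrete orientations.
    """

    index: np.ndarray
    orientation_values: np.ndarray

    @property
    def angles(self) -> np.ndarray:
        """Optimal orientation theta~(x, y) in radians."""
        return self.orientation_values[self.index]

    @property
    def n_orientations(self) -> int:
        return len(self.orientation_values)


def gabor_energy(image: np.ndarray, params: GaborParams) -> EnergyStack:
    """Compute the Gabor energy E(x, y; theta_i) at every orientation.

    For each orientation the image is convolved (reflect boundary) with the
    even and odd members of the quadrature pair and the responses are
    combined as sqrt(e_0^2 + e_{pi/2}^2).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    support = 2 * params.half_width + 1
    if min(image.shape) < support:
        raise ValueError(
            f"image of shape {image.shape} is smaller than the "
            f"{support}x{support} kernel support at sigma={params.sigma}"
        )
    thetas = params.orientations()
    out = np.empty(image.shape + (params.n_orientations,), dtype=float)
    for i, theta in enumerate(thetas):
        sq = np.zeros_like(image)
        for phi in params.phases:
            resp = convolve2d_reflect(image, gabor_kernel(params, theta, phi))
            sq += resp**2
        out[..., i] = np.sqrt(sq)
    return EnergyStack(energies=out, params=params)


def max_energy_and_orientation(
    stack: EnergyStack,
) -> tuple[np.ndarray, OrientationMap]:
    """Winner-take-all across the hypercolumn.

    Returns the maximum Gabor energy map E~(x, y) and the optimal
    orientation map theta~(x, y).  Ties are broken toward the smallest
    orientation index (np.argmax convention), so blank regions where all
    orientations respond equally are assigned theta_1 = 0.
    """
    e = stack.energies
    idx = np.argmax(e, axis=2)
    e_tilde = np.take_along_axis(e, idx[..., None], axis=2)[..., 0]
    return e_tilde, OrientationMap(index=idx, orientation_values=stack.orientations())
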