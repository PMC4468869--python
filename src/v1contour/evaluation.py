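"""Tolerance-based contour evaluation and parameter sweeps.

A detected pixel counts as correct if a ground-truth contour pixel lies
within its 5 x 5 square neighborhood (a +/- 2 pixel tolerance).  With
E_GT the ground-truth set, E_D the detected set, T the square dilation
template:

    E    = E_D  intersect (E_GT dilated by T)      correctly detected
    E_FP = E_D - E                                 false positives
    E_FN = E_GT - (E_GT intersect (E_D dilated by T))  false negatives

    e_FP = |E_FP| / |E|
    e_FN = |E_FN| / |E_GT|
    P    = |E| / (|E| + |E_FP| + |E_FN|)

Lower e_FP means better texture suppression, lower e_FN better contour
integrity, higher P better overall performance.  The module also runs
the standard 80-combination parameter grids per detector and summarises
the resulting P distribution with box-and-whisker statistics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import binary_dilation

from .gabor import GaborParams, gabor_energy, max_energy_and_orientation
from .inhibition import (
    SurroundParams,
    distance_weight,
    ns_inhibition,
    ns_response,
    os_inhibition,
    os_response,
)
from .postprocess import BinarizationParams, binarize
from .saliency import SaliencySpec, bos_map, model1_response, model2_response, ros_map

__all__ = [
    "EvalResult",
    "SweepGrid",
    "SweepSummary",
    "evaluate_contours",
    "run_parameter_sweep",
    "summarize_sweep",
    "DETECTORS",
]

DETECTORS = ("os", "ns", "model1", "model2")


@dataclass(frozen=True)
class EvalResult:
    """Counts and ratios of the tolerance-based contour comparison.

    ``e_fp`` is +inf when no pixel was correctly detected but false
    positives exist; ``e_fn`` is NaN when the ground truth is empty.
    """

    card_e: int
    card_e_fp: int
    card_e_fn: int
    card_gt: int

    @property
    def e_fp(self) -> float:
        if self.card_e == 0:
            return 0.0 if self.card_e_fp == 0 else math.inf
        return self.card_e_fp / self.card_e

    @property
    def e_fn(self) -> float:
        if self.card_gt == 0:
            return math.nan
        return self.card_e_fn / self.card_gt

    @property
    def performance(self) -> float:
        denom = self.card_e + self.card_e_fp + self.card_e_fn
        if denom == 0:
            # both detected and ground-truth maps empty: vacuously perfect
            return 1.0
        return self.card_e / denom

    # short alias matching the field's notation
    @property
    def P(self) -> float:  # noqa: N802
        return self.performance


def _as_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} must be binary, found values {vals[:5]}")
        arr = arr.astype(bool)
    return arr


def evaluate_contours(
    detected: np.ndarray, ground_truth: np.ndarray, tolerance: int = 5
) -> EvalResult:
    """Compare a binary contour map against ground truth.

    ``tolerance`` is the side of the square matching neighborhood
    (default 5, i.e. +/- 2 pixels).  The dilation template is clipped at
    image borders.
    """
    detected = _as_binary(detected, "detected")
    ground_truth = _as_binary(ground_truth, "ground_truth")
    if detected.shape != ground_truth.shape:
        raise ValueError("maps must share dimensions")
    if tolerance < 1 or tolerance % 2 == 0:
        raise ValueError("tolerance must be a positive odd integer")
    template = np.ones((tolerance, tolerance), dtype=bool)
    gt_dilated = binary_dilation(ground_truth, structure=template)
    d_dilated = binary_dilation(detected, structure=template)
    e = detected & gt_dilated
    e_fp = detected & ~gt_dilated
    e_fn = ground_truth & ~d_dilated
    return EvalResult(
        card_e=int(e.sum()),
        card_e_fp=int(e_fp.sum()),
        card_e_fn=int(e_fn.sum()),
        card_gt=int(ground_truth.sum()),
    )


# ---------------------------------------------------------------------------
# parameter sweeps

_OS_NS_SIGMAS = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 2.2, 2.4)
_OS_NS_ALPHAS = (1.0, 1.2)
_OS_NS_PS = (0.1, 0.2, 0.3, 0.4, 0.5)
_MODEL_SIGMAS = (1.2, 1.6, 2.0, 2.4)
_MODEL_ALPHA1S = (1.8, 2.0)
_MODEL_ALPHA2_MULTIPLIERS = (1.2, 1.4)
_MODEL_PS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class SweepGrid:
    """Parameter grid of a sweep.

    For the single-inhibition detectors (``os``, ``ns``) the grid is
    sigmas x alphas x ps; for the integrated models it is sigmas x
    alpha1s x alpha2_multipliers x ps, with alpha2 = multiplier * alpha1.
    The defaults enumerate exactly 80 combinations per detector.
    """

    detector: str
    sigmas: tuple[float, ...]
    alphas: tuple[float, ...] = ()
    alpha1s: tuple[float, ...] = ()
    alpha2_multipliers: tuple[float, ...] = ()
    ps: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.detector not in DETECTORS:
            raise ValueError(f"unknown detector {self.detector!r}")

    @classmethod
    def default(cls, detector: str) -> "SweepGrid":
        if detector in ("os", "ns"):
            return cls(
                detector=detector,
                sigmas=_OS_NS_SIGMAS,
                alphas=_OS_NS_ALPHAS,
                ps=_OS_NS_PS,
            )
        return cls(
            detector=detector,
            sigmas=_MODEL_SIGMAS,
            alpha1s=_MODEL_ALPHA1S,
            alpha2_multipliers=_MODEL_ALPHA2_MULTIPLIERS,
            ps=_MODEL_PS,
        )

    def combinations(self) -> list[dict]:
        """Enumerate parameter combinations as dicts."""
        combos = []
        if self.detector in ("os", "ns"):
            for sigma, alpha, p in itertools.product(self.sigmas, self.alphas, self.ps):
                combos.append({"sigma": sigma, "alpha": alpha, "p": p})
        else:
            for sigma, a1, mult, p in itertools.product(
                self.sigmas, self.alpha1s, self.alpha2_multipliers, self.ps
            ):
                combos.append(
                    {
                        "sigma": sigma,
                        "alpha1": a1,
                        "alpha2": round(mult * a1, 10),
                        "p": p,
                    }
                )
        return combos


def run_parameter_sweep(
    image: np.ndarray,
    ground_truth: np.ndarray,
    grid: SweepGrid,
    n_orientations: int = 12,
    tolerance: int = 5,
) -> list[tuple[dict, EvalResult]]:
    """Run one detector over a parameter grid and evaluate every run.

    The Gabor energy stack, the winner-take-all maps, both inhibition
    terms and the saliency maps depend only on sigma, so they are
    computed once per sigma and reused across the alpha/p combinations.
    """
    combos = grid.combinations()
    if not combos:
        raise ValueError("parameter grid is empty")
    image = np.asarray(image, dtype=float)
    results: list[tuple[dict, EvalResult]] = []
    for sigma in sorted({c["sigma"] for c in combos}):
        gp = GaborParams(sigma=sigma, n_orientations=n_orientations)
        sp = SurroundParams(sigma=sigma)
        stack = gabor_energy(image, gp)
        e_tilde, theta_tilde = max_energy_and_orientation(stack)
        w_d = distance_weight(sp)
        i_os = i_ns = mu_ros = mu_bos = None
        if grid.detector in ("os", "model1", "model2"):
            i_os = os_inhibition(e_tilde, theta_tilde, sp, w_d=w_d)
        if grid.detector in ("ns", "model1"):
            i_ns = ns_inhibition(e_tilde, sp, w_d=w_d)
        if grid.detector in ("model1", "model2"):
            spec = SaliencySpec(smoothing_sigma=2 * sigma)
            mu_ros = ros_map(stack, spec)
            mu_bos = bos_map(mu_ros, spec.th)
        for combo in (c for c in combos if c["sigma"] == sigma):
            if grid.detector == "os":
                response = os_response(e_tilde, i_os, combo["alpha"])
            elif grid.detector == "ns":
                response = ns_response(e_tilde, i_ns, combo["alpha"])
            elif grid.detector == "model1":
                response = model1_response(
                    e_tilde, i_os, i_ns, mu_bos, combo["alpha1"], combo["alpha2"]
                )
            else:
                response = model2_response(
                    e_tilde,
                    theta_tilde,
                    mu_ros,
                    sp,
                    combo["alpha1"],
                    combo["alpha2"],
                    i_os=i_os,
                    w_d=w_d,
                )
            contour = binarize(
                response, theta_tilde, BinarizationParams(p=combo["p"])
            )
            results.append(
                (dict(combo), evaluate_contours(contour, ground_truth, tolerance))
            )
    return results


@dataclass(frozen=True)
class SweepSummary:
    """Box-and-whisker statistics of the P values of a sweep."""

    p_max: float
    p_med: float
    whisker_length: float  # max - min
    box_length: float  # interquartile range


def summarize_sweep(
    results: Iterable[tuple[dict, EvalResult]] | Sequence[float],
) -> SweepSummary:
    """Summarise a sweep's P distribution.

    Accepts either the (params, EvalResult) pairs from
    :func:`run_parameter_sweep` or a bare sequence of P values.
    """
    values = []
    for item in results:
        if isinstance(item, (int, float, np.floating)):
            values.append(float(item))
        else:
            values.append(item[1].performance)
    if not values:
        raise ValueError("need at least one result")
    values = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return SweepSummary(
        p_max=float(values.max()),
        p_med=float(med),
        whisker_length=float(values.max() - values.min()),
        box_length=float(q3 - q1),
    )
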