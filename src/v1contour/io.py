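"""Reading and writing grayscale images and binary contour maps.

Images are 8-bit PNG or PGM on disk and float arrays in [0, 1] in
memory (0 = black ink, 1 = white ground).  Binary maps are stored with
contour = 255 on 0 and thresholded at mid-gray on read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_gray", "write_gray", "read_binary_map", "write_binary_map"]

logger = logging.getLogger(__name__)

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def read_gray(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale image as a float array in [0, 1].

    Color input is converted to luminance with a logged warning.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        logger.warning("%s is not grayscale; converting to luminance", path)
        arr = arr[..., :3] @ _LUMA
    return np.asarray(arr, dtype=float) / 255.0


def write_gray(path: str | Path, image: np.ndarray) -> None:
    """Write a float image in [0, 1] as an 8-bit grayscale PNG/PGM."""
    image = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, np.round(image * 255.0).astype(np.uint8))


def read_binary_map(path: str | Path) -> np.ndarray:
    """Read a binary (contour / ground-truth) map as a boolean array.

    Values other than {0, 255} are thresholded at mid-gray with a
    warning.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        logger.warning("%s is not grayscale; converting to luminance", path)
        arr = arr[..., :3] @ _LUMA
    vals = np.unique(arr)
    if not np.isin(vals, (0, 255)).all():
        logger.warning(
            "%s contains non-binary values; thresholding at mid-gray", path
        )
    return np.asarray(arr) > 127.5


def write_binary_map(path: str | Path, contour: np.ndarray) -> None:
    """Write a boolean map with contour = 255 (white) on black."""
    iio.imwrite(path, (np.asarray(contour, dtype=bool) * 255).astype(np.uint8))
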