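"""Shared convolution helper with mirror boundary handling."""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve, oaconvolve

__all__ = ["convolve2d_reflect"]


def convolve2d_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """2-D linear convolution with reflect (mirror) padding.

    Mirror padding avoids the spurious border responses that zero padding
    creates on light-background stimuli.  The output has the shape of
    ``image``.  This is a true convolution (kernel flipped), matching the
    direct double-sum definition sum_{m,n} f(x-m, y-n) k(m, n).
    """
    image = np.asarray(image, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = np.pad(image, ((ph, ph), (pw, pw)), mode="reflect")
    # overlap-add is faster than one big FFT for large kernels on large maps
    conv = oaconvolve if max(kh, kw) > 64 else fftconvolve
    return conv(padded, kernel, mode="valid")
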