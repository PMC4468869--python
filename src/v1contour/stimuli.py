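"""Synthetic four-region test stimulus and fixture generators.

The canonical test image embeds a salient line (contour) in four kinds
of backgrounds, one per quadrant:

  (i)   a luminance step edge,
  (ii)  isolated line segments on blank ground,
  (iii) a random-bar texture — square cells each containing one bar at a
        uniformly random orientation — with an embedded salient vertical
        line, and
  (iv)  an oblique grating with an embedded salient vertical line.

The embedded lines use the same ink as the surrounding texture elements:
their salience arises from context (orientation contrast or its
absence), not from luminance contrast.  Orientation-selective surround
inhibition makes the line in (iv) pop out but not the one in (iii);
non-selective inhibition does the reverse; the integrated models recover
both.  The ground-truth contour map marks the step edge, the isolated
lines and the embedded salient lines, but not the texture or grating
elements (nor the texture-defined region boundaries, which these models
cannot extract).

All stimuli are rasterized without anti-aliasing (hard binary ink) so
that responses are bit-reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.draw import line as draw_line

__all__ = [
    "StimulusSpec",
    "FourRegionStimulus",
    "generate_four_region_image",
    "generate_grating",
    "generate_random_bar_texture",
    "REGION_NAMES",
]

REGION_NAMES = ("step_edge", "isolated_lines", "random_bars", "grating")


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry and rendering parameters of the four-region stimulus.

    Defaults follow the canonical configuration: 15 x 15 pixel texture
    cells each holding a 10 x 2 pixel bar at a random orientation, a
    grating of lines 15 pixels apart at 45 degrees from the vertical,
    dark ink on light ground.  The 480 x 480 canvas gives each quadrant
    16 texture cells / grating periods across, large relative to the
    non-classical receptive field at sigma = 4.
    """

    canvas_height: int = 480
    canvas_width: int = 480
    cell_size: int = 15
    bar_length: int = 10
    bar_width: int = 2
    grating_spacing: int = 15
    grating_angle_deg: float = 45.0
    background_level: float = 1.0
    ink_level: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.bar_length > self.cell_size:
            raise ValueError("bar_length must not exceed cell_size")
        if self.bar_width >= self.bar_length:
            raise ValueError("bar_width must be smaller than bar_length")
        if self.grating_spacing < 2:
            raise ValueError("grating_spacing must be at least 2")
        if not (0 <= self.ink_level < self.background_level <= 1):
            raise ValueError("need 0 <= ink_level < background_level <= 1")
        min_quadrant = 2 * max(self.cell_size, self.grating_spacing)
        if self.canvas_height < 2 * min_quadrant or self.canvas_width < 2 * min_quadrant:
            raise ValueError(
                "canvas too small to hold four regions at the given "
                "cell/spacing sizes"
            )


@dataclass
class FourRegionStimulus:
    """A rendered four-region stimulus with its annotations.

    ``region_masks`` partitions the canvas exactly into the four named
    quadrants.  ``line_masks`` marks the drawn ink of each salient
    structure that the ground truth represents.  ``salient_line_columns``
    maps the textured regions to the centre column of their embedded
    vertical line.
    """

    image: np.ndarray
    ground_truth: np.ndarray
    region_masks: dict[str, np.ndarray]
    line_masks: dict[str, np.ndarray]
    salient_line_columns: dict[str, int]
    spec: StimulusSpec

    def background_mask(
        self, region: str, line_exclusion: int = 10, margin: int = 40
    ) -> np.ndarray:
        """Background (non-contour) pixels of a region, for analysis.

        Shrinks the region by ``margin`` pixels on every side — surround
        inhibition is weakened within roughly an nCRF radius of a region
        boundary, which would otherwise dominate upper percentiles — and
        removes columns within ``line_exclusion`` of the embedded line.
        """
        mask = _erode_box(self.region_masks[region], margin)
        if region in self.salient_line_columns:
            col = self.salient_line_columns[region]
            cols = np.arange(mask.shape[1])
            mask &= np.abs(cols[None, :] - col) > line_exclusion
        else:
            mask &= ~_dilate_box(self.line_masks.get(region, np.zeros_like(mask)), 3)
        return mask

    def line_mask(self, region: str, margin: int = 40) -> np.ndarray:
        """Drawn pixels of the region's salient structure, border-trimmed."""
        return self.line_masks[region] & _erode_box(self.region_masks[region], margin)


def _erode_box(mask: np.ndarray, margin: int) -> np.ndarray:
    """Shrink a rectangular (quadrant) mask by ``margin`` on each side."""
    if margin <= 0:
        return mask.copy()
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    out = np.zeros_like(mask)
    if rows.size == 0:
        return out
    r0, r1 = rows[0] + margin, rows[-1] - margin
    c0, c1 = cols[0] + margin, cols[-1] - margin
    if r0 <= r1 and c0 <= c1:
        out[r0 : r1 + 1, c0 : c1 + 1] = mask[r0 : r1 + 1, c0 : c1 + 1]
    return out


def _dilate_box(mask: np.ndarray, radius: int) -> np.ndarray:
    from scipy.ndimage import binary_dilation

    return binary_dilation(mask, np.ones((2 * radius + 1,) * 2, dtype=bool))


def _draw_bar(
    canvas: np.ndarray,
    center_rc: tuple[float, float],
    length: float,
    width: float,
    angle_from_vertical: float,
    ink: float,
) -> None:
    """Rasterize a rotated length x width bar (hard ink, no anti-aliasing).

    A pixel is inked iff its centre lies inside the rotated rectangle.
    ``angle_from_vertical`` is in radians; 0 gives a vertical bar.
    """
    cr, cc = center_rc
    half = int(math.ceil(length / 2 + width)) + 1
    r0, r1 = int(cr - half), int(cr + half) + 1
    c0, c1 = int(cc - half), int(cc + half) + 1
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, canvas.shape[0]), min(c1, canvas.shape[1])
    rr, cc_ = np.mgrid[r0:r1, c0:c1]
    # pixel centres at (+0.5, +0.5); axis u runs along the bar
    dy = rr + 0.5 - cr
    dx = cc_ + 0.5 - cc
    ca, sa = math.cos(angle_from_vertical), math.sin(angle_from_vertical)
    u = dy * ca + dx * sa  # along the bar (vertical when angle = 0)
    v = -dy * sa + dx * ca  # across the bar
    inside = (np.abs(u) < length / 2) & (np.abs(v) < width / 2)
    canvas[r0:r1, c0:c1][inside] = ink


def generate_grating(
    angle_deg: float,
    spacing: int,
    shape: tuple[int, int],
    line_width: int = 2,
    background_level: float = 1.0,
    ink_level: float = 0.0,
) -> np.ndarray:
    """Periodic dark lines on light ground.

    ``angle_deg`` is the line orientation measured from the vertical;
    ``spacing`` the period along the line normal, in pixels.  Swapping
    the angle between 0 and 90 degrees transposes the pattern.
    """
    if spacing < 2:
        raise ValueError("spacing must be at least 2")
    h, w = shape
    a = math.radians(angle_deg)
    y, x = np.mgrid[0:h, 0:w].astype(float)
    t = x * math.cos(a) + y * math.sin(a)
    dark = np.mod(t, spacing) < line_width - 1e-9
    out = np.full(shape, background_level, dtype=float)
    out[dark] = ink_level
    return out


def generate_random_bar_texture(
    shape: tuple[int, int],
    cell: int,
    bar_len: int,
    bar_wid: int,
    seed: int,
    background_level: float = 1.0,
    ink_level: float = 0.0,
) -> np.ndarray:
    """Tile ``shape`` with cells each holding one randomly oriented bar.

    Orientations are drawn uniformly from [0, pi), one independent draw
    per cell, cells enumerated row-major from a generator seeded with
    ``seed`` — the same seed always reproduces the same texture.  Bars
    are centred in their cells and never cross cell boundaries.
    """
    if bar_len > cell:
        raise ValueError("bar_len must not exceed cell")
    rng = np.random.default_rng(seed)
    out = np.full(shape, background_level, dtype=float)
    n_rows, n_cols = shape[0] // cell, shape[1] // cell
    for i in range(n_rows):
        for j in range(n_cols):
            angle = rng.uniform(0.0, math.pi)
            center = (i * cell + cell / 2 - 0.5, j * cell + cell / 2 - 0.5)
            _draw_bar(out, center, bar_len, bar_wid, angle, ink_level)
    return out


def generate_four_region_image(spec: StimulusSpec) -> FourRegionStimulus:
    """Render the four-region stimulus, its ground truth and region masks.

    The canvas is split into 2 x 2 quadrants: step edge (top left),
    isolated lines (top right), random-bar texture with an embedded
    vertical salient line (bottom left), oblique grating with an
    embedded vertical salient line (bottom right).  Identical specs
    (including ``rng_seed``) produce bit-identical output.
    """
    h, w = spec.canvas_height, spec.canvas_width
    h2, w2 = h // 2, w // 2
    bg, ink = spec.background_level, spec.ink_level
    image = np.full((h, w), bg, dtype=float)
    gt = np.zeros((h, w), dtype=bool)
    masks = {name: np.zeros((h, w), dtype=bool) for name in REGION_NAMES}
    masks["step_edge"][:h2, :w2] = True
    masks["isolated_lines"][:h2, w2:] = True
    masks["random_bars"][h2:, :w2] = True
    masks["grating"][h2:, w2:] = True
    line_masks = {name: np.zeros((h, w), dtype=bool) for name in REGION_NAMES}

    # (i) luminance step edge: darker half-quadrant meets the background
    edge_col = w2 // 2
    mid = ink + 0.5 * (bg - ink)
    image[:h2, :edge_col] = mid
    gt[:h2, edge_col] = True
    line_masks["step_edge"][:h2, edge_col] = True

    # (ii) isolated line segments: vertical, horizontal, oblique
    seg_len = int(0.4 * min(h2, w2))
    segments = [
        ((0.3 * h2, w2 + 0.2 * w2), 0.0),  # vertical
        ((0.7 * h2, w2 + 0.5 * w2), math.pi / 2),  # horizontal
        ((0.33 * h2, w2 + 0.67 * w2), math.pi / 4),  # oblique
    ]
    for center, angle in segments:
        _draw_bar(image, center, seg_len, spec.bar_width, angle, ink)
        dr, dc = math.cos(angle), math.sin(angle)  # unit vector along line
        half = seg_len / 2 - 0.5
        r0, c0 = round(center[0] - half * dr), round(center[1] - half * dc)
        r1, c1 = round(center[0] + half * dr), round(center[1] + half * dc)
        rr, cc = draw_line(r0, c0, r1, c1)
        gt[rr, cc] = True
        line_masks["isolated_lines"][rr, cc] = True

    # (iii) random-bar texture with an embedded vertical salient line
    texture = generate_random_bar_texture(
        (h - h2, w2),
        spec.cell_size,
        spec.bar_length,
        spec.bar_width,
        spec.rng_seed,
        background_level=bg,
        ink_level=ink,
    )
    image[h2:, :w2] = texture
    col_iii = w2 // 2
    image[h2:, col_iii - 1 : col_iii + 1] = ink  # 2-px vertical salient line
    gt[h2:, col_iii] = True
    line_masks["random_bars"][h2:, col_iii - 1 : col_iii + 1] = True

    # (iv) oblique grating with an embedded vertical salient line
    grating = generate_grating(
        spec.grating_angle_deg,
        spec.grating_spacing,
        (h - h2, w - w2),
        line_width=spec.bar_width,
        background_level=bg,
        ink_level=ink,
    )
    image[h2:, w2:] = grating
    col_iv = w2 + (w - w2) // 2
    image[h2:, col_iv - 1 : col_iv + 1] = ink  # 2-px vertical salient line
    gt[h2:, col_iv] = True
    line_masks["grating"][h2:, col_iv - 1 : col_iv + 1] = True

    return FourRegionStimulus(
        image=image,
        ground_truth=gt,
        region_masks=masks,
        line_masks=line_masks,
        salient_line_columns={"random_bars": col_iii, "grating": col_iv},
        spec=spec,
    )
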