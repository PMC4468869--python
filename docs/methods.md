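# Methods

## Model overview

The package implements a feed-forward phenomenological model of contour
detection in primary visual cortex.  Five stages are composed:

1. **CRF simulation.**  Complex-cell responses are modelled by the Gabor
   energy `E(x, y; θᵢ) = √(e₀² + e_{π/2}²)`, where `e_φ` is the
   convolution of the image with the 2-D Gabor filter
   `g = (2πσ²)⁻¹ exp(−(x̃² + γ²ỹ²)/2σ²) cos(2πx̃/λ + φ)`,
   `x̃ = x cos θ + y sin θ`, `ỹ = −x sin θ + y cos θ`.  A hypercolumn of
   `N_θ` orientations `θᵢ = (i−1)π/N_θ` spans 180°; a winner-take-all
   over the hypercolumn gives the maximum energy map `Ẽ` and the
   optimal-orientation map `θ̃` (ties broken toward the lowest index,
   which matters only on featureless regions).
2. **Surround inhibition.**  The non-classical surround contributes a
   suppressive term that is a distance-weighted sum of `Ẽ`, with weight
   `W_d`: the difference-of-Gaussians `G_{kσ} − G_σ`, halfwave
   rectified (which zeroes the CRF core, so the centre never inhibits
   itself) and L1-normalised.  The non-selective term is
   `I_ns = Ẽ ∗ W_d`; the orientation-selective term additionally scales
   each surround contribution by `W_Δθ = exp(−θ_Δ²/2σ_Δ²)` of the axial
   orientation difference between centre and surround (wrapped to
   `[0, π/2]`).  Responses are `H(Ẽ − α·I)` with `H` the halfwave
   rectifier.
3. **Orientation saliency.**  `μ_ros = max_i E / Σ_i E` per pixel
   measures how dominated a location is by a single orientation
   (1/N_θ when all orientations respond equally, 1 when one carries all
   the energy).  The raw ratio is Gaussian-smoothed and min–max
   normalised to [0, 1]; thresholding at `th` gives the binary map
   `μ_bos`.
4. **Integration.**  Model 1 is a hard switch: OS inhibition (strength
   α₁) where `μ_bos = 1`, NS inhibition (strength α₂) where
   `μ_bos = 0`.  Model 2 is a soft cascade: first
   `R_os = H(Ẽ − α₁ μ_ros I_os)`, then
   `r₂ = H(R_os − α₂ (1 − μ_ros)(R_os ∗ W_d))`.  The OS stage must come
   first: non-selective suppression applied to the raw energy would
   erase contours embedded in uniformly oriented backgrounds before
   orientation contrast could protect them (the stage-order test
   demonstrates exactly this failure).
5. **Binarization and evaluation.**  Non-maxima suppression across the
   contour normal (the direction `θ̃` from the x-axis, quantized to the
   4 axial/diagonal neighbour pairs) is followed by hysteresis
   thresholding; detected maps are scored against ground truth with a
   5×5-pixel tolerance (`e_FP`, `e_FN`, `P`).

## Parameters

| parameter | meaning | default | notes |
| --- | --- | --- | --- |
| σ | CRF scale (px) | 2.0 (4.0 for the synthetic demos) | sweep grids use 1.0–2.4 |
| σ/λ | spatial-frequency bandwidth | 0.56 | ≈ one octave |
| γ | envelope aspect ratio | 0.5 | elongated along the contour |
| N_θ | hypercolumn orientations | 12 | 15° spacing |
| k | nCRF/CRF size ratio | 4 | physiological range 2–5 |
| σ_Δ | orientation-contrast tuning width | π/6 | `W_Δθ(90°) = e⁻⁴·⁵ ≈ 0.011` |
| α, α₁, α₂ | inhibition strengths | grid-dependent | α₂ given as multiples of α₁ in the model grids |
| th | BOS threshold | 0.4 | |
| ROS smoothing σ | saliency smoothing scale | 2σ | saliency should vary at nCRF, not pixel, scale |
| p | fraction of candidates above t_Bh | grid-dependent | `t_Bl = 0.5 t_Bh` |

Kernel truncation: the Gabor support half-width is `⌈3σ/γ⌉` and the
`W_d` support half-width `⌈3kσ⌉`, putting the envelope below `e⁻⁴·⁵`
at the border.  All convolutions use mirror (reflect) padding; zero
padding would create spurious border energy on light-background
stimuli.  Coordinates are (row, column) with x rightward and y
downward; the Gabor `θ` parametrises the carrier direction from the
x-axis, equivalently the preferred contour orientation from the
vertical.

## Synthetic stimulus

The generator renders a 2×2-quadrant canvas (default 480×480): a
luminance step edge; three isolated line segments; a random-bar texture
(15×15 px cells, one 10×2 px bar per cell at an orientation drawn
uniformly from [0, π), one independent seeded draw per cell, row-major);
and a grating of lines 15 px apart at 45° from the vertical.  A 2-px
salient vertical line is embedded in each textured quadrant with the
same ink as the texture elements, so its salience arises purely from
context.  Rendering is hard-ink (no anti-aliasing) for bit-exact
reproducibility.  The ground truth marks the step edge, the isolated
lines and the embedded lines — not the texture elements and not the
texture-defined region boundaries, which these models cannot extract.

What the generator does *not* emulate: luminance gradients, noise,
curved contours, occlusion, and the mixed regular/irregular textures of
natural scenes.  Tests passing on it show that the operators implement
the intended arithmetic and reproduce the canonical pop-out contrasts;
they do not certify natural-image performance, which in the literature
is benchmarked on external datasets (supported via the `--dataset`
sweep mode, not shipped).

For region-level statistics the analysis masks shrink each quadrant by
a 40 px margin (≈ the nCRF half-width at σ = 4) because surround
inhibition is weakened near region boundaries, and exclude columns
within 10 px of the embedded line; the "pop-out" statistic compares the
mean response on the line's drawn pixels with the 95th percentile of
the remaining background response.

## Numerical choices

- Convolution is FFT-based (overlap–add for the large nCRF kernels)
  over reflect-padded arrays; the OS inhibition sum is decomposed
  exactly into N_θ masked convolutions because `θ̃` takes only N_θ
  values.  A direct triple-loop summation serves as the test oracle.
- `W_Δθ` is precomputed as an N_θ×N_θ table.
- ROS: pixels with zero total energy get raw ratio 0 (no stimulus, no
  orientation salience); a constant smoothed ROS map normalises to all
  zeros.  Normalisation is per image.  Note that the literal Gabor
  filter has a small nonzero DC component, so rendered stimuli rarely
  contain exactly-zero-energy pixels.
- BOS uses `μ_ros ≥ th` (boundary value counts as salient).
- NMS keeps a pixel if it strictly exceeds one neighbour along the
  quantized normal and at least equals the other; the asymmetric rule
  thins constant plateaus to a single deterministic column.
- Hysteresis: the candidate set for the `t_Bh` quantile is the strictly
  positive post-NMS pixels; quantiles use linear interpolation;
  connectivity is 8-connected; kept-pixel sets grow monotonically
  with p.
- Evaluation: the 5×5 dilation template is clipped at borders;
  `e_FP` with no correctly detected pixel is reported as +inf
  (rendered "—" in tables); the median of an even-length sweep is the
  mean of the two central order statistics; an all-empty comparison
  scores P = 1.
- Homogeneity: every stage is 1-homogeneous and the saliency maps are
  scale-invariant, so globally rescaling the input rescales the
  responses.  Numerically this is exact only for power-of-two factors;
  other factors can flip winner-take-all ties between near-equal
  orientation energies.

## Design choices and limitations

- The divisive-normalisation view of ROS is implemented as its
  fixed-point arithmetic (the max/sum ratio), not as circuit dynamics.
  Facilitation, disinhibition, multi-scale pyramids and top-down
  feedback are out of scope.
- Model 2's second stage reuses the same `W_d` (same σ, k) as the
  first.
- The sweep grids reproduce the standard 80-combination protocol:
  8 σ × 2 α × 5 p for the single-inhibition detectors and
  4 σ × 2 α₁ × 2 α₂-multipliers × 5 p for the integrated models.  They
  were designed for natural images; applied to the synthetic stimulus
  their permissive thresholds (p up to 0.9) flood the integrated
  models' output with texture candidates, so the sweep statistics
  reported by `scripts/acceptance.py` favour the strict-threshold
  single-inhibition grids there — a property of the grids, not of the
  models, whose single-shot σ = 4 scores and pop-out indices show the
  intended advantage.
- A known, measured deviation from the idealised pop-out taxonomy: an
  extended straight line yields roughly twice the Gabor energy of a
  short bar (the elongated envelope integrates along the contour), and
  OS inhibition suppresses line and clutter in the random-bar texture
  by similar average factors (mean `W_Δθ` ≈ 0.4 under uniformly random
  surround orientations).  The embedded line therefore retains a mean
  OS response above the texture background's 95th percentile even
  though both survive together — the OS operator still fails to
  *suppress* the clutter, which is what distinguishes it from the NS
  and integrated models.
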