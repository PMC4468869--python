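# v1contour

Bio-inspired contour detection with model V1 neurons that combine
**orientation-selective** and **non-selective** surround inhibition.

Most V1 neurons are suppressed by stimulation of the region surrounding
their classical receptive field (CRF).  For some neurons that surround
suppression is strongest when centre and surround share an orientation
and decays with orientation contrast (orientation-selective, OS); for
others it is independent of orientation contrast (non-selective, NS).
The two neuron types behave almost conversely on textured scenes: OS
inhibition pops a contour out of a uniformly oriented grating but cannot
separate it from randomly oriented clutter, while NS inhibition
suppresses random clutter but extinguishes contours embedded in oriented
textures.  This package implements both operators and two integrated
models that route each image location through the appropriate inhibition
type using an orientation-saliency map, so that contours pop out of
*both* kinds of background.

## Model

A complex-cell response is simulated by the Gabor energy
`E(x, y; θᵢ) = √(e₀² + e_{π/2}²)` of a quadrature filter pair at
`N_θ = 12` orientations `θᵢ = (i−1)π/N_θ`, with a winner-take-all over
the hypercolumn giving the maximum energy map `Ẽ` and the optimal
orientation map `θ̃`.  Surround inhibition is a weighted sum of `Ẽ` over
the non-classical receptive field (nCRF, `k = 4` times the CRF size):

* distance weight `W_d = H(DOG_{σ,k}) / ‖H(DOG_{σ,k})‖₁` — a rectified,
  L1-normalised difference-of-Gaussians annulus;
* orientation-contrast weight `W_Δθ = exp(−θ_Δ² / 2σ_Δ²)` with the
  axial difference `θ_Δ ∈ [0, π/2]` and `σ_Δ = π/6`;
* `I_ns = Ẽ ∗ W_d` and `I_os(x,y) = Σ W_Δθ(θ̃(x,y), θ̃(x+m,y+n)) ·
  W_d(m,n) · Ẽ(x+m,y+n)`, giving responses `H(Ẽ − α·I)` with halfwave
  rectification `H`.

The **real-valued orientation saliency** (ROS) is the divisive-
normalisation ratio `μ_ros = max_i E(·; θᵢ) / Σ_i E(·; θᵢ)` (smoothed
and min–max normalised); thresholding at `th = 0.4` gives the binary
BOS map.  **Model 1** applies OS inhibition where BOS = 1 and NS
inhibition where BOS = 0.  **Model 2** cascades both everywhere:
`R_os = H(Ẽ − α₁ μ_ros I_os)`, then `r₂ = H(R_os − α₂ (1−μ_ros)
(R_os ∗ W_d))`.  Responses are binarized by orientation-guided
non-maxima suppression plus hysteresis (`t_Bl = 0.5 t_Bh`, `t_Bh` the
(1−p)-quantile of the positive candidates), and contour maps are scored
against ground truth with a 5×5-pixel tolerance: false-positive ratio
`e_FP = |E_FP|/|E|`, false-negative ratio `e_FN = |E_FN|/|E_GT|` and
overall performance `P = |E| / (|E| + |E_FP| + |E_FN|)`.

A seeded generator renders the canonical four-region synthetic test
image (luminance step edge; isolated lines; a random-bar texture of
15×15 px cells each holding a 10×2 px bar; a 45° grating with 15 px
spacing — with a salient vertical line embedded in each textured
region), so no download is needed.

## Worked example

```sh
python examples/integrated_models.py
```

```
Model 1 random_bars  line 0.1503 vs bg p95 0.0000
Model 1 grating      line 0.1271 vs bg p95 0.0000
Model 1 texture survival 1.88%  e_FP 1.03  e_FN 0.01  P 0.49
Model 2 random_bars  line 0.1172 vs bg p95 0.0000
Model 2 grating      line 0.1609 vs bg p95 0.0027
Model 2 texture survival 0.28%  e_FP 2.04  e_FN 0.01  P 0.33
```

Each `line ... vs bg p95 ...` row compares the mean response on the
embedded salient line with the 95th percentile of the surrounding
background response: both integrated models keep the line well above
the background in *both* the random-bar texture and the grating, which
neither single-inhibition operator achieves alone (see
`examples/surround_inhibition_popout.py`).  `texture survival` is the
fraction of background pixels in the random-bar region left with any
response — Model 2 cleans that clutter roughly seven times more
completely than Model 1.  The `e_FP/e_FN/P` numbers score the binarized
contour map against the built-in ground truth with the 5×5 tolerance.

Other examples: `examples/synthetic_stimulus.py` (render the test
image), `examples/parameter_sweep.py` (80-combination grid with
box-and-whisker summary).  The same functionality is exposed on the
command line:

```sh
v1contour synth --out-dir stimulus
v1contour detect stimulus/stimulus.png --detector model2 --sigma 4 \
    --alpha1 1.6 --alpha2 2.56 --out-dir detections
v1contour evaluate detections/stimulus_contour.png stimulus/ground_truth.png
v1contour sweep stimulus/stimulus.png stimulus/ground_truth.png \
    --detector ns --out sweep.csv
v1contour report sweep.csv --plot box.png
```

`v1contour sweep --dataset DIR` evaluates every image/ground-truth pair
in a directory laid out as `DIR/images/` + `DIR/ground_truth/` with
matching file names (the layout of the RuG contour dataset, which is
not shipped).

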