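# Methods

This note documents the models and procedures implemented in `leukosuite`,
the choices made where the design was genuinely open, and what the bundled
synthetic data can and cannot demonstrate.

## Problem setting

The toolkit automates white-blood-cell (leukocyte) analysis on stained
blood-smear micrographs: clean the image, delineate the cell against the
background, summarize its texture, and assign a leukocyte class. All
stages operate on a single intensity plane in `[0, 1]`; color images are
collapsed to luminance (ITU-R 601 weights) on read.

## Preprocessing

Five operators, each mapping `[0, 1]` grids to `[0, 1]` grids of the same
shape, with reflect padding at borders (chosen so borders are neither
darkened nor shifted; the border policy is otherwise arbitrary):

* **Denoising** — a sliding-window filter. The default is the median
  (robust to impulse noise); a neighbourhood-mean mode is also provided,
  which is exactly equivalent to convolution with a flat kernel.
* **Contrast enhancement** — histogram equalization through the empirical
  CDF over 256 bins. The mapping is monotone and idempotent up to one bin
  width. Equalization helps visual inspection but compresses minority
  foreground levels toward zero, which measurably *hurts* threshold
  segmentation of small cells; `run_pipeline` therefore allows disabling it.
* **Background removal** — hard thresholding: pixels strictly above `U`
  survive, all others become 0. Monotone in `U`.
* **Smoothing** — normalized Gaussian convolution, truncated at ±3σ; the
  global mean is preserved to ~1e-6 under reflect padding.
* **Sharpening** — `J + ν·∇²J` with the 4-neighbour Laplacian stencil.
  The additive orientation is kept as the primary form; classic unsharp
  masking (subtractive) is available behind a flag. Whether a 4- or
  8-neighbour stencil is "the" Laplacian is a convention; 4-neighbour was
  chosen and is pinned by tests.

## Segmentation: DBO-LF over intensity thresholds

### Search-space encoding

A segmentation candidate is a vector of `K` sorted intensity thresholds in
`[0, 1]` defining `K + 1` intensity regions. Thresholds were chosen over a
parametric contour encoding because they admit an *exhaustive oracle*: the
image is quantized to 256 levels, so the within-region squared error is
piecewise constant in the threshold and the global optimum can be found by
scanning all 256 positions. Tests exploit this to verify end-to-end that
the optimizer finds the true minimum.

Two fitness modes score a candidate:

* `global` (default): total within-region squared intensity error,
  evaluated in O(256) per call from histogram prefix sums.
* `localized`: the localized region energy of the contour induced by the
  candidate's foreground mask (below).

After optimization, the foreground is the region whose mean intensity lies
farthest from the histogram's dominant mode (taken as the background
level) — a deterministic, testable rule that matches smears, where
background occupies most of the frame. An optional Lloyd-style refinement
(thresholds moved to midpoints of adjacent region means, ≤5 rounds) is off
by default.

### Localized region energy

The energy follows the local region-based active-contour idea. The
contour is the zero crossing of a signed-distance field `φ` (negative
inside). A smoothed Heaviside
`H(η) = ½{1 − η/ε − sin(πη/ε)/π}` for `|η| ≤ ε` (1 below `−ε`, 0 above
`+ε`) softly labels interior versus exterior. For every pixel `y` in the
narrow band `|φ| < band_width`, interior/exterior means `v_y, u_y` are the
`H`-weighted means of the image within the strict disk `‖y − y′‖ < s`
(default `s = 4` px), and the energy sums
`H(y′)(J(y′) − v_y)² + (1 − H(y′))(J(y′) − u_y)²` over disk neighbours.
It is nonnegative and vanishes exactly when the contour separates a
two-level image in the sharp-Heaviside limit. The implementation expands
the squares into six disk convolutions; tests pin it to a literal
double-loop evaluator at 1e-9.

Full PDE-style curve evolution with reinitialization is out of scope; the
energy serves as a candidate score, not a flow.

### The optimizer

Dung Beetle Optimization evolves a population (default 30) split into four
fixed behavioural roles — 6 ball-rollers, 6 breeders, 7 foragers, 11
thieves (the conventional split):

* **Roll** `Y ← Y + b·l·Y_prev + a·|Y − Y_worst|·λ`, with `b = 0.3` fixed,
  deflection `l ∈ (0, 0.2]` (default 0.1), `a` a random sign, and `λ` a
  Levy-flight step. Attaching the heavy-tailed multiplier to the rolling
  increment is this implementation's reading of "Levy-flight enhancement":
  rolling is the global-exploration role, and occasional long jumps keep it
  exploring while breeders/foragers exploit.
* **Dance** (obstacle branch, probability 0.1 per roller per iteration)
  `Y ← Y + tan(β)|Y − Y_prev|`, `β ~ U[0, π]`; the singular and zero
  angles `{0, π/2, π}` leave the position unchanged.
* **Breed** inside the box `[X*(1−R), X*(1+R)]` shrinking around the
  iteration best `X*` with `R = 1 − t/T`.
* **Forage** with Gaussian/uniform mixing toward the box around the
  global best.
* **Steal** jumps near the global best scaled by distances to the worst
  and iteration-best positions.

All positions are clipped to bounds after every update; an elitist archive
keeps the best-so-far solution, so the reported trace is monotone
non-increasing by construction. Ties keep the earlier find. Every random
draw comes from one seeded generator, so runs are bit-reproducible. A
non-finite fitness aborts immediately, naming the offending point.

### Levy-flight sampler

Steps use the Mantegna construction: `u/|v|^(1/δ)` with
`u ~ N(0, σ_u²)`, `v ~ N(0, 1)` and `σ_u` the standard δ-dependent scale,
giving magnitude tails `~ t^(−1−δ)` for `δ ∈ (0, 2)`. The construction is
singular at `δ = 2` (its scale factor vanishes), where the distribution's
correct limit is Gaussian, so `δ = 2` returns plain Gaussian steps. Tests
check the tail exponent with a Hill estimator on the top 1% of 10⁵
magnitudes (δ = 1.5 recovered within ±0.2) and the Gaussian limit by
excess kurtosis. A pure-roll walk with δ = 2 shows linear variance growth
(ordinary diffusion), which the test suite uses as a sampler diagnostic.

### Boundary extraction

The reported boundary is the morphological inner contour
`mask & ~erode(mask)` with the 4-connected structuring element, giving a
closed, 1-pixel-wide, 8-connected curve (a 5×5 filled square yields
exactly its 16 outline pixels). This is the discrete edge-thinning route;
a gradient-based edge detector adds nothing on binary masks.

## Feature extraction

Eight scalar descriptors per image or masked region; two modes.

First-order (always on raw pixel values): mean, population standard
deviation, entropy, skewness (set to 0 when the SD is 0). Entropy in
`conventional` mode is the Shannon entropy `−Σ p log₂ p` of the 256-bin
intensity histogram; `literal` mode evaluates `Σ g log₂ g` directly over
pixels (with `0·log 0 := 0`), a signed quantity retained for exact
testability.

Texture: homogeneity (inverse difference moment), direction moment,
correlation, coarseness. The index-space forms are genuinely ambiguous
between "evaluate over image coordinates" and "evaluate over the
gray-level co-occurrence matrix"; both are shipped and neither is asserted
as canonical. `literal` mode treats the unit-normalized grid as a 2-D
mass function over its indices — exactly checkable against a double loop —
and its IDM is bounded by 1. `conventional` mode computes GLCM
homogeneity/dissimilarity/correlation (scikit-image backend) at a
configurable offset (default one pixel to the right, 32 gray levels).
Coarseness is always the literal size-scaled sum `2^−(m+n)·Σg`; the
prefactor underflows to 0 beyond `m + n ≈ 1000`, which is documented
behaviour (`exp2` keeps the underflow graceful).

## Classifier: dual-encoder attention U-shaped network

No autodiff framework is used: layers are NumPy with hand-written
backpropagation, verified against central finite differences (the only
disagreements are at exact ReLU kinks, where finite differences straddle
the nondifferentiability).

Architecture (channels-last `(B, H, W, C)`):

* **Channel A (residual encoder)** — per stage, a stack of 3×3
  convolutions + ReLU with an identity shortcut (1×1 projection when the
  width changes), then 2×2 max pooling. Pre-pool maps feed the decoder as
  skip connections. Widths double per stage from `base_width`.
* **Channel B (dilated encoder)** — per stage, three parallel 3×3
  convolutions at dilation rates 1/2/3 (receptive fields 3/5/7), fused by
  concatenation and a 1×1 convolution, then pooled. Concatenation was
  chosen over addition for fusion to preserve the per-rate information.
* **Bottleneck** — channel A and B maps concatenated; multiplicative
  (Luong) attention over the flattened spatial positions, with the
  global-average feature as query, pools a context vector. The attention
  is parameter-free; the query-is-mean choice is the only consistent
  reading for a feed-forward image network (the alternative — a recurrent
  query — belongs to sequence models).
* **Decoder** — nearest-neighbour ×2 upsampling, concatenation with the
  channel-A skip, 3×3 convolution + ReLU per stage, back to full
  resolution.
* **Head** — dropout (default 0.4), then a fully connected softmax layer
  over the attention context concatenated with the global-average decoder
  feature. Routing the decoder feature into the head gives every decoder
  parameter a gradient in classification mode.

Inputs are affinely centred (`2x − 1`) before the first convolution; this
is purely a conditioning choice and measurably stabilizes training.

Ablation switches disable attention or channel B; both change the
parameter count (the head input shrinks) while preserving every output
contract (rows of the softmax still sum to 1, all remaining parameters
still receive gradients).

The **loss** is `v·BCE + Dice` (default `v = 1`) applied to the softmax
probability vector of each sample against its one-hot label, averaged over
the batch. Predictions are clipped at 1e-7 inside the BCE; the Dice term
uses 1e-7 smoothing so the all-zero case is defined as 0. The optimizer is
Adam with Nesterov momentum (Nadam, Dozat's incorporation), learning rate
1e-3, batch size 32, dropout 0.4 — the stated training profile.
Initialization, batch order and dropout masks all derive from the training
seed, so training is exactly reproducible.

The **full profile** uses five encoder stages with (2, 2, 3, 3, 3)
convolutions. The desk-scale profile used by the bundled experiments
(`NetConfig.small()`) keeps 32×32 inputs, two stages and `base_width = 8`
(~33k parameters), which trains in tens of seconds on one CPU while
exercising every architectural element; the stage plan is the only
difference. Checkpoints round-trip bit-identically through a single
`.npz` archive holding parameters plus a JSON header.

## Evaluation metrics

Per-class one-vs-rest confusion counts; accuracy `(TP+TN)/total`,
precision, recall, F1, plus unweighted macro averages. Zero denominators
return 0 with an explicit `degenerate` flag rather than NaN. Overlap
scores are the set-cardinality Dice and Jaccard on true-pixel sets; two
empty masks score 1 by declared convention, and the identity
`Dice = 2J/(1+J)` is tested on random pairs. The Hausdorff distance is
the symmetric max–min Euclidean distance between *boundary* point sets
(boundaries via the morphological contour above), scaled by a
`pixel_spacing` parameter (units per pixel, default 1) because physical
units require a magnification the data files do not carry; an empty mask
is an error, as the distance is undefined.

## Synthetic data generator

Each sample is a light background (0.9), a darker elliptical cell and a
darker still nucleus, with three built-in classes separable by
construction:

| class | nucleus/cell area | lobes | cell / nucleus intensity |
|---|---|---|---|
| lymphocyte-like | 0.75 | 1 | 0.55 / 0.25 |
| monocyte-like | 0.50 | 1 | 0.65 / 0.35 |
| neutrophil-like | 0.30 | 3 | 0.45 / 0.15 |

Intensities within a spec are pairwise ≥ 0.1 apart, so a nearest-centroid
rule on (mean cell intensity, nucleus ratio) already exceeds 95% accuracy
on clean data — downstream training targets are attainable by
construction. Cell centre and rotation are jittered per sample from the
seed. Degradations — Gaussian noise (default SD 0.03), salt-and-pepper
impulses (1% of pixels), and a linear illumination ramp (up to 0.1) — are
applied after the masks are recorded, so ground truth always reflects the
clean geometry. Per-sample seeds derive from the master seed via
`SeedSequence(master, spawn_key=(index,))`, truncated to 31 bits.

What the generator does **not** emulate: overlapping or touching cells,
stain variability and color, out-of-focus blur, red-cell clutter with
texture, or class-imbalanced populations. Passing tests therefore
demonstrate that each stage honours its contract and that the stack
composes correctly — not that real-smear accuracy would match the
synthetic numbers.

## Problem sizes in the bundled experiments

The shipped test suite and the acceptance script use: 20 smears at
128×128 for segmentation quality; 10 optimizer seeds per benchmark at
population 30 × 300 iterations; 20 bimodal 16×16 images × 10 seeds for
the threshold-oracle check; 10⁵ Levy samples for tail estimation; and
402 samples at 32×32 (a 300/100 train/validation split) × 10 epochs for
the classifier. These sizes make the full stack reproducible on a single
CPU in minutes while leaving each estimate well away from its pass
boundary (observed: mean Dice ≈ 0.97 against ≥ 0.90, Hill index ≈ 1.53
against 1.5 ± 0.2, validation accuracy ≈ 1.0 against ≥ 0.90).

## Numerical conventions

* Intensity scale `[0, 1]` internally; 8-bit PNG on disk.
* Disk windows use the *strict* inequality `‖y − y′‖ < s`.
* Equal-fitness ties keep the earlier candidate (determinism).
* The smoothed Heaviside is oriented interior = 1, continuous at ±ε and
  monotone non-increasing.
* Max-pool routes gradient equally among tied maxima.
* All stochastic components draw from explicit `numpy.random.Generator`
  instances; no global RNG state is touched.

## Known limitations

* Threshold candidates cannot separate touching cells of similar
  intensity; instance separation (e.g. watershed) is out of scope.
* The localized-energy fitness mode is O(image × disk) per candidate and
  is practical only for small images or few iterations.
* The literal coarseness feature is uninformative for images larger than
  ~500×500 (underflow to 0 by design).
* The classifier's full five-stage profile is CPU-affordable only for
  small batches; no GPU path is provided.
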