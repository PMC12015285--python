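# leukosuite

A toolkit for automated white-blood-cell (leukocyte) analysis on stained
blood-smear micrographs: image preprocessing, cell segmentation by a
Levy-flight-enhanced dung beetle optimizer, hand-crafted texture features,
a dual-encoder attention U-shaped classifier, and the standard evaluation
metrics — all exercisable without external data through a bundled
synthetic smear generator with per-pixel ground truth.

It is aimed at researchers in computational hematology and medical image
analysis who want the individual stages of such a pipeline as tested,
reusable, CPU-friendly components.

## What is inside

* **`leukosuite.preprocess`** — median/mean denoising, histogram
  equalization, background thresholding, Gaussian smoothing, Laplacian
  sharpening; all `[0,1] → [0,1]`, shape-preserving.
* **`leukosuite.segment`** — the core contribution. A candidate
  segmentation is a vector of K intensity thresholds scored either by
  within-region squared error or by a localized region energy
  E = Σ_y Σ_{‖y′−y‖<s} [H(φ(y′))(J(y′) − v_y)² + (1 − H(φ(y′)))(J(y′) − u_y)²]
  over a narrow band around the contour (H a smoothed Heaviside of the
  signed distance φ, v_y/u_y local interior/exterior means). The search
  runs Dung Beetle Optimization — four behavioural roles: rolling,
  dancing/breeding, foraging, stealing — with heavy-tailed Levy-flight
  steps (Mantegna sampler, tail exponent δ) on the rolling role for global
  exploration. Also: boundary extraction and an exhaustive-search oracle.
* **`leukosuite.features`** — mean, SD, entropy, skewness, homogeneity
  (IDM), direction moment, correlation, coarseness; literal index-space
  and conventional GLCM modes.
* **`leukosuite.net`** — a NumPy implementation (hand-written
  backpropagation) of a dual-encoder U-shaped classifier: residual encoder
  + parallel dilated encoder (rates 1/2/3), multiplicative attention at
  the bottleneck, skip-connected decoder, softmax head; trained with
  Nadam on the combined loss v·BCE + Dice.
* **`leukosuite.metrics`** — confusion counts, accuracy/precision/recall/
  F1 with macro averages, Dice and Jaccard overlap, boundary Hausdorff
  distance.
* **`leukosuite.synth`** — reproducible synthetic smears (three
  separable leukocyte-like classes) with masks, labels and controlled
  degradations.
* **`leukosuite` CLI** — `leukosuite {simulate,preprocess,segment,
  features,train,predict,evaluate} --config cfg.yaml --seed N --out DIR`,
  with file-based stage boundaries.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
import leukosuite as lk
from leukosuite.segment import DBOConfig, segment_image

# a clean synthetic lymphocyte-like smear + realistic degradations
spec = lk.synth.DEFAULT_CLASSES[0]
sample = lk.synth.render_smear(spec, size=(128, 128), seed=3)
noisy = lk.synth.degrade_image(sample.image, lk.synth.DEFAULT_NOISE, seed=3)

# preprocess, then segment with DBO-LF (one threshold, 40 iterations)
cfg = lk.preprocess.PreprocessConfig(window=3)
clean = lk.preprocess.smooth(lk.preprocess.denoise(noisy, cfg), 1.0)
mask = segment_image(clean, K=1, cfg=DBOConfig(max_iter=40, seed=0))

dice, jaccard = lk.metrics.overlap_scores(mask, sample.mask)
hd = lk.metrics.hausdorff(mask, sample.mask)
print(f"dice={dice:.4f}  jaccard={jaccard:.4f}  hausdorff={hd:.2f} px")
```

prints

```
dice=0.9691  jaccard=0.9400  hausdorff=1.41 px
```

i.e. the recovered mask overlaps the ground truth at Dice 0.97, and no
boundary point of either contour is farther than 1.4 px from the other
contour. Region descriptors for the segmented cell come from

```python
feats = lk.features.feature_vector(clean, mask)
```

giving, for this sample, a mean cell intensity of 0.368 (darker than the
0.9 background), SD 0.118 and positive skewness 1.22 (the dark nucleus
pulls the lower tail), with texture terms in literal index-space mode.

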