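"""Synthetic blood-smear image generator with per-pixel ground truth.

Each sample is a grayscale stained-smear look-alike: a light background, a
darker elliptical cell body, and a still darker nucleus inside the cell —
optionally multi-lobed, as in granulocytes.  Three built-in leukocyte-like
classes are separable by construction through distinct intensity levels and
nucleus-to-cell area ratios:

* ``lymphocyte_like`` — large round nucleus filling most of the cell,
* ``monocyte_like`` — medium, slightly eccentric nucleus,
* ``neutrophil_like`` — small multi-lobed nucleus.

The generator is fully deterministic: every sample is a pure function of
its (spec, size, seed) triple, and a dataset derives per-sample seeds from
one master seed by a fixed splitting rule, so datasets are reproducible and
can be regenerated in parallel.  Degradations (Gaussian noise, impulse
noise, an illumination ramp) are applied after ground truth is recorded, so
masks always reflect the clean geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import write_image, write_mask

__all__ = [
    "CellSpec",
    "NoiseSpec",
    "LabeledSample",
    "DEFAULT_CLASSES",
    "render_smear",
    "degrade_image",
    "generate_dataset",
    "write_dataset",
    "derive_seed",
]


@dataclass
class CellSpec:
    """Geometry and intensity of one synthetic leukocyte class.

    ``cell_axes`` are the ellipse half-axes in pixels; ``nucleus_ratio`` is
    the target nucleus/cell area fraction; ``lobedness`` is the number of
    nucleus lobes (1 = round).  Intensities are pairwise at least 0.1 apart
    so classes stay separable by construction.
    """

    cell_axes: tuple[float, float] = (24.0, 18.0)
    nucleus_ratio: float = 0.6
    cell_intensity: float = 0.55
    nucleus_intensity: float = 0.25
    background_intensity: float = 0.9
    rotation: float = 0.0
    lobedness: int = 1
    class_label: str = "lymphocyte_like"

    def __post_init__(self) -> None:
        if not 0.0 < self.nucleus_ratio < 1.0:
            raise ValueError("nucleus_ratio must lie in (0, 1)")
        vals = [self.cell_intensity, self.nucleus_intensity, self.background_intensity]
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("intensities must lie in [0, 1]")
        for i in range(3):
            for j in range(i + 1, 3):
                if abs(vals[i] - vals[j]) < 0.1:
                    raise ValueError("intensities must be pairwise >= 0.1 apart")
        if min(self.cell_axes) <= 1:
            raise ValueError("cell axes must exceed 1 pixel")
        if self.lobedness < 1:
            raise ValueError("lobedness must be >= 1")


@dataclass
class NoiseSpec:
    """Degradations applied to a rendered smear.

    ``gaussian_sd`` — additive white-noise SD; ``impulse_fraction`` —
    fraction of pixels replaced by salt (1) or pepper (0);
    ``illumination_gradient`` — maximum additive linear ramp across the
    frame.  Outputs are clipped to ``[0, 1]``.
    """

    gaussian_sd: float = 0.0
    impulse_fraction: float = 0.0
    illumination_gradient: float = 0.0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0 or self.illumination_gradient < 0:
            raise ValueError("noise magnitudes must be nonnegative")
        if not 0.0 <= self.impulse_fraction < 1.0:
            raise ValueError("impulse_fraction must lie in [0, 1)")


@dataclass
class LabeledSample:
    """One generated sample: image, cell mask, nucleus mask, label, seed."""

    image: np.ndarray
    mask: np.ndarray
    nucleus_mask: np.ndarray
    label: str
    seed: int

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")


DEFAULT_CLASSES: list[CellSpec] = [
    CellSpec(
        cell_axes=(22.0, 20.0),
        nucleus_ratio=0.75,
        cell_intensity=0.55,
        nucleus_intensity=0.25,
        lobedness=1,
        class_label="lymphocyte_like",
    ),
    CellSpec(
        cell_axes=(26.0, 20.0),
        nucleus_ratio=0.5,
        cell_intensity=0.65,
        nucleus_intensity=0.35,
        lobedness=1,
        class_label="monocyte_like",
    ),
    CellSpec(
        cell_axes=(24.0, 22.0),
        nucleus_ratio=0.3,
        cell_intensity=0.45,
        nucleus_intensity=0.15,
        lobedness=3,
        class_label="neutrophil_like",
    ),
]


# degradation profile used by the bundled experiments: mild sensor noise,
# occasional dead/saturated pixels, and a gentle illumination ramp
DEFAULT_NOISE = NoiseSpec(gaussian_sd=0.03, impulse_fraction=0.01, illumination_gradient=0.1)


def scaled_classes(factor: float, classes: list[CellSpec] | None = None) -> list[CellSpec]:
    """The built-in classes with cell axes scaled by ``factor``.

    Useful for rendering into small frames (e.g. 32×32 classifier inputs):
    intensities and area ratios — the separable quantities — are untouched.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    out = []
    for c in classes or DEFAULT_CLASSES:
        kw = dict(c.__dict__)
        kw["cell_axes"] = (c.cell_axes[0] * factor, c.cell_axes[1] * factor)
        out.append(CellSpec(**kw))
    return out


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    rotation: float,
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = yy - center[0]
    dx = xx - center[1]
    c, s = np.cos(rotation), np.sin(rotation)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def render_smear(
    spec: CellSpec, size: tuple[int, int] = (128, 128), seed: int = 0
) -> LabeledSample:
    """Render one clean smear image with its ground-truth masks.

    The cell centre is jittered within the central quarter of the frame and
    the rotation perturbed slightly, both drawn from ``seed``, so repeated
    samples of one class vary while staying bit-reproducible.  The nucleus
    is one or more lobes whose total area approximates
    ``nucleus_ratio × cell area`` and is clipped to the cell support.
    """
    h, w = size
    if h < 32 or w < 32:
        raise ValueError("size must be at least 32x32")
    a, b = spec.cell_axes
    if 2 * a >= min(h, w) - 4 or 2 * b >= min(h, w) - 4:
        raise ValueError("cell does not fit in the frame")
    rng = np.random.default_rng(seed)
    cy = h / 2 + rng.uniform(-h / 8, h / 8)
    cx = w / 2 + rng.uniform(-w / 8, w / 8)
    # keep the jittered cell inside the frame
    margin = max(a, b) + 2
    cy = float(np.clip(cy, margin, h - margin))
    cx = float(np.clip(cx, margin, w - margin))
    rot = spec.rotation + rng.uniform(-0.3, 0.3)

    cell = _ellipse_mask(size, (cy, cx), (a, b), rot)
    target_area = spec.nucleus_ratio * np.pi * a * b
    nucleus = np.zeros(size, dtype=bool)
    k = spec.lobedness
    lobe_area = target_area / k
    # lobe half-axes from the area, slightly eccentric
    la = np.sqrt(lobe_area / np.pi) * 1.15
    lb = lobe_area / (np.pi * la)
    if k == 1:
        centers = [(cy, cx)]
    else:
        # lobes on a small ring inside the cell
        ring = 0.45 * min(a, b)
        angles = rng.uniform(0, 2 * np.pi) + np.arange(k) * 2 * np.pi / k
        centers = [(cy + ring * np.sin(t), cx + ring * np.cos(t)) for t in angles]
    for (ly, lx), ang in zip(centers, rng.uniform(0, np.pi, size=k)):
        nucleus |= _ellipse_mask(size, (ly, lx), (la, lb), ang)
    nucleus &= cell  # geometric consistency: every nucleus pixel is a cell pixel

    image = np.full(size, spec.background_intensity)
    image[cell] = spec.cell_intensity
    image[nucleus] = spec.nucleus_intensity
    return LabeledSample(image, cell, nucleus, spec.class_label, seed)


def degrade_image(image: np.ndarray, noise: NoiseSpec, seed: int = 0) -> np.ndarray:
    """Apply the degradations of ``noise`` to an image; clip to ``[0, 1]``.

    A zero spec is the identity.  Impulse pixels are chosen without
    replacement and set to 0 or 1 with equal probability.
    """
    image = np.asarray(image, dtype=float)
    rng = np.random.default_rng(seed)
    out = image.copy()
    if noise.illumination_gradient > 0:
        h, w = out.shape
        ramp = np.linspace(0, noise.illumination_gradient, w)[None, :]
        out = out + ramp
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape)
    if noise.impulse_fraction > 0:
        n_imp = int(round(noise.impulse_fraction * out.size))
        idx = rng.choice(out.size, size=n_imp, replace=False)
        vals = rng.integers(0, 2, size=n_imp).astype(float)
        flat = out.ravel()
        flat[idx] = vals
        out = flat.reshape(out.shape)
    return np.clip(out, 0.0, 1.0)


def derive_seed(master_seed: int, index: int) -> int:
    """Fixed master-seed → per-sample-seed splitting rule.

    Uses numpy's ``SeedSequence(master, spawn_key=(index,))`` entropy
    expansion, truncated to a 31-bit integer.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(
    n_per_class: int,
    classes: list[CellSpec] | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    size: tuple[int, int] = (128, 128),
) -> list[LabeledSample]:
    """Generate ``n_per_class`` degraded samples for each class.

    Per-sample seeds come from :func:`derive_seed`, so the dataset is a pure
    function of the master seed; masks record the clean geometry.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if classes is None:
        classes = DEFAULT_CLASSES
    if not classes:
        raise ValueError("need at least one class")
    noise = noise or NoiseSpec()
    out = []
    idx = 0
    for spec in classes:
        for _ in range(n_per_class):
            s = derive_seed(seed, idx)
            sample = render_smear(spec, size=size, seed=s)
            sample.image = degrade_image(sample.image, noise, seed=s + 1)
            out.append(sample)
            idx += 1
    return out


def write_dataset(samples: list[LabeledSample], out_dir) -> Path:
    """Write images/masks as 8-bit PNG, labels as CSV, manifest as JSON."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = ["sample_id,label,seed"]
    manifest = []
    for i, s in enumerate(samples):
        img_path = out_dir / "images" / f"sample_{i:04d}.png"
        mask_path = out_dir / "masks" / f"sample_{i:04d}.png"
        write_image(img_path, s.image)
        write_mask(mask_path, s.mask)
        rows.append(f"sample_{i:04d},{s.label},{s.seed}")
        manifest.append(
            {
                "sample_id": f"sample_{i:04d}",
                "image": str(img_path.relative_to(out_dir)),
                "mask": str(mask_path.relative_to(out_dir)),
                "label": s.label,
                "seed": s.seed,
            }
        )
    (out_dir / "labels.csv").write_text("\n".join(rows) + "\n")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out_dir
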