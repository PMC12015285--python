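"""Hand-crafted intensity and texture descriptors for leukocyte regions.

Eight scalar features per image (or per masked region): four first-order
statistics — mean, standard deviation, entropy, skewness — and four texture
terms — homogeneity (inverse difference moment, IDM), direction moment,
correlation, and coarseness.

Two modes are offered.  ``literal`` evaluates the texture formulas directly
over image indices, treating the unit-normalized grid as a 2-D mass
function — exactly testable against a brute-force double loop.
``conventional`` computes the same quantities where they conventionally
live: the entropy on the intensity histogram, and IDM / direction moment /
correlation on the gray-level co-occurrence matrix (GLCM) at a fixed pixel
offset.  Coarseness is always the literal size-scaled intensity sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix, graycoprops

__all__ = ["FeatureConfig", "first_order", "texture", "feature_vector", "feature_table"]

FEATURE_NAMES = (
    "mean",
    "std",
    "entropy",
    "skewness",
    "idm",
    "dm",
    "correlation",
    "coarseness",
)


@dataclass
class FeatureConfig:
    """Mode and histogram/GLCM parameters for feature extraction."""

    mode: str = "literal"
    bins: int = 256
    glcm_offset: tuple[int, int] = (0, 1)
    glcm_levels: int = 32

    def __post_init__(self) -> None:
        if self.mode not in ("literal", "conventional"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")


def _check(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty grid")
    return image


def first_order(image: np.ndarray, cfg: FeatureConfig | None = None):
    """Mean, standard deviation, entropy and skewness of the pixel values.

    Mean/SD/skewness are the population moments of the raw pixels (skewness
    is 0 by convention when SD is 0).  Entropy in ``conventional`` mode is
    the Shannon entropy ``−Σ p·log₂ p`` of the normalized intensity
    histogram; in ``literal`` mode it is the raw pixel sum ``Σ g·log₂ g``
    with ``0·log 0 := 0``.
    """
    cfg = cfg or FeatureConfig()
    g = _check(image)
    m = float(g.mean())
    sd = float(np.sqrt(np.mean((g - m) ** 2)))
    if sd == 0.0:
        skew = 0.0
    else:
        skew = float(np.mean((g - m) ** 3) / sd**3)
    if cfg.mode == "conventional":
        idx = np.clip((g * (cfg.bins - 1)).round().astype(int), 0, cfg.bins - 1)
        p = np.bincount(idx.ravel(), minlength=cfg.bins) / g.size
        nz = p[p > 0]
        ent = float(-np.sum(nz * np.log2(nz)))
    else:
        flat = g.ravel()
        nz = flat[flat > 0]
        ent = float(np.sum(nz * np.log2(nz)))
    return m, sd, ent, skew


def _literal_texture(g: np.ndarray):
    """Index-space texture terms on the unit-normalized grid."""
    total = g.sum()
    p = g / total if total > 0 else np.zeros_like(g)
    m, n = p.shape
    x = np.arange(m)[:, None]
    y = np.arange(n)[None, :]
    idm = float(np.sum(p / (1.0 + (x - y) ** 2)))
    dm = float(np.sum(p * np.abs(x - y)))
    # correlation of the index coordinates under the mass function p
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mx = float(np.sum(np.arange(m) * px))
    my = float(np.sum(np.arange(n) * py))
    sx = float(np.sqrt(np.sum((np.arange(m) - mx) ** 2 * px)))
    sy = float(np.sqrt(np.sum((np.arange(n) - my) ** 2 * py)))
    if sx == 0.0 or sy == 0.0:
        corr = 0.0
    else:
        corr = float((np.sum(x * y * p) - mx * my) / (sx * sy))
    return idm, dm, corr


def _glcm_texture(g: np.ndarray, cfg: FeatureConfig):
    """GLCM homogeneity / dissimilarity / correlation at ``glcm_offset``."""
    levels = cfg.glcm_levels
    q = np.clip((g * (levels - 1)).round().astype(np.uint8), 0, levels - 1)
    dr, dc = cfg.glcm_offset
    dist = int(round(np.hypot(dr, dc)))
    angle = float(np.arctan2(-dr, dc))
    glcm = graycomatrix(q, [max(dist, 1)], [angle], levels=levels, symmetric=False, normed=True)
    idm = float(graycoprops(glcm, "homogeneity")[0, 0])
    dm = float(graycoprops(glcm, "dissimilarity")[0, 0])
    corr = float(graycoprops(glcm, "correlation")[0, 0])
    return idm, dm, corr


def coarseness(image: np.ndarray) -> float:
    """Size-scaled intensity sum ``2^−(m+n) · Σ g`` on the raw values.

    The prefactor underflows to 0 for grids with ``m + n`` beyond ~1000
    (float64 limit); evaluated via ``exp2`` so the underflow is graceful.
    """
    g = _check(image)
    m, n = g.shape
    return float(g.sum() * np.exp2(-float(m + n)))


def texture(image: np.ndarray, cfg: FeatureConfig | None = None):
    """IDM, direction moment, correlation and coarseness of a grid."""
    cfg = cfg or FeatureConfig()
    g = _check(image)
    if cfg.mode == "literal":
        idm, dm, corr = _literal_texture(g)
    else:
        idm, dm, corr = _glcm_texture(g, cfg)
    return idm, dm, corr, coarseness(g)


def feature_vector(image: np.ndarray, mask: np.ndarray | None = None, cfg: FeatureConfig | None = None) -> dict:
    """All eight descriptors of one image, optionally restricted to a mask.

    First-order statistics use only masked pixels; texture terms are
    computed on the image with pixels outside the mask zeroed (the index
    grid must stay rectangular).
    """
    cfg = cfg or FeatureConfig()
    g = _check(image)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != g.shape:
            raise ValueError("image and mask shapes differ")
        fo_src = g[mask] if mask.any() else g
        tex_src = np.where(mask, g, 0.0)
    else:
        fo_src = g
        tex_src = g
    m, sd, ent, skew = first_order(fo_src, cfg)
    idm, dm, corr, coarse = texture(tex_src, cfg)
    return dict(zip(FEATURE_NAMES, (m, sd, ent, skew, idm, dm, corr, coarse)))


def feature_table(samples, cfg: FeatureConfig | None = None) -> pd.DataFrame:
    """Feature rows for a list of ``(image, mask-or-None)`` pairs.

    Returns a DataFrame with ``sample_id``, ``mode`` and one column per
    descriptor, in a fixed column order suitable for CSV export.
    """
    cfg = cfg or FeatureConfig()
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    rows = []
    for i, (image, mask) in enumerate(samples):
        row = {"sample_id": i, "mode": cfg.mode}
        row.update(feature_vector(image, mask, cfg))
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", "mode", *FEATURE_NAMES])
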