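"""Image preprocessing operators for stained blood-smear micrographs.

Five operators are provided, each mapping a ``[0, 1]`` intensity grid to a
``[0, 1]`` grid of the same shape:

* :func:`denoise` — neighbourhood median (default) or neighbourhood mean,
* :func:`equalize` — histogram equalization via the empirical CDF,
* :func:`remove_background` — keep pixels above a threshold, zero the rest,
* :func:`smooth` — normalized truncated Gaussian convolution,
* :func:`sharpen` — additive Laplacian sharpening.

All neighbourhood operators use reflect padding so borders are neither
darkened nor shifted.  Images are floating point throughout; 8-bit files are
rescaled on read and write (see :mod:`leukosuite.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PreprocessConfig",
    "denoise",
    "equalize",
    "remove_background",
    "smooth",
    "sharpen",
    "run_pipeline",
]

# 4-neighbour discrete Laplacian stencil
_LAPLACIAN = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    Parameters
    ----------
    window : int
        Odd neighbourhood side length for :func:`denoise`.
    threshold_U : float
        Background-removal threshold in ``[0, 1]``.
    gaussian_sd : float
        Standard deviation (pixels) of the smoothing kernel.
    sharpen_nu : float
        Nonnegative scale of the Laplacian sharpening term.
    noise_mode : str
        ``"median"`` (neighbourhood median) or ``"mean"``
        (neighbourhood arithmetic mean).
    """

    window: int = 3
    threshold_U: float = 0.0
    gaussian_sd: float = 1.0
    sharpen_nu: float = 0.5
    noise_mode: str = "median"
    use_equalize: bool = True

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if not 0.0 <= self.threshold_U <= 1.0:
            raise ValueError("threshold_U must lie in [0, 1]")
        if self.gaussian_sd <= 0:
            raise ValueError("gaussian_sd must be positive")
        if self.sharpen_nu < 0:
            raise ValueError("sharpen_nu must be nonnegative")
        if self.noise_mode not in ("median", "mean"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a nonempty 2-D intensity grid")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image


def denoise(image: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Suppress pixel noise with a sliding-window filter.

    ``median`` mode replaces each pixel by the median of its
    ``window × window`` neighbourhood; ``mean`` mode uses the
    neighbourhood arithmetic mean.  Reflect padding at the borders.
    """
    image = _check_image(image)
    if cfg.window > min(image.shape):
        raise ValueError("window larger than the image")
    if cfg.noise_mode == "median":
        out = ndimage.median_filter(image, size=cfg.window, mode="reflect")
    else:
        out = ndimage.uniform_filter(image, size=cfg.window, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def equalize(image: np.ndarray, bins: int = 256) -> np.ndarray:
    """Histogram equalization: map each pixel through the empirical CDF.

    The CDF is computed from a ``bins``-level histogram over ``[0, 1]`` and
    rescaled so the output again lies in ``[0, 1]``.  The mapping is monotone,
    so the intensity ordering of pixels is preserved up to ties.
    """
    image = _check_image(image)
    idx = np.clip((image * (bins - 1)).round().astype(int), 0, bins - 1)
    hist = np.bincount(idx.ravel(), minlength=bins)
    cdf = np.cumsum(hist) / image.size
    return cdf[idx]


def remove_background(image: np.ndarray, U: float) -> np.ndarray:
    """Zero every pixel not strictly above the threshold ``U``."""
    image = _check_image(image)
    if not 0.0 <= U <= 1.0:
        raise ValueError("U must lie in [0, 1]")
    return np.where(image > U, image, 0.0)


def smooth(image: np.ndarray, sd: float) -> np.ndarray:
    """Convolve with a normalized Gaussian kernel truncated at ±3·sd.

    The kernel sums to one, so constant images are fixed points and, under
    reflect padding, the global mean is preserved to floating-point accuracy.
    """
    image = _check_image(image)
    if sd <= 0:
        raise ValueError("sd must be positive")
    return np.clip(
        ndimage.gaussian_filter(image, sigma=sd, mode="reflect", truncate=3.0),
        0.0,
        1.0,
    )


def sharpen(image: np.ndarray, nu: float, subtract: bool = False) -> np.ndarray:
    """Laplacian sharpening ``J + ν·∇²J`` with the 4-neighbour stencil.

    The additive form is the default; classic unsharp masking subtracts the
    Laplacian instead, which ``subtract=True`` selects.  Output clipped to
    ``[0, 1]``.
    """
    image = _check_image(image)
    if nu < 0:
        raise ValueError("nu must be nonnegative")
    lap = ndimage.convolve(image, _LAPLACIAN, mode="reflect")
    sign = -1.0 if subtract else 1.0
    return np.clip(image + sign * nu * lap, 0.0, 1.0)


def run_pipeline(image: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Apply denoise → equalize → background removal → smooth → sharpen.

    Histogram equalization can be disabled (``use_equalize=False``); it
    helps visual contrast but compresses minority foreground levels, which
    hurts threshold-based segmentation.
    """
    out = denoise(image, cfg)
    if cfg.use_equalize:
        out = equalize(out)
    out = remove_background(out, cfg.threshold_U)
    out = smooth(out, cfg.gaussian_sd)
    return sharpen(out, cfg.sharpen_nu)
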