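"""Reading and writing images, masks and small tabular artifacts.

Images are handled as float grids in [0, 1] internally; files are 8-bit
grayscale PNG/JPEG.  RGB inputs are collapsed to luminance with the
ITU-R 601 weights 0.299/0.587/0.114.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image", "read_mask", "write_mask"]

_LUMA = np.array([0.299, 0.587, 0.114])


def read_image(path) -> np.ndarray:
    """Read an 8-bit image file as a float grid in [0, 1] (RGB → luminance)."""
    arr = iio.imread(Path(path))
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    return np.clip(arr / 255.0, 0.0, 1.0)


def write_image(path, image: np.ndarray) -> None:
    """Write a [0, 1] float grid as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255.0).round().astype(np.uint8))


def read_mask(path) -> np.ndarray:
    """Read a binary mask stored as 0/255 PNG."""
    return iio.imread(Path(path)) > 127


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as 0/255 8-bit PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))
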