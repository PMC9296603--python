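"""Image input/output: grayscale loading and binary/16-bit map writing."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ShapeError

LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def to_grayscale(array: np.ndarray) -> np.ndarray:
    """Convert an image array to float grayscale in [0, 1].

    RGB(A) is collapsed by the 0.299/0.587/0.114 luminance weights; integer
    dtypes are scaled by their full range.
    """
    array = np.asarray(array)
    if array.ndim == 3:
        if array.shape[2] < 3:
            array = array[:, :, 0]
        else:
            array = array[:, :, :3] @ LUMA_WEIGHTS
    if array.ndim != 2:
        raise ShapeError(f"cannot interpret array of ndim={array.ndim} as an image")
    if np.issubdtype(array.dtype, np.integer):
        return array.astype(float) / np.iinfo(array.dtype).max
    return array.astype(float)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/PGM image as float grayscale in [0, 1]."""
    return to_grayscale(iio.imread(path))


def load_edge_map(path: str | Path) -> np.ndarray:
    """Read a 1-bit (or thresholdable grayscale) edge map as a boolean grid."""
    return to_grayscale(iio.imread(path)) > 0.5


def save_edge_map(path: str | Path, edge_map: np.ndarray) -> None:
    """Write a boolean map as an 8-bit black/white PNG/PGM."""
    iio.imwrite(path, (np.asarray(edge_map, dtype=bool) * 255).astype(np.uint8))


def save_gray16(path: str | Path, values: np.ndarray) -> None:
    """Write values in [0, 1] as a 16-bit grayscale image (NaN maps to 0)."""
    v = np.nan_to_num(np.asarray(values, dtype=float), nan=0.0)
    iio.imwrite(path, np.clip(v * 65535, 0, 65535).astype(np.uint16))
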