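"""Candidate edge pixels (CEP): the pre-screened set the EM stage classifies.

Gestalt edges must be edges, so the extractor starts from the output of a
standard low-level detector and only ever *removes* pixels.  Canny is the
default front end; any externally produced binary edge map can be loaded and
unioned in (e.g. a Gabor-energy detector's output).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import canny

from .errors import ConfigurationError, ShapeError

DEFAULT_HIGH = 0.2
DEFAULT_LOW_RATIO = 0.4
DEFAULT_SIGMA = math.sqrt(2.0)


@dataclass
class CandidateSet:
    """A set of (row, col) candidate edge coordinates with provenance.

    Coordinates are 0-based, row increasing downward.  ``params`` records the
    detector settings that produced the set.
    """

    pixels: frozenset
    shape: tuple[int, int]
    source: tuple[str, ...] = ("unknown",)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for r, c in self.pixels:
            if not (0 <= r < self.shape[0] and 0 <= c < self.shape[1]):
                raise ShapeError(f"candidate ({r}, {c}) outside bounds {self.shape}")

    def __len__(self) -> int:
        return len(self.pixels)

    def __contains__(self, pixel) -> bool:
        return tuple(pixel) in self.pixels

    def sorted_pixels(self) -> list[tuple[int, int]]:
        """Raster order (top-left to bottom-right), the deterministic queue order."""
        return sorted(self.pixels)

    def to_map(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for r, c in self.pixels:
            out[r, c] = True
        return out


def canny_cep(
    image: np.ndarray,
    high: float = DEFAULT_HIGH,
    low: float | None = None,
    sigma: float = DEFAULT_SIGMA,
    normalize_thresholds: bool = True,
) -> CandidateSet:
    """Run the Canny detector and collect its thinned edge pixels.

    Defaults follow the usual dual-threshold setting high = 0.2,
    low = 0.4 * high, smoothing sigma = sqrt(2).  With
    ``normalize_thresholds=True`` the thresholds are read as fractions of the
    maximal smoothed-gradient magnitude (the Matlab-style normalized-gradient
    interpretation); otherwise they are passed to the backend as absolute
    values.  A blank image yields an empty set, not an error.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ShapeError(f"expected a 2-D grayscale image, got ndim={image.ndim}")
    if low is None:
        low = DEFAULT_LOW_RATIO * high
    if not (0 < high < 1) or not (0 < low < high):
        raise ConfigurationError("thresholds must satisfy 0 < low < high < 1")
    if sigma <= 0:
        raise ConfigurationError("sigma must be positive")

    lo, hi = low, high
    if normalize_thresholds:
        smoothed = ndimage.gaussian_filter(image, sigma, mode="reflect")
        gmax = np.hypot(ndimage.sobel(smoothed, axis=0), ndimage.sobel(smoothed, axis=1)).max()
        if gmax == 0:
            return CandidateSet(frozenset(), image.shape, ("canny",),
                                {"high": high, "low": low, "sigma": sigma})
        lo, hi = low * gmax, high * gmax

    edges = canny(image, sigma=sigma, low_threshold=lo, high_threshold=hi)
    pixels = frozenset(map(tuple, np.argwhere(edges)))
    return CandidateSet(pixels, image.shape, ("canny",),
                        {"high": high, "low": low, "sigma": sigma})


def load_external_cep(edge_map: np.ndarray, source: str = "external") -> CandidateSet:
    """Wrap an externally supplied binary edge map as a candidate set."""
    edge_map = np.asarray(edge_map)
    if edge_map.ndim != 2:
        raise ShapeError(f"expected a 2-D binary edge map, got ndim={edge_map.ndim}")
    pixels = frozenset(map(tuple, np.argwhere(edge_map.astype(bool))))
    return CandidateSet(pixels, edge_map.shape, (source,))


def union_cep(a: CandidateSet, b: CandidateSet) -> CandidateSet:
    """Set union of two candidate sets over the same image bounds."""
    if a.shape != b.shape:
        raise ShapeError(f"bound mismatch: {a.shape} vs {b.shape}")
    return CandidateSet(a.pixels | b.pixels, a.shape, a.source + b.source,
                        {**b.params, **a.params})
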