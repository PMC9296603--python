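"""Low-level training data for the EM mask: prefiltering, gradients, and feature maps.

The EM stage consumes three per-pixel quantities derived from the input image:

* ``g`` — gradient magnitude, from any of the classic 3x3 / 2x2 operators;
* ``gN`` — the log-magnitude min-max normalized to [0, 1], used both as the
  threshold variable for the feature maps and as the Bayes prior downstream;
* ``theta`` — gradient orientation in degrees on [-90, 90), undefined (NaN)
  where the gradient vanishes.

Thresholding ``gN`` at ``tau`` splits the orientation data into two null-masked
planes: ``theta_tau`` keeps orientations of strong-gradient pixels (the gestalt
class observable data) and ``theta_bar_tau`` keeps the weak-gradient rest.  The
two planes partition the theta-defined pixels; null entries are NaN and never
enter a histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DegenerateInputError, ShapeError

DEFAULT_GAUSSIAN_SIGMA = np.sqrt(2.0)
DEFAULT_MEDIAN_SIZE = 3

_ROBERTS_PLUS = np.array([[1.0, 0.0], [0.0, -1.0]])
_ROBERTS_MINUS = np.array([[0.0, 1.0], [-1.0, 0.0]])


@dataclass
class GradientField:
    """Per-pixel gradient magnitude, normalized log-magnitude, and orientation.

    ``theta`` is NaN exactly where ``g`` is zero; ``gN`` lies in [0, 1] with the
    maximal log-magnitude mapped to 1 and the minimal positive one to 0.
    """

    g: np.ndarray
    gN: np.ndarray
    theta: np.ndarray
    operator: str = "sobel"
    convention: str = "printed"

    @property
    def theta_defined(self) -> np.ndarray:
        """Boolean mask of pixels with a defined orientation (g > 0)."""
        return ~np.isnan(self.theta)


@dataclass
class FeatureMaps:
    """The two null-masked orientation planes observed by the EM mask.

    ``theta_tau`` is non-null only where ``gN > tau`` (strong gradients, class
    Omega data); ``theta_bar_tau`` only where ``gN <= tau`` (class Omega-bar).
    Their non-null supports partition the theta-defined pixels.
    """

    theta_tau: np.ndarray
    theta_bar_tau: np.ndarray
    tau: float
    bin_count: int = 49
    convention: str = field(default="printed", repr=False)

    @property
    def bin_width(self) -> float:
        return 180.0 / self.bin_count

    @property
    def shape(self) -> tuple[int, int]:
        return self.theta_tau.shape

    def theta_at(self, pixel: tuple[int, int]) -> float:
        """Raw orientation of ``pixel`` (NaN if the gradient vanished there)."""
        v = self.theta_tau[pixel]
        if np.isnan(v):
            v = self.theta_bar_tau[pixel]
        return float(v)

    def to_array(self) -> np.ndarray:
        """Two-plane float stack (NaN sentinel for null), for debugging dumps."""
        return np.stack([self.theta_tau, self.theta_bar_tau])

    @classmethod
    def from_array(cls, planes: np.ndarray, tau: float, bin_count: int = 49) -> "FeatureMaps":
        if planes.ndim != 3 or planes.shape[0] != 2:
            raise ShapeError("expected a (2, H, W) plane stack")
        return cls(planes[0], planes[1], tau, bin_count)


def prefilter(image: np.ndarray, kind: str = "gaussian", param: float | None = None) -> np.ndarray:
    """Optionally smooth the raw image before gradient computation.

    ``kind`` is ``"gaussian"`` (sigma = ``param``, default sqrt(2), matching the
    Canny smoothing default), ``"median"`` (square kernel of odd size ``param``,
    default 3), or ``"none"``.  Reflect padding keeps the output the same shape.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ShapeError(f"expected a 2-D grayscale image, got ndim={image.ndim}")
    if kind == "none":
        return image
    if kind == "gaussian":
        sigma = DEFAULT_GAUSSIAN_SIGMA if param is None else float(param)
        if sigma <= 0:
            raise ConfigurationError("gaussian sigma must be positive")
        return ndimage.gaussian_filter(image, sigma=sigma, mode="reflect")
    if kind == "median":
        size = DEFAULT_MEDIAN_SIZE if param is None else int(param)
        if size < 1:
            raise ConfigurationError("median kernel size must be >= 1")
        return ndimage.median_filter(image, size=size, mode="reflect")
    raise ConfigurationError(f"unknown prefilter kind: {kind!r}")


def _directional_gradients(image: np.ndarray, operator: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (g_rows, g_cols): derivatives along axis 0 and axis 1."""
    if operator in ("sobel", "prewitt"):
        fn = ndimage.sobel if operator == "sobel" else ndimage.prewitt
        return fn(image, axis=0, mode="reflect"), fn(image, axis=1, mode="reflect")
    if operator == "roberts":
        gp = ndimage.convolve(image, _ROBERTS_PLUS, mode="reflect")
        gm = ndimage.convolve(image, _ROBERTS_MINUS, mode="reflect")
        # rotate the 45-degree Roberts responses back onto the row/col axes
        return (gp + gm) / np.sqrt(2.0), (gm - gp) / np.sqrt(2.0)
    raise ConfigurationError(f"unknown gradient operator: {operator!r}")


def orientation_from_gradients(
    g_rows: np.ndarray, g_cols: np.ndarray, convention: str = "printed"
) -> np.ndarray:
    """Fold gradient components into an axial orientation in degrees on [-90, 90).

    ``"printed"`` uses arctan(g_x / g_y) with g_x the horizontal (column)
    derivative — a vertical step edge reads |theta| = 90.  ``"standard"`` uses
    the conventional arctan(g_y / g_x), where the same edge reads theta = 0.
    """
    if convention == "printed":
        ang = np.degrees(np.arctan2(g_cols, g_rows))
    elif convention == "standard":
        ang = np.degrees(np.arctan2(g_rows, g_cols))
    else:
        raise ConfigurationError(f"unknown orientation convention: {convention!r}")
    return ((ang + 90.0) % 180.0) - 90.0


def normalize_magnitude(
    g: np.ndarray, clip_percentiles: tuple[float, float] | None = None
) -> np.ndarray:
    """Min-max normalize log-magnitudes to [0, 1].

    The log restricts to positive magnitudes; zero-magnitude pixels map to 0.
    ``clip_percentiles=(lo, hi)`` winsorizes the log values before the min-max,
    guarding against isolated extreme responses.  A constant positive magnitude
    has no range: those pixels map to 1 by convention, with a warning.
    """
    g = np.asarray(g, dtype=float)
    pos = g > 0
    if not pos.any():
        raise DegenerateInputError("all-zero gradient magnitude")
    logs = np.log(g[pos])
    if clip_percentiles is not None:
        lo, hi = np.percentile(logs, clip_percentiles)
        logs = np.clip(logs, lo, hi)
    span = logs.max() - logs.min()
    gN = np.zeros_like(g)
    if span == 0:
        warnings.warn("constant positive gradient magnitude; gN set to 1 on its support")
        gN[pos] = 1.0
        return gN
    gN[pos] = (logs - logs.min()) / span
    return gN


def compute_gradient_field(
    image: np.ndarray,
    operator: str = "sobel",
    convention: str = "printed",
    clip_percentiles: tuple[float, float] | None = None,
) -> GradientField:
    """Differentiate the image and assemble magnitude, gN, and orientation.

    A constant image yields g = 0 everywhere, all-NaN theta, and gN = 0 (the
    degenerate normalization is tolerated here; downstream tau selection is
    where it becomes an error).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ShapeError(f"expected a 2-D grayscale image, got ndim={image.ndim}")
    if operator in ("sobel", "prewitt") and min(image.shape) < 3:
        raise ShapeError("image must be at least 3x3 for 3x3 gradient operators")
    g_rows, g_cols = _directional_gradients(image, operator)
    g = np.hypot(g_rows, g_cols)
    theta = orientation_from_gradients(g_rows, g_cols, convention)
    theta[g == 0] = np.nan
    if (g > 0).any():
        gN = normalize_magnitude(g, clip_percentiles)
    else:
        gN = np.zeros_like(g)
    return GradientField(g=g, gN=gN, theta=theta, operator=operator, convention=convention)


def select_tau(gN: np.ndarray, mode: str = "median", mask: np.ndarray | None = None) -> float:
    """Pick the feature-map threshold as the median or mean of gN.

    ``mask`` restricts the statistic to theta-defined pixels (the pipeline
    passes the gradient field's validity mask).  The threshold must strictly
    separate, i.e. lie in (0, 1); a constant gN cannot and raises.
    """
    if mode not in ("median", "mean"):
        raise ConfigurationError(f"unknown tau mode: {mode!r}")
    vals = np.asarray(gN, dtype=float)
    if mask is not None:
        vals = vals[np.asarray(mask, dtype=bool)]
    vals = vals.ravel()
    if vals.size == 0:
        raise DegenerateInputError("no pixels available for tau selection")
    tau = float(np.median(vals) if mode == "median" else np.mean(vals))
    if not 0.0 < tau < 1.0:
        raise DegenerateInputError(
            f"tau = {tau} does not strictly separate gN values (constant or degenerate gN)"
        )
    return tau


def build_feature_maps(field: GradientField, tau: float, bn: int = 49) -> FeatureMaps:
    """Split orientations into the strong-gradient and weak-gradient planes.

    A pixel with gN <= tau is null in ``theta_tau`` and present in
    ``theta_bar_tau`` (boundary assigned to the complement class); gN > tau is
    the reverse.  Pixels with undefined theta are null in both.
    """
    if not 0.0 < tau < 1.0:
        raise ConfigurationError("tau must lie strictly between 0 and 1")
    if bn < 1:
        raise ConfigurationError("bin count must be a positive integer")
    strong = field.gN > tau
    theta_tau = np.where(strong, field.theta, np.nan)
    theta_bar_tau = np.where(~strong, field.theta, np.nan)
    return FeatureMaps(
        theta_tau=theta_tau,
        theta_bar_tau=theta_bar_tau,
        tau=float(tau),
        bin_count=int(bn),
        convention=field.convention,
    )
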