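"""Synthetic fixtures: worked mask contents, planted line fields, shape scenes.

Everything the test suite samples is generated here, deterministically from a
seed: the four worked converged-mask contents (uniform, minority-target,
majority-target, single-bin), orientation fields with a planted principal
direction, piecewise-constant shape scenes with constructed (not detected)
boundary ground truth, and the two noise models used in the robustness
experiments — additive Gaussian noise of variance 0.01 and 10% salt-and-pepper
impulse noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .em_mask import bin_center
from .errors import ConfigurationError, ShapeError
from .gradient_features import FeatureMaps

__all__ = [
    "SyntheticScene",
    "fig6_fixture",
    "line_field",
    "feature_maps_from_field",
    "line_scene",
    "shape_scene",
    "noisy_square_scene",
    "add_noise",
]

FIG6_BN = 49
_MAJORITY_ANGLE = 0.0  # a "right-arrow" orientation, bin center under Bn=49 irrelevant
_MINORITY_ANGLE = 45.0


@dataclass
class SyntheticScene:
    """Rendered image plus exact contour ground truth and provenance."""

    image: np.ndarray
    gt_contours: np.ndarray
    field_gt: np.ndarray | None = None
    noise_spec: tuple | None = None
    seed: int | None = None


def fig6_fixture(case: str):
    """Worked converged-mask contents with known likelihood outcomes.

    Returns ``(theta_map, footprint, target, bn)`` with Bn = 49:

    * ``"a"`` — 49 samples spread exactly one per bin: uniform heights, the
      entropy attains its bound, p = 0.
    * ``"b"`` — 18 samples, 15 in one bin and 3 in the target's bin
      (alpha = 0.2, p ~ 0.178).
    * ``"c"`` — the same 15/3 split but the target sits in the majority bin
      (alpha = 1, p ~ 0.885).
    * ``"d"`` — all samples share the target's bin: p = 1.
    """
    if case not in ("a", "b", "c", "d"):
        raise ConfigurationError(f"unknown case: {case!r}")
    if case == "a":
        theta = np.full((7, 7), np.nan)
        angles = [bin_center(i, FIG6_BN) for i in range(FIG6_BN)]
        theta.flat[:] = angles
        footprint = np.array([(r, c) for r in range(7) for c in range(7)])
        target = (3, 3)
        return theta, footprint, target, FIG6_BN

    theta = np.full((3, 6), np.nan)
    footprint = np.array([(r, c) for r in range(3) for c in range(6)])
    if case == "d":
        theta[:, :] = _MAJORITY_ANGLE
        target = (1, 2)
        return theta, footprint, target, FIG6_BN

    theta[:, :] = _MAJORITY_ANGLE
    theta[0, :3] = _MINORITY_ANGLE  # the 3 odd-one-out samples
    target = (0, 0) if case == "b" else (1, 2)
    return theta, footprint, target, FIG6_BN


def line_field(
    angle: float,
    shape: tuple[int, int] = (31, 31),
    background: str = "random",
    background_angle: float = 90.0,
    seed: int | None = None,
    thickness: int = 1,
) -> np.ndarray:
    """Orientation field with a line of the given angle planted through the center.

    Pixels on the line (drawn along the level-line direction of ``angle``, so
    the planted orientation is consistent with an actual contour there) carry
    ``angle``; the background is either a constant orientation or uniformly
    random, reproducible from ``seed``.
    """
    if not -90.0 <= angle < 90.0:
        raise ConfigurationError("angle must lie in [-90, 90)")
    rng = np.random.default_rng(seed)
    if background == "random":
        theta = rng.uniform(-90.0, 90.0, size=shape)
    elif background == "constant":
        theta = np.full(shape, ((background_angle + 90.0) % 180.0) - 90.0)
    else:
        raise ConfigurationError(f"unknown background kind: {background!r}")
    for r, c in _line_pixels(angle, shape, thickness):
        theta[r, c] = angle
    return theta


def _line_pixels(angle: float, shape: tuple[int, int], thickness: int = 1):
    """Pixels of a line through the grid center along the level-line direction."""
    from .em_mask import axis_vector

    ur, uc = axis_vector(angle, "printed")
    r0, c0 = shape[0] // 2, shape[1] // 2
    half = max(shape)  # long enough to cross the grid
    pts = set()
    for s in np.linspace(-half, half, 8 * half + 1):
        r, c = r0 + s * ur, c0 + s * uc
        for dt in range(thickness):
            rr = int(round(r + dt * (-uc)))
            cc = int(round(c + dt * ur))
            if 0 <= rr < shape[0] and 0 <= cc < shape[1]:
                pts.add((rr, cc))
    return sorted(pts)


def line_mask(angle: float, shape: tuple[int, int] = (31, 31), thickness: int = 1) -> np.ndarray:
    """Boolean mask of the planted line's pixels."""
    m = np.zeros(shape, dtype=bool)
    for r, c in _line_pixels(angle, shape, thickness):
        m[r, c] = True
    return m


def feature_maps_from_field(
    theta: np.ndarray,
    foreground: np.ndarray | None = None,
    tau: float = 0.5,
    bn: int = 49,
) -> FeatureMaps:
    """Wrap an orientation field as EM feature maps.

    ``foreground`` marks the strong-gradient pixels (assigned to the gestalt
    plane); the rest go to the complement plane, as they would around a real
    contour where the off-contour gradient is weak.  With ``foreground=None``
    the whole field is strong-gradient data and the complement plane is empty.
    """
    theta = np.asarray(theta, dtype=float)
    if foreground is None:
        foreground = np.ones(theta.shape, dtype=bool)
    foreground = np.asarray(foreground, dtype=bool)
    if foreground.shape != theta.shape:
        raise ShapeError("foreground mask shape must match the field")
    theta_tau = np.where(foreground, theta, np.nan)
    theta_bar = np.where(~foreground, theta, np.nan)
    return FeatureMaps(theta_tau=theta_tau, theta_bar_tau=theta_bar, tau=tau, bin_count=bn)


def line_scene(
    angle: float,
    shape: tuple[int, int] = (31, 31),
    background: str = "constant",
    background_angle: float = 90.0,
    seed: int | None = None,
    bn: int = 49,
):
    """Planted-line field packaged for run_em: (maps, target) with the line
    in the strong-gradient plane and the background in the complement plane."""
    theta = line_field(angle, shape, background, background_angle, seed)
    fg = line_mask(angle, shape)
    maps = feature_maps_from_field(theta, foreground=fg, bn=bn)
    target = (shape[0] // 2, shape[1] // 2)
    return maps, target


def shape_scene(
    spec: list[dict],
    size: tuple[int, int] = (64, 64),
    background: float = 0.25,
    seed: int | None = None,
) -> SyntheticScene:
    """Render filled shapes and construct their exact boundary ground truth.

    Each spec entry is ``{"kind": "square"|"rect"|"disk", ...}`` with
    ``origin``/``side`` (square), ``origin``/``extent`` (rect), or
    ``center``/``radius`` (disk) plus an ``intensity``.  Later shapes occlude
    earlier ones; the ground truth follows the visible region boundaries
    (shape-side pixels whose 4-neighborhood leaves the region).

    A ``{"kind": "texture", "origin", "extent", "amplitude", "scale"}`` entry
    modulates the region with spatially correlated zero-mean texture (smoothed
    white noise rescaled to peak amplitude/2, correlation length ``scale``
    pixels, drawn from ``seed``).  Texture is a surface property, not an
    object: it contributes no ground-truth contour, which is exactly what
    makes its edge responses the false positives the screening stage should
    remove.
    """
    rng = np.random.default_rng(seed)
    image = np.full(size, float(background))
    labels = np.zeros(size, dtype=int)
    solid = [s for s in spec if s.get("kind", "square") != "texture"]
    textures = [s for s in spec if s.get("kind") == "texture"]
    for i, shape_spec in enumerate(solid, start=1):
        mask = _shape_mask(shape_spec, size)
        image[mask] = float(shape_spec.get("intensity", 1.0))
        labels[mask] = i
    gt = (labels > 0) & _no_wrap_boundary(labels) if solid else np.zeros(size, dtype=bool)
    for tex in textures:
        r0, c0 = tex["origin"]
        h, w = tex["extent"]
        _check_bounds(r0, c0, r0 + h, c0 + w, size)
        amp = float(tex.get("amplitude", 0.8))
        scale = float(tex.get("scale", 1.2))
        from scipy import ndimage as _ndi

        field = _ndi.gaussian_filter(rng.standard_normal((h, w)), scale)
        field = field / np.abs(field).max() * amp / 2.0
        image[r0:r0 + h, c0:c0 + w] += field
    image = np.clip(image, 0.0, 1.0)
    return SyntheticScene(image=image, gt_contours=gt, seed=seed)


def noisy_square_scene(
    seed: int | None = None,
    size: tuple[int, int] = (96, 96),
    side: int = 48,
    contrast: tuple[float, float] = (0.05, 0.95),
    texture_amplitude: float = 0.8,
    impulse_fraction: float = 0.10,
) -> SyntheticScene:
    """The canonical noise-robustness scene: textured square + impulse noise.

    A high-contrast square on a dark background carries a correlated texture
    patch on its interior (inset 10 px from the edges), emulating a textured
    object surface; the whole frame is then corrupted by salt-and-pepper
    impulse noise.  The texture survives a median prefilter and produces
    spurious edge candidates for the screening stage, while the square's
    perimeter is the only ground-truth contour.
    """
    o = (size[0] - side) // 2
    inset = 10
    scene = shape_scene(
        [
            {"kind": "square", "origin": (o, o), "side": side, "intensity": contrast[1]},
            {"kind": "texture", "origin": (o + inset, o + inset),
             "extent": (side - 2 * inset, side - 2 * inset),
             "amplitude": texture_amplitude, "scale": 1.2},
        ],
        size=size,
        background=contrast[0],
        seed=seed,
    )
    noisy = add_noise(scene.image, "impulse", impulse_fraction,
                      seed=None if seed is None else seed + 1000)
    return SyntheticScene(image=noisy, gt_contours=scene.gt_contours,
                          noise_spec=("impulse", impulse_fraction), seed=seed)


def _no_wrap_boundary(labels: np.ndarray) -> np.ndarray:
    """True where some in-bounds 4-neighbor has a different label."""
    out = np.zeros(labels.shape, dtype=bool)
    out[1:, :] |= labels[1:, :] != labels[:-1, :]
    out[:-1, :] |= labels[:-1, :] != labels[1:, :]
    out[:, 1:] |= labels[:, 1:] != labels[:, :-1]
    out[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    return out


def _shape_mask(shape_spec: dict, size: tuple[int, int]) -> np.ndarray:
    kind = shape_spec.get("kind", "square")
    mask = np.zeros(size, dtype=bool)
    if kind == "square":
        r0, c0 = shape_spec["origin"]
        s = shape_spec["side"]
        _check_bounds(r0, c0, r0 + s, c0 + s, size)
        mask[r0:r0 + s, c0:c0 + s] = True
    elif kind == "rect":
        r0, c0 = shape_spec["origin"]
        h, w = shape_spec["extent"]
        _check_bounds(r0, c0, r0 + h, c0 + w, size)
        mask[r0:r0 + h, c0:c0 + w] = True
    elif kind == "disk":
        r0, c0 = shape_spec["center"]
        rad = shape_spec["radius"]
        _check_bounds(r0 - rad, c0 - rad, r0 + rad + 1, c0 + rad + 1, size)
        rr, cc = np.ogrid[:size[0], :size[1]]
        mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
    else:
        raise ConfigurationError(f"unknown shape kind: {kind!r}")
    return mask


def _check_bounds(r0, c0, r1, c1, size):
    if r0 < 0 or c0 < 0 or r1 > size[0] or c1 > size[1]:
        raise ShapeError("shape exceeds scene bounds")


def add_noise(image: np.ndarray, kind: str, param: float, seed: int | None = None) -> np.ndarray:
    """Corrupt an image with Gaussian or impulse noise, reproducibly.

    ``gaussian``: zero-mean additive noise of variance ``param`` (e.g. 0.01),
    clipped back to [0, 1].  ``impulse``: exactly round(param * n) pixels are
    replaced by extreme values, half black and half white (salt-and-pepper).
    """
    image = np.asarray(image, dtype=float)
    rng = np.random.default_rng(seed)
    if kind == "gaussian":
        if not 0 < param <= 1:
            raise ConfigurationError("gaussian variance must lie in (0, 1]")
        out = image + rng.normal(0.0, np.sqrt(param), size=image.shape)
        return np.clip(out, 0.0, 1.0)
    if kind == "impulse":
        if not 0 < param <= 1:
            raise ConfigurationError("impulse fraction must lie in (0, 1]")
        n = image.size
        n_hit = int(round(param * n))
        flat = image.copy().ravel()
        idx = rng.choice(n, size=n_hit, replace=False)
        half = n_hit // 2
        flat[idx[:half]] = 0.0
        flat[idx[half:]] = 1.0
        return flat.reshape(image.shape)
    raise ConfigurationError(f"unknown noise kind: {kind!r}")
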