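"""The EM-driven deformable/rotatable sampling mask.

This is the core of the method.  A rectangular mask of constant area budget
``Bn = L x W`` sits on a target edge pixel.  Each iteration it samples the
orientation feature map under its footprint, builds an orientation histogram,
and converts the histogram into a gestalt likelihood

    p = alpha * (H_max - H) / H_max,      alpha = h_T / h_max,

where ``H`` is the Shannon entropy of the bin heights, ``H_max = -log(1/Bn)``
its upper bound, ``h_T`` the height of the target pixel's own bin and ``h_max``
the highest bin.  The second factor (the *directivity*, or entropy deficit)
measures how concentrated the sampled orientations are — evidence of a
principal direction; ``alpha`` weights that evidence by how well the target
itself agrees with it.  A companion mask samples the complement map and yields
the non-gestalt likelihood

    p_bar = beta * H_bar / H_max,         beta = h_bar_min / h_bar_T.

The M-phase turns the likelihood into new mask parameters: the width snaps to
``r (1 - p)`` with ``r = sqrt(Bn)`` (floor when p rose, ceiling when it fell,
never below 1) and the length follows as ``L = Bn / W``, so a confident
principal direction elongates the mask along that direction while a flat
histogram keeps it square.  Rotation aligns the long axis with the maximal
bin's center angle.  Iteration stops when W stabilizes.

The squared residual ``[W - r(1-p)]^2`` averaged over all candidate pixels is
the Lyapunov objective of the scheme; its first-order change
``2 r [W^t - r(1-p^t)] (p^t - p^{t-1})`` is non-positive by the floor/ceiling
choice, which is what stabilizes the integer dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .gradient_features import FeatureMaps

__all__ = [
    "EMConfig",
    "MaskState",
    "OrientationHistogram",
    "TraceStep",
    "ConvergedMask",
    "entropy_upper_bound",
    "axis_vector",
    "rasterize_mask",
    "bin_index",
    "bin_center",
    "angular_distance",
    "orientation_histogram",
    "shannon_entropy",
    "directivity",
    "gestalt_likelihood",
    "nongestalt_likelihood",
    "update_width",
    "update_length",
    "principal_direction",
    "run_em",
    "objective_term",
    "objective_value",
]


@dataclass
class EMConfig:
    """Tunables of the EM loop.

    init_size: initial square mask side (7 for images below ~1024 px).
    bn_mode: "area" sets Bn = init_size**2 (the initialization rule; 49 for a
        7x7 mask, and the value that reproduces the worked likelihood examples);
        "quarter" sets Bn to a quarter of the mask area.
    bar_mode: "mirror" runs the complement mask with its own p_bar-driven
        deformation; "shadow" makes it copy the main mask's geometry.
    max_iter: hard cap — the Lyapunov argument proves descent, not finite
        termination of the integer width dynamics.
    """

    init_size: int = 7
    bn_mode: str = "area"
    bar_mode: str = "mirror"
    max_iter: int = 50
    convention: str = "printed"

    def __post_init__(self) -> None:
        if self.init_size < 1:
            raise ConfigurationError("init_size must be >= 1")
        if self.bn_mode not in ("area", "quarter"):
            raise ConfigurationError(f"unknown bn_mode: {self.bn_mode!r}")
        if self.bar_mode not in ("mirror", "shadow"):
            raise ConfigurationError(f"unknown bar_mode: {self.bar_mode!r}")

    @property
    def bn(self) -> int:
        area = self.init_size**2
        return area if self.bn_mode == "area" else max(2, round(area / 4))

    @property
    def r(self) -> float:
        return math.sqrt(self.bn)


@dataclass
class MaskState:
    """Deformable rectangle around a target pixel at one EM iteration."""

    center: tuple[int, int]
    t: int = 0
    L: float = 7.0
    W: int = 7
    phi: float = 0.0
    p: float = 0.0
    p_bar: float = 0.0
    bn: int = 49

    @property
    def r(self) -> float:
        return math.sqrt(self.bn)


@dataclass
class OrientationHistogram:
    """Normalized orientation-bin heights under a mask footprint.

    Heights sum to 1 over the non-null sampled pixels (all zero when nothing
    was sampled).  ``target_bin`` is the bin of the target pixel's raw
    orientation; it is bookkept even when its height is zero.
    """

    heights: np.ndarray
    n_samples: int
    target_bin: int | None

    @property
    def h_T(self) -> float:
        if self.target_bin is None:
            return 0.0
        return float(self.heights[self.target_bin])

    @property
    def h_max(self) -> float:
        return float(self.heights.max()) if self.heights.size else 0.0

    @property
    def h_min_pos(self) -> float:
        """Minimum height among occupied bins (0 if no samples)."""
        occ = self.heights[self.heights > 0]
        return float(occ.min()) if occ.size else 0.0


@dataclass
class TraceStep:
    """Per-iteration record: geometry, likelihoods, and objective bookkeeping.

    ``term`` is the squared residual [W - r(1-p)]^2 of the Lyapunov objective;
    ``delta_e`` is its first-order change 2r [W - r(1-p)] (p - p_prev), the
    quantity proven non-positive by the width update's floor/ceiling choice.
    """

    t: int
    L: float
    W: int
    phi: float
    p: float
    p_bar: float
    term: float
    delta_e: float

    def as_record(self) -> dict:
        return {
            "t": self.t, "L": self.L, "W": self.W, "phi": self.phi,
            "p": self.p, "p_bar": self.p_bar, "term": self.term, "delta_e": self.delta_e,
        }


@dataclass
class ConvergedMask:
    """Outcome of the EM loop for one target pixel."""

    state: MaskState
    footprint: np.ndarray
    principal_direction: float | None
    p_c: float
    p_bar_c: float
    trace: list[TraceStep] = field(default_factory=list)
    converged: bool = True
    degenerate_target: bool = False


def entropy_upper_bound(bn: int) -> float:
    """Maximal Shannon entropy of a Bn-bin histogram, -log(1/Bn) in nats."""
    if bn < 1:
        raise ConfigurationError("bin count must be >= 1")
    return -math.log(1.0 / bn)


def axis_vector(phi: float, convention: str = "printed") -> tuple[float, float]:
    """Unit (row, col) vector of the mask's long axis for orientation ``phi``.

    The long axis runs along the level line, perpendicular to the gradient.
    Under the "printed" convention (theta = arctan(g_x/g_y)) the gradient unit
    vector is (cos phi, sin phi) in (row, col), so the level line is
    (-sin phi, cos phi); the "standard" convention swaps the roles.
    """
    a = math.radians(phi)
    if convention == "printed":
        return (-math.sin(a), math.cos(a))
    if convention == "standard":
        return (math.cos(a), -math.sin(a))
    raise ConfigurationError(f"unknown orientation convention: {convention!r}")


def rasterize_mask(
    center: tuple[int, int],
    L: float,
    W: float,
    phi: float,
    shape: tuple[int, int],
    convention: str = "printed",
) -> np.ndarray:
    """Pixels whose centers fall inside the rotated L x W rectangle.

    Returns an (N, 2) int array of (row, col) coordinates clipped to the image
    bounds; the target pixel itself is always included.
    """
    r0, c0 = center
    ur, uc = axis_vector(phi, convention)  # long axis
    vr, vc = -uc, ur  # short axis (gradient direction)
    radius = int(math.ceil(math.hypot(L, W) / 2.0))
    rows = np.arange(max(0, r0 - radius), min(shape[0], r0 + radius + 1))
    cols = np.arange(max(0, c0 - radius), min(shape[1], c0 + radius + 1))
    dr = (rows - r0)[:, None]
    dc = (cols - c0)[None, :]
    u = dr * ur + dc * uc
    v = dr * vr + dc * vc
    inside = (np.abs(u) <= L / 2.0 + 1e-9) & (np.abs(v) <= W / 2.0 + 1e-9)
    rr, cc = np.nonzero(inside)
    pts = np.column_stack([rows[rr], cols[cc]])
    if not ((pts[:, 0] == r0) & (pts[:, 1] == c0)).any():
        pts = np.vstack([pts, [r0, c0]])
    return pts


def bin_index(angle: float, bn: int) -> int:
    """Bin of an axial angle on [-90, 90) with -90 identified with 90."""
    a = ((angle + 90.0) % 180.0) - 90.0
    idx = int((a + 90.0) // (180.0 / bn))
    return min(idx, bn - 1)


def bin_center(idx: int, bn: int) -> float:
    return -90.0 + (idx + 0.5) * (180.0 / bn)


def angular_distance(a: float, b: float) -> float:
    """Axial angular distance (period 180 degrees)."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def orientation_histogram(
    theta_map: np.ndarray,
    footprint: np.ndarray,
    bn: int,
    target_theta: float,
) -> OrientationHistogram:
    """Histogram the non-null orientations sampled under the footprint.

    Bins are uniform over [-90, 90), width 180/Bn.  The target bin comes from
    the target's raw orientation even if that pixel is null in ``theta_map``;
    it is None when the target orientation itself is undefined.
    """
    samples = theta_map[footprint[:, 0], footprint[:, 1]]
    samples = samples[~np.isnan(samples)]
    heights = np.zeros(bn)
    if samples.size:
        wrapped = ((samples + 90.0) % 180.0) - 90.0
        idx = np.minimum(((wrapped + 90.0) // (180.0 / bn)).astype(int), bn - 1)
        counts = np.bincount(idx, minlength=bn)
        heights = counts / samples.size
    target_bin = None if np.isnan(target_theta) else bin_index(float(target_theta), bn)
    return OrientationHistogram(heights=heights, n_samples=int(samples.size), target_bin=target_bin)


def shannon_entropy(hist: OrientationHistogram) -> float:
    """Shannon entropy -sum h log h in nats; zero-height bins contribute 0.

    An empty-sample histogram is defined to have H = 0.
    """
    h = hist.heights[hist.heights > 0]
    if h.size == 0:
        return 0.0
    return float(-np.sum(h * np.log(h)))


def directivity(hist: OrientationHistogram, bn: int) -> float:
    """Normalized entropy deficit (H_max - H)/H_max of the bin heights.

    Computed as KL(h || uniform)/log(Bn), which is the same quantity but exact
    in the two corner cases: 0 at exactly uniform heights, 1 at a single
    occupied bin.  Clamped to [0, 1].
    """
    if bn <= 1:
        return 0.0
    h = hist.heights[hist.heights > 0]
    if h.size == 0:
        return 0.0
    kl = float(np.sum(h * np.log(h * bn)))
    return min(1.0, max(0.0, kl / math.log(bn)))


def gestalt_likelihood(hist: OrientationHistogram, bn: int) -> float:
    """p = (h_T / h_max) * (H_max - H)/H_max, the gestalt-class likelihood.

    Degenerate cases (no samples, empty maximal bin, undefined target bin)
    yield 0.
    """
    if hist.n_samples == 0 or hist.target_bin is None:
        return 0.0
    h_max = hist.h_max
    if h_max == 0:
        return 0.0
    alpha = hist.h_T / h_max
    return float(alpha * directivity(hist, bn))


def nongestalt_likelihood(hist_bar: OrientationHistogram, bn: int) -> float:
    """p_bar = (h_bar_min / h_bar_T) * H_bar / H_max, the complement likelihood.

    High when the complement-map orientations around the target are spread out
    (noise-like) and the target's own bin is not privileged among them.
    Degenerate cases (no samples, empty target bin) yield 0.
    """
    if hist_bar.n_samples == 0 or hist_bar.target_bin is None:
        return 0.0
    h_t = hist_bar.h_T
    if h_t == 0:
        return 0.0
    beta = hist_bar.h_min_pos / h_t
    h_max_bound = entropy_upper_bound(bn)
    if h_max_bound == 0:
        return 0.0
    value = beta * shannon_entropy(hist_bar) / h_max_bound
    return float(min(1.0, max(0.0, value)))


def update_width(p_t: float, p_prev: float, r: float) -> int:
    """Snap the mask width to r(1-p): floor when p rose, ceiling when it fell.

    The floor/ceiling choice is what makes the Lyapunov change non-positive;
    the result is clamped to [1, ceil(r)].
    """
    x = r * (1.0 - p_t)
    if p_t >= p_prev:
        w = math.floor(x)
    else:
        w = math.ceil(x)
    if w <= 1:
        return 1
    return min(w, math.ceil(r))


def update_length(bn: int, W: int) -> float:
    """L = Bn / W; keeps the area budget L*W = Bn exact (L may be fractional)."""
    return bn / W


def principal_direction(hist: OrientationHistogram, prev_phi: float | None = None) -> float | None:
    """Center angle of the maximal bin; None for an empty histogram.

    Ties go to the bin angularly closest to ``prev_phi`` (modulo 180), or to
    the lowest index when no previous direction exists.
    """
    if hist.n_samples == 0:
        return None
    h_max = hist.heights.max()
    ties = np.nonzero(hist.heights == h_max)[0]
    bn = hist.heights.size
    if prev_phi is None or ties.size == 1:
        return bin_center(int(ties[0]), bn)
    best = min(ties, key=lambda i: (angular_distance(bin_center(int(i), bn), prev_phi), i))
    return bin_center(int(best), bn)


def objective_term(W: float, p: float, r: float) -> float:
    """Per-target squared residual [W - r(1-p)]^2 of the Lyapunov objective."""
    return (W - r * (1.0 - p)) ** 2


def objective_value(terms, n_cep: int) -> float:
    """Mean of per-target residual terms over the candidate set."""
    if n_cep <= 0:
        raise ConfigurationError("n_cep must be positive")
    return float(np.sum(terms) / n_cep)


def _run_single_mask(
    target: tuple[int, int],
    theta_map: np.ndarray,
    target_theta: float,
    likelihood,
    config: EMConfig,
    geometry_trace: list[TraceStep] | None = None,
) -> tuple[MaskState, np.ndarray, float | None, list[TraceStep], bool]:
    """Drive one mask (main or complement) to W-stability.

    ``likelihood`` maps (histogram, Bn) to the value driving the width update.
    If ``geometry_trace`` is given the mask shadows that geometry instead of
    deforming on its own, and only the likelihood is tracked.
    """
    bn, r = config.bn, config.r
    shape = theta_map.shape
    state = MaskState(center=target, L=float(config.init_size), W=config.init_size, bn=bn)
    trace: list[TraceStep] = []
    footprint = rasterize_mask(target, state.L, state.W, state.phi, shape, config.convention)
    direction: float | None = None
    p_prev = 0.0
    converged = False
    w_history = [state.W]
    osc_candidate: tuple[float, MaskState, np.ndarray] | None = None

    n_iter = len(geometry_trace) if geometry_trace is not None else config.max_iter
    for t in range(1, n_iter + 1):
        if geometry_trace is not None:
            g = geometry_trace[t - 1]
            state = MaskState(center=target, t=t, L=g.L, W=g.W, phi=g.phi, bn=bn)
        footprint = rasterize_mask(target, state.L, state.W, state.phi, shape, config.convention)
        hist = orientation_histogram(theta_map, footprint, bn, target_theta)
        p_t = likelihood(hist, bn)

        if geometry_trace is not None:
            state.p = p_t
            trace.append(TraceStep(t, state.L, state.W, state.phi, p_t, 0.0,
                                   objective_term(state.W, p_t, r), 0.0))
            p_prev = p_t
            converged = True
            continue

        w_new = update_width(p_t, p_prev, r)
        l_new = update_length(bn, w_new)
        term = objective_term(w_new, p_t, r)
        delta_e = 2.0 * r * (w_new - r * (1.0 - p_t)) * (p_t - p_prev)
        new_dir = principal_direction(hist, prev_phi=state.phi if t > 1 else None)
        phi_new = state.phi if new_dir is None else new_dir
        trace.append(TraceStep(t, l_new, w_new, phi_new, p_t, 0.0, term, delta_e))

        stable = w_new == state.W
        state = MaskState(center=target, t=t, L=l_new, W=w_new, phi=phi_new, p=p_t, bn=bn)
        direction = new_dir if new_dir is not None else direction
        if stable:
            converged = True
            break
        # period-2 width oscillation: keep the visited state with the larger p
        w_history.append(w_new)
        if len(w_history) >= 4 and w_history[-1] == w_history[-3] and w_history[-2] == w_history[-4]:
            if osc_candidate is None or p_t > osc_candidate[0]:
                osc_candidate = (p_t, state, footprint)
            if len(w_history) >= 6 and w_history[-1] == w_history[-5]:
                p_t, state, footprint = osc_candidate
                direction = state.phi
                converged = True
                break
        p_prev = p_t

    final_footprint = rasterize_mask(target, state.L, state.W, state.phi, shape, config.convention)
    return state, final_footprint, direction, trace, converged


def run_em(
    target: tuple[int, int],
    maps: FeatureMaps,
    config: EMConfig | None = None,
) -> ConvergedMask:
    """Run the full EM loop for one candidate pixel and return its converged mask.

    The main mask samples ``theta_tau`` with the gestalt likelihood driving its
    deformation; the complement mask samples ``theta_bar_tau`` driven by the
    non-gestalt likelihood (or shadowing the main geometry, per config).  A
    target whose own orientation is undefined returns immediately with zero
    likelihoods and the ``degenerate_target`` flag set.
    """
    config = config or EMConfig()
    if maps.bin_count != config.bn:
        raise ConfigurationError(
            f"feature maps built with Bn={maps.bin_count} but config implies Bn={config.bn}"
        )
    rows, cols = maps.shape
    if not (0 <= target[0] < rows and 0 <= target[1] < cols):
        raise ConfigurationError(f"target {target} outside image bounds {maps.shape}")

    target_theta = maps.theta_at(target)
    if np.isnan(target_theta):
        state = MaskState(center=target, L=float(config.init_size), W=config.init_size,
                          bn=config.bn)
        fp = rasterize_mask(target, state.L, state.W, state.phi, maps.shape, config.convention)
        return ConvergedMask(state=state, footprint=fp, principal_direction=None,
                             p_c=0.0, p_bar_c=0.0, trace=[], converged=True,
                             degenerate_target=True)

    state, footprint, direction, trace, converged = _run_single_mask(
        target, maps.theta_tau, target_theta, gestalt_likelihood, config
    )
    if config.bar_mode == "mirror":
        bar_state, _, _, bar_trace, bar_conv = _run_single_mask(
            target, maps.theta_bar_tau, target_theta, nongestalt_likelihood, config
        )
    else:
        bar_state, _, _, bar_trace, bar_conv = _run_single_mask(
            target, maps.theta_bar_tau, target_theta, nongestalt_likelihood, config,
            geometry_trace=trace,
        )
    for step, bar_step in zip(trace, bar_trace):
        step.p_bar = bar_step.p
    state.p_bar = bar_state.p

    return ConvergedMask(
        state=state,
        footprint=footprint,
        principal_direction=direction if direction is not None else state.phi,
        p_c=state.p,
        p_bar_c=bar_state.p,
        trace=trace,
        converged=converged and bar_conv,
    )
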