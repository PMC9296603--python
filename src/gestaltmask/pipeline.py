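"""End-to-end contour extraction: CEP screening by the EM mask + Bayes rule.

For every candidate edge pixel the EM mask converges to a pair of class
likelihoods (p_c, p_bar_c).  With the normalized gradient magnitude gN as the
prior for the gestalt class, the posterior is

    p(Omega | x, y) = p_c gN / (p_c gN + p_bar_c (1 - gN)),

and the pixel is kept iff the posterior reaches the decision threshold ``k``
(default 0.5, the Bayes minimum-error cut).  Pixels under an accepted mask's
footprint that share the target's orientation bin are aligned with it on the
same line or curve; they are co-labeled gestalt directly and skipped — the
continuity-law shortcut.  Every candidate therefore ends exactly one of
accepted, rejected, or co-labeled, and the output is always a subset of the
candidate set: the method screens, it never adds edges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import cep as cep_mod
from .em_mask import ConvergedMask, EMConfig, bin_index, run_em
from .errors import ConfigurationError
from .gradient_features import (
    FeatureMaps,
    build_feature_maps,
    compute_gradient_field,
    prefilter,
    select_tau,
)

__all__ = [
    "PipelineConfig",
    "PipelineStats",
    "MaskRecord",
    "ContourResult",
    "posterior",
    "classify",
    "co_label",
    "extract_contours",
]


@dataclass
class PipelineConfig:
    """All knobs of the extractor, mirroring the CLI flags."""

    ht: float = 0.2
    lt_ratio: float = 0.4
    sigma: float = math.sqrt(2.0)
    k: float = 0.5
    mask_size: int = 7
    bn_mode: str = "area"
    bar_mode: str = "mirror"
    prefilter: str = "gaussian"
    prefilter_param: float | None = None
    tau_mode: str = "median"
    operator: str = "sobel"
    convention: str = "printed"
    max_iter: int = 50
    normalize_thresholds: bool = True

    def em_config(self) -> EMConfig:
        return EMConfig(init_size=self.mask_size, bn_mode=self.bn_mode,
                        bar_mode=self.bar_mode, max_iter=self.max_iter,
                        convention=self.convention)


@dataclass
class PipelineStats:
    processed: int = 0
    co_labeled: int = 0
    accepted: int = 0
    rejected: int = 0

    @property
    def total(self) -> int:
        return self.accepted + self.rejected + self.co_labeled


@dataclass
class MaskRecord:
    """Converged-mask summary stored for each accepted pixel (the matrix C)."""

    row: int
    col: int
    phi: float
    L: float
    W: int
    p_c: float

    def as_row(self) -> tuple:
        return (self.row, self.col, self.phi, self.L, self.W, self.p_c)


@dataclass
class ContourResult:
    gestalt_map: np.ndarray
    posterior_map: np.ndarray
    mask_store: list[MaskRecord] = field(default_factory=list)
    stats: PipelineStats = field(default_factory=PipelineStats)
    cep: cep_mod.CandidateSet | None = None
    tau: float | None = None
    traces: dict = field(default_factory=dict)


def posterior(p_c: float, p_bar_c: float, gn_xy: float) -> tuple[float, float]:
    """Bayes posterior pair (p(Omega|x,y), p(Omega_bar|x,y)).

    gN acts as the gestalt-class prior.  A vanishing denominator (both
    weighted likelihoods zero) classifies non-gestalt: (0, 1).
    """
    num = p_c * gn_xy
    num_bar = p_bar_c * (1.0 - gn_xy)
    denom = num + num_bar
    if denom == 0:
        return 0.0, 1.0
    return num / denom, num_bar / denom


def classify(p_omega: float, k: float = 0.5) -> bool:
    """Gestalt iff the posterior reaches the threshold (inclusive)."""
    if not 0.4 <= k <= 0.9:
        warnings.warn(f"decision threshold k={k} outside the usual [0.4, 0.9] range")
    return p_omega >= k


def co_label(cm: ConvergedMask, maps: FeatureMaps, target: tuple[int, int]) -> set:
    """Footprint pixels aligned with an accepted target's orientation bin.

    Alignment means the pixel's strong-gradient orientation falls in the same
    bin as the target's — the two points lie on the same line or curve.  The
    target itself is excluded.
    """
    target_theta = maps.theta_at(target)
    if np.isnan(target_theta):
        return set()
    t_bin = bin_index(float(target_theta), maps.bin_count)
    out = set()
    for r, c in cm.footprint:
        if (r, c) == tuple(target):
            continue
        v = maps.theta_tau[r, c]
        if not np.isnan(v) and bin_index(float(v), maps.bin_count) == t_bin:
            out.add((int(r), int(c)))
    return out


def extract_contours(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    external_cep: cep_mod.CandidateSet | None = None,
    keep_traces: bool = False,
) -> ContourResult:
    """Run the full extractor on a grayscale image.

    Candidates are processed in raster order; co-labeled pixels are removed
    from the queue on the fly, which makes the run deterministic for a fixed
    configuration.  An empty candidate set returns an empty result with a
    warning.
    """
    config = config or PipelineConfig()
    image = np.asarray(image, dtype=float)

    filtered = prefilter(image, config.prefilter, config.prefilter_param)
    candidates = cep_mod.canny_cep(
        filtered, high=config.ht, low=config.lt_ratio * config.ht,
        sigma=config.sigma, normalize_thresholds=config.normalize_thresholds,
    )
    if external_cep is not None:
        candidates = cep_mod.union_cep(candidates, external_cep)

    gestalt = np.zeros(image.shape, dtype=bool)
    post_map = np.full(image.shape, np.nan)
    result = ContourResult(gestalt_map=gestalt, posterior_map=post_map, cep=candidates)
    if len(candidates) == 0:
        warnings.warn("empty candidate edge set; nothing to extract")
        return result

    fld = compute_gradient_field(filtered, config.operator, config.convention)
    try:
        tau = select_tau(fld.gN, config.tau_mode, mask=fld.theta_defined)
    except ConfigurationError:
        raise
    em_cfg = config.em_config()
    maps = build_feature_maps(fld, tau, em_cfg.bn)
    result.tau = tau

    status: dict[tuple[int, int], str] = {}
    stats = result.stats
    for px in candidates.sorted_pixels():
        if px in status:
            continue
        theta_px = maps.theta_at(px)
        if np.isnan(theta_px):
            status[px] = "rejected"
            stats.rejected += 1
            post_map[px] = 0.0
            continue
        cm = run_em(px, maps, em_cfg)
        stats.processed += 1
        p_omega, _ = posterior(cm.p_c, cm.p_bar_c, float(fld.gN[px]))
        post_map[px] = p_omega
        if keep_traces:
            result.traces[px] = cm.trace
        if classify(p_omega, config.k):
            status[px] = "accepted"
            stats.accepted += 1
            gestalt[px] = True
            result.mask_store.append(MaskRecord(px[0], px[1], float(cm.state.phi),
                                                float(cm.state.L), int(cm.state.W),
                                                float(cm.p_c)))
            for q in co_label(cm, maps, px):
                if q in candidates and q not in status:
                    status[q] = "co_labeled"
                    stats.co_labeled += 1
                    gestalt[q] = True
        else:
            status[px] = "rejected"
            stats.rejected += 1

    assert stats.total == len(candidates), "every candidate must be labeled exactly once"
    return result
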