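"""Distance-tolerant edge-map evaluation: Pratt's FoM, EQ/MQ, screening rate.

Hand-sketched ground-truth contours are displaced by a pixel or two from the
true intensity edges, so strict pixel equality is meaningless.  All counts here
are tolerant: a detected pixel (DP) counts as a true positive when its
Euclidean distance to the nearest ground-truth (GT) pixel is at most ``d0``
(1..5 px); a GT pixel with no detection within ``d0`` is a false negative.

    EQ    = TP / (TP + FP)                       (precision of the detections)
    MQ    = TP / (n_GT + FP)                     (map quality)
    MQ_f1 = TP / (TP + 0.5 (FP + FN))            (the F1 form of MQ)
    FoM   = 1/max(n_DP, n_GT) * sum_DP 1 / (1 + (d/d0)^2)
    sR    = (n_CEP - n_DT) / n_CEP * 100         (screening rate, %)

The working-zone diagnostic flags |MQ - EQ| <= 0.2 with MQ >= 0.5 — the
operating region in which at least half the ground truth is guaranteed present
in the output (the "Half-GT" rule of thumb).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, ShapeError

__all__ = [
    "EvalReport",
    "tolerant_match",
    "pratt_fom",
    "eq_mq",
    "screening_rate",
    "evaluate",
    "pr_sweep",
]


@dataclass
class EvalReport:
    """Bundle of tolerant counts and the derived quality metrics."""

    d0: int
    TP: int
    FP: int
    FN: int
    EQ: float
    MQ: float
    MQ_f1: float
    FoM: float
    sR: float | None = None

    @property
    def in_working_zone(self) -> bool:
        """Half-GT diagnostic: |MQ - EQ| <= 0.2 with MQ >= 0.5."""
        if np.isnan(self.MQ) or np.isnan(self.EQ):
            return False
        return abs(self.MQ - self.EQ) <= 0.2 and self.MQ >= 0.5


def _as_bool_map(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 2:
        raise ShapeError(f"expected a 2-D binary map, got ndim={m.ndim}")
    return m.astype(bool)


def _distances_to(mask: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean distance to the nearest True pixel (inf if none)."""
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask)


def tolerant_match(dp: np.ndarray, gt: np.ndarray, d0: int = 1) -> tuple[int, int, int]:
    """Count (TP, FP, FN) with distance tolerance ``d0`` (inclusive).

    Matching is one-sided: every DP pixel within ``d0`` of GT is a TP (no
    one-to-one assignment), every other DP pixel an FP, and every GT pixel
    without a DP pixel within ``d0`` an FN.
    """
    if not 1 <= int(d0) <= 5:
        raise ConfigurationError("d0 must be an integer in 1..5")
    dp, gt = _as_bool_map(dp), _as_bool_map(gt)
    if dp.shape != gt.shape:
        raise ShapeError(f"shape mismatch: {dp.shape} vs {gt.shape}")
    d_to_gt = _distances_to(gt)
    d_to_dp = _distances_to(dp)
    tp = int(np.count_nonzero(dp & (d_to_gt <= d0)))
    fp = int(np.count_nonzero(dp)) - tp
    fn = int(np.count_nonzero(gt & (d_to_dp > d0)))
    return tp, fp, fn


def pratt_fom(dp: np.ndarray, gt: np.ndarray, d0: int = 1) -> float:
    """Pratt's figure of merit with kernel 1/(1 + (d/d0)^2).

    ``d`` is each detected pixel's distance-transform distance to the ground
    truth; the prefactor 1/max(n_DP, n_GT) penalizes both over- and
    under-detection.  Empty DP returns 0 by convention; GT must be non-empty.
    """
    if not 1 <= int(d0) <= 5:
        raise ConfigurationError("d0 must be an integer in 1..5")
    dp, gt = _as_bool_map(dp), _as_bool_map(gt)
    if dp.shape != gt.shape:
        raise ShapeError(f"shape mismatch: {dp.shape} vs {gt.shape}")
    n_gt = int(np.count_nonzero(gt))
    if n_gt == 0:
        raise ConfigurationError("ground truth is empty")
    n_dp = int(np.count_nonzero(dp))
    if n_dp == 0:
        return 0.0
    d = _distances_to(gt)[dp]
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / max(n_dp, n_gt))


def eq_mq(tp: int, fp: int, fn: int, n_gt: int) -> tuple[float, float, float]:
    """Edge quality, map quality, and the F1 form of map quality.

    Zero denominators yield NaN (undefined), never 0.
    """
    if min(tp, fp, fn, n_gt) < 0:
        raise ConfigurationError("counts must be non-negative")
    eq = tp / (tp + fp) if tp + fp > 0 else float("nan")
    mq = tp / (n_gt + fp) if n_gt + fp > 0 else float("nan")
    denom = tp + 0.5 * (fp + fn)
    mq_f1 = tp / denom if denom > 0 else float("nan")
    return eq, mq, mq_f1


def screening_rate(n_cep: int, n_dt: int) -> float:
    """Percentage of candidate pixels removed by the classifier."""
    if n_cep <= 0:
        raise ConfigurationError("screening rate undefined for an empty candidate set")
    if not 0 <= n_dt <= n_cep:
        raise ConfigurationError("retained count must lie in [0, n_cep]")
    return (n_cep - n_dt) / n_cep * 100.0


def evaluate(dp: np.ndarray, gt: np.ndarray, d0: int = 1,
             n_cep: int | None = None) -> EvalReport:
    """Full tolerant evaluation of a detected map against ground truth."""
    tp, fp, fn = tolerant_match(dp, gt, d0)
    eq, mq, mq_f1 = eq_mq(tp, fp, fn, int(np.count_nonzero(np.asarray(gt).astype(bool))))
    fom = pratt_fom(dp, gt, d0)
    sr = None
    if n_cep is not None and n_cep > 0:
        sr = screening_rate(n_cep, int(np.count_nonzero(np.asarray(dp).astype(bool))))
    return EvalReport(d0=int(d0), TP=tp, FP=fp, FN=fn, EQ=eq, MQ=mq, MQ_f1=mq_f1,
                      FoM=fom, sR=sr)


def pr_sweep(scenes, ht_values, k_values, d0: int = 1, config=None):
    """Precision/recall over a grid of Canny high thresholds and decision cuts.

    ``scenes`` is an iterable of objects with ``image`` and ``gt_contours``
    attributes (e.g. :class:`gestaltmask.synthetic.SyntheticScene`).  For each
    (H_t, k) pair the full pipeline runs on every scene; precision (= EQ) and
    recall = TP/(TP+FN) are averaged over scenes.  Returns a list of dicts
    with keys ht, k, precision, recall.
    """
    from dataclasses import replace

    from .pipeline import PipelineConfig, extract_contours

    base = config or PipelineConfig()
    scenes = list(scenes)
    if not scenes:
        raise ConfigurationError("at least one scene with ground truth is required")
    points = []
    for ht in ht_values:
        for k in k_values:
            cfg = replace(base, ht=float(ht), k=float(k))
            precisions, recalls = [], []
            for scene in scenes:
                result = extract_contours(scene.image, cfg)
                tp, fp, fn = tolerant_match(result.gestalt_map, scene.gt_contours, d0)
                precisions.append(tp / (tp + fp) if tp + fp else np.nan)
                recalls.append(tp / (tp + fn) if tp + fn else np.nan)
            points.append({
                "ht": float(ht), "k": float(k),
                "precision": float(np.nanmean(precisions)),
                "recall": float(np.nanmean(recalls)),
            })
    return points
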