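"""Detection and segmentation metrics.

Detection quality is scored by matching detected centroids to ground-truth
blob centers within a distance threshold ``d`` (by default the average blob
diameter of the ground truth).  To avoid double counting, the number of true
positives is the smaller of (i) the number of ground-truth centers whose
nearest candidate lies within ``d`` and (ii) the number of candidates whose
nearest ground-truth center lies within ``d``; a greedy nearest-first
one-to-one matching is also produced for per-blob auditing and coincides
with that count on sparse instances.

Segmentation quality uses voxel overlap (Dice, IoU); counting error uses the
absolute relative difference of object counts (DER).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .identify import DetectionResult
from .phantom import Phantom

__all__ = [
    "MatchingConfig",
    "MetricsReport",
    "der",
    "match_detections",
    "precision_recall_fscore",
    "dice_iou",
    "average_blob_diameter",
    "evaluate_run",
    "aggregate_reports",
]


@dataclass
class MatchingConfig:
    """Distance threshold (voxels) for center matching."""

    distance: float

    def __post_init__(self) -> None:
        if not self.distance > 0:
            raise ValueError(f"matching distance must be positive, got {self.distance}")


@dataclass
class MetricsReport:
    """All evaluation metrics for one volume."""

    der: float
    tp: int
    m: int  # ground-truth blob count
    n: int  # detected candidate count
    precision: float
    recall: float
    f_score: float
    dice: float
    iou: float
    mean_blobness: float
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "der": self.der, "tp": self.tp, "m": self.m, "n": self.n,
            "precision": self.precision, "recall": self.recall,
            "f_score": self.f_score, "dice": self.dice, "iou": self.iou,
            "mean_blobness": self.mean_blobness, "flags": list(self.flags),
        }


def der(n_ground_truth: int, n_detected: int) -> float:
    """Detection error rate: |N_GT - N_det| / N_GT."""
    if n_ground_truth <= 0:
        raise ValueError("DER is undefined for zero ground-truth blobs")
    return abs(n_ground_truth - n_detected) / n_ground_truth


def _pairwise_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)


def match_detections(
    gt_centers: np.ndarray,
    det_centroids: np.ndarray,
    config: MatchingConfig,
) -> tuple[int, list[tuple[int, int]]]:
    """True-positive count and greedy matched (gt_index, det_index) pairs.

    TP is the min-construction described in the module docstring; the greedy
    pairs come from scanning candidate-GT pairs by ascending distance (ties
    broken by candidate then GT index) and accepting a pair only when both
    endpoints are still unmatched.
    """
    gt = np.asarray(gt_centers, dtype=float).reshape(-1, 3)
    det = np.asarray(det_centroids, dtype=float).reshape(-1, 3)
    if not (np.all(np.isfinite(gt)) and np.all(np.isfinite(det))):
        raise ValueError("non-finite coordinates in matching input")
    if gt.shape[0] == 0 or det.shape[0] == 0:
        return 0, []
    dmat = _pairwise_distances(gt, det)  # (m, n)
    d = config.distance

    gt_hit = int(np.count_nonzero(dmat.min(axis=1) <= d))
    det_hit = int(np.count_nonzero(dmat.min(axis=0) <= d))
    tp = min(gt_hit, det_hit)

    # Greedy one-to-one pairs (deterministic, permutation-invariant order).
    gi, di = np.nonzero(dmat <= d)
    order = np.lexsort((gi, di, dmat[gi, di]))
    used_gt: set[int] = set()
    used_det: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for k in order:
        g, c = int(gi[k]), int(di[k])
        if g in used_gt or c in used_det:
            continue
        used_gt.add(g)
        used_det.add(c)
        pairs.append((g, c))
    return tp, pairs


def precision_recall_fscore(tp: int, m: int, n: int) -> tuple[float, float, float]:
    """Precision = TP/n, recall = TP/m, F = harmonic mean (0 when degenerate)."""
    if m <= 0:
        raise ValueError("recall undefined for zero ground-truth blobs")
    if n < 0 or tp < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / n if n > 0 else 0.0
    recall = tp / m
    denom = precision + recall
    f_score = 2.0 * precision * recall / denom if denom > 0 else 0.0
    return precision, recall, f_score


def dice_iou(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[float, float]:
    """Dice and IoU overlap of two binary volumes (1, 1 when both empty)."""
    a = np.asarray(mask_a) > 0
    b = np.asarray(mask_b) > 0
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(a & b))
    sa, sb = int(np.count_nonzero(a)), int(np.count_nonzero(b))
    union = sa + sb - inter
    if sa == 0 and sb == 0:
        return 1.0, 1.0
    dice = 2.0 * inter / (sa + sb)
    iou = inter / union if union else 1.0
    return dice, iou


def average_blob_diameter(phantom: Phantom) -> float:
    """Average ground-truth blob diameter: 2 x mean of all per-axis sigmas.

    The e^(-1) level set of each Gaussian is the ellipsoid with semi-axes
    equal to the sigmas, so 2*sigma is the corresponding axis diameter.
    """
    sig = np.array([b.sigmas for b in phantom.blobs], dtype=float)
    return float(2.0 * sig.mean())


def evaluate_run(
    detections: DetectionResult,
    phantom: Phantom,
    config: MatchingConfig | None = None,
) -> MetricsReport:
    """Score one detection result against a phantom's ground truth."""
    if detections.mask.shape != phantom.mask.shape:
        raise ValueError(
            f"volume frames differ: detection {detections.mask.shape} vs "
            f"phantom {phantom.mask.shape}"
        )
    if config is None:
        config = MatchingConfig(distance=average_blob_diameter(phantom))
    flags: list[str] = []
    m = phantom.n_blobs
    n = detections.count
    tp, _ = match_detections(phantom.centers, detections.centroids, config)
    tp = min(tp, m, n)
    precision, recall, f_score = precision_recall_fscore(tp, m, n)
    if n == 0:
        flags.append("no_detections:precision_set_to_0")
    dice, iou = dice_iou(detections.mask, phantom.mask)
    scores = detections.table["blobness"].to_numpy(dtype=float)
    mean_blobness = float(np.nanmean(scores)) if np.isfinite(scores).any() else float("nan")
    return MetricsReport(
        der=der(m, n), tp=tp, m=m, n=n,
        precision=precision, recall=recall, f_score=f_score,
        dice=dice, iou=iou, mean_blobness=mean_blobness, flags=flags,
    )


def aggregate_reports(reports: list[MetricsReport]) -> pd.DataFrame:
    """Mean +/- std of each metric across per-image reports."""
    if not reports:
        raise ValueError("no reports to aggregate")
    df = pd.DataFrame([r.to_dict() for r in reports]).drop(columns=["flags"])
    return df.agg(["mean", "std"])
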