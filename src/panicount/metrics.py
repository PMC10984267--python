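"""Counting and detection quality metrics.

Counting accuracy is scored with RMSE and the coefficient of determination
R^2 over per-image (manual, predicted) count pairs. Detection quality uses
precision/recall matching at an IoU threshold, average precision AP@k with
101-point precision–recall interpolation, and the mean AP over the IoU
thresholds 0.50, 0.55, …, 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .boxes import DetectionSet, ScoredBox, iou

__all__ = [
    "CountPair",
    "MatchResult",
    "EvalSummary",
    "rmse",
    "r_squared",
    "match_detections",
    "average_precision",
    "map_50_95",
    "evaluate_detections",
    "MAP_THRESHOLDS",
]

MAP_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class CountPair:
    """Manual count ``y`` and predicted count ``y_hat`` for one test image."""

    y: int
    y_hat: int

    def __post_init__(self) -> None:
        if self.y < 0 or self.y_hat < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class MatchResult:
    """Greedy prediction-to-ground-truth matching at one IoU threshold."""

    is_tp: np.ndarray  # bool, one per prediction, in descending-score order
    scores: np.ndarray  # matching descending order
    n_gt: int

    @property
    def n_tp(self) -> int:
        return int(self.is_tp.sum())

    @property
    def n_fp(self) -> int:
        return int((~self.is_tp).sum())

    @property
    def n_fn(self) -> int:
        return self.n_gt - self.n_tp

    @property
    def precision(self) -> float:
        n = self.is_tp.size
        return self.n_tp / n if n else 0.0

    @property
    def recall(self) -> float:
        return self.n_tp / self.n_gt if self.n_gt else 0.0


@dataclass
class EvalSummary:
    """Aggregate evaluation of a detector run."""

    rmse: float
    r2: float
    ap_by_threshold: dict[float, float]
    map_50_95: float


def rmse(pairs: Sequence[CountPair]) -> float:
    """Root mean squared error of predicted vs manual counts."""
    if not pairs:
        raise ValueError("rmse needs at least one count pair")
    d = np.array([p.y - p.y_hat for p in pairs], dtype=float)
    return float(np.sqrt(np.mean(d * d)))


def r_squared(pairs: Sequence[CountPair]) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (may be negative)."""
    if len(pairs) < 2:
        raise ValueError("r_squared needs at least two count pairs")
    y = np.array([p.y for p in pairs], dtype=float)
    yhat = np.array([p.y_hat for p in pairs], dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("manual counts are all identical; R^2 undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def match_detections(
    preds: DetectionSet, gts: DetectionSet, iou_k: float
) -> MatchResult:
    """Match predictions to ground truth greedily by descending score.

    Each prediction claims the unmatched ground-truth box with the highest
    IoU, provided that IoU is at least ``iou_k`` (a true positive);
    otherwise it is a false positive. Each ground truth is matched at most
    once. Equal-IoU ties go to the lower ground-truth index.
    """
    order = sorted(
        range(len(preds.boxes)), key=lambda i: (-preds.boxes[i].score, i)
    )
    gt_taken = [False] * len(gts.boxes)
    is_tp = np.zeros(len(order), dtype=bool)
    scores = np.array([preds.boxes[i].score for i in order], dtype=float)
    for rank, pi in enumerate(order):
        best_iou, best_gi = 0.0, -1
        for gi, gt in enumerate(gts.boxes):
            if gt_taken[gi]:
                continue
            v = iou(preds.boxes[pi], gt)
            if v > best_iou:  # strict: ties keep the lower index
                best_iou, best_gi = v, gi
        if best_gi >= 0 and best_iou >= iou_k:
            is_tp[rank] = True
            gt_taken[best_gi] = True
    return MatchResult(is_tp=is_tp, scores=scores, n_gt=len(gts.boxes))


def average_precision(match: MatchResult, n_points: int = 101) -> float:
    """Area under the precision–recall curve, 101-point interpolation.

    Precision at each recall level r in {0, 0.01, …, 1} is the maximum
    precision attained at recall >= r; AP is the mean over levels.
    """
    if match.n_gt == 0:
        raise ValueError("average precision undefined with no ground truth")
    if match.is_tp.size == 0 or match.n_tp == 0:
        return 0.0
    tp_cum = np.cumsum(match.is_tp)
    ranks = np.arange(1, match.is_tp.size + 1)
    precision = tp_cum / ranks
    recall = tp_cum / match.n_gt
    # precision envelope: max precision at recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    levels = np.linspace(0.0, 1.0, n_points)
    # tolerance so a recall level of e.g. 0.3 accepts a recall of 3/10 despite
    # one-ulp float differences between linspace levels and count ratios
    idx = np.searchsorted(recall, levels - 1e-10, side="left")
    ap = np.where(idx < recall.size, env[np.minimum(idx, recall.size - 1)], 0.0)
    return float(ap.mean())


def map_50_95(
    preds: DetectionSet,
    gts: DetectionSet,
    thresholds: Sequence[float] = MAP_THRESHOLDS,
    divisor: int | None = None,
) -> float:
    """Mean AP over IoU thresholds 0.50:0.05:0.95.

    ``divisor`` defaults to the number of thresholds (the standard
    convention); pass an explicit value to reproduce a different
    normalisation.
    """
    total = sum(
        average_precision(match_detections(preds, gts, k)) for k in thresholds
    )
    return total / (divisor if divisor is not None else len(thresholds))


def evaluate_detections(
    preds_by_image: dict[str, DetectionSet],
    gts_by_image: dict[str, DetectionSet],
    count_pairs: Sequence[CountPair] | None = None,
) -> EvalSummary:
    """Pool detections across images and summarise all metrics.

    Matching runs per image (a prediction can only match ground truth in its
    own image); TP/FP flags are pooled by score for the AP computation.
    Count pairs default to per-image (n_gt, n_pred).
    """
    images = sorted(gts_by_image)
    if count_pairs is None:
        count_pairs = [
            CountPair(
                y=len(gts_by_image[im]),
                y_hat=len(preds_by_image.get(im, DetectionSet())),
            )
            for im in images
        ]
    ap_by: dict[float, float] = {}
    for k in MAP_THRESHOLDS:
        flags, scores, n_gt = [], [], 0
        for im in images:
            m = match_detections(
                preds_by_image.get(im, DetectionSet()), gts_by_image[im], k
            )
            flags.append(m.is_tp)
            scores.append(m.scores)
            n_gt += m.n_gt
        scores_all = np.concatenate(scores) if scores else np.empty(0)
        flags_all = np.concatenate(flags) if flags else np.empty(0, bool)
        order = np.argsort(-scores_all, kind="stable")
        pooled = MatchResult(
            is_tp=flags_all[order], scores=scores_all[order], n_gt=n_gt
        )
        ap_by[k] = average_precision(pooled)
    return EvalSummary(
        rmse=rmse(count_pairs),
        r2=r_squared(count_pairs),
        ap_by_threshold=ap_by,
        map_50_95=float(np.mean(list(ap_by.values()))),
    )
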