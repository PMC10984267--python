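"""Scored bounding boxes, detection sets, IoU and greedy NMS.

Boxes are axis-aligned, in pixel units, half-open: a box occupies
``[x_min, x_max) x [y_min, y_max)``. All detections carry a single implicit
class ("panicle"); suppression and matching are class-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = ["Frame", "ScoredBox", "DetectionSet", "iou", "nms"]


class Frame(str, Enum):
    """Coordinate frame a detection set lives in."""

    TILE = "tile"
    PLOT = "plot"


@dataclass(frozen=True)
class ScoredBox:
    """A single detection: box corners plus a confidence score in [0, 1]."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    score: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def translate(self, dx: float, dy: float) -> "ScoredBox":
        return ScoredBox(
            self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy,
            self.score,
        )

    def clip(self, width: float, height: float) -> Optional["ScoredBox"]:
        """Clip to ``[0, width) x [0, height)``; None if nothing remains."""
        x0, y0 = max(self.x_min, 0.0), max(self.y_min, 0.0)
        x1, y1 = min(self.x_max, width), min(self.y_max, height)
        if x0 >= x1 or y0 >= y1:
            return None
        return ScoredBox(x0, y0, x1, y1, self.score)


@dataclass
class DetectionSet:
    """An ordered collection of scored boxes in a declared frame.

    ``source_tile`` identifies the tile a tile-frame set came from (set by the
    tiling workflow; ``None`` for plot-frame sets).
    """

    boxes: list[ScoredBox] = field(default_factory=list)
    frame: Frame = Frame.PLOT
    source_tile: Optional[object] = None  # tiles.Tile; untyped to avoid a cycle

    def __len__(self) -> int:
        return len(self.boxes)

    def __iter__(self) -> Iterator[ScoredBox]:
        return iter(self.boxes)

    def scores(self) -> np.ndarray:
        return np.array([b.score for b in self.boxes], dtype=float)

    def as_array(self) -> np.ndarray:
        """(n, 5) array of [x_min, y_min, x_max, y_max, score]."""
        if not self.boxes:
            return np.empty((0, 5), dtype=float)
        return np.array(
            [[b.x_min, b.y_min, b.x_max, b.y_max, b.score] for b in self.boxes],
            dtype=float,
        )

    @classmethod
    def from_array(
        cls, arr: np.ndarray, frame: Frame = Frame.PLOT
    ) -> "DetectionSet":
        boxes = [ScoredBox(*row[:4], score=row[4]) for row in np.asarray(arr, float)]
        return cls(boxes=boxes, frame=frame)


def iou(a: ScoredBox, b: ScoredBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def _nms_order(boxes: Sequence[ScoredBox]) -> list[int]:
    # descending score; ties broken by larger area, then input order
    return sorted(
        range(len(boxes)),
        key=lambda i: (-boxes[i].score, -boxes[i].area, i),
    )


def nms(dets: DetectionSet, iou_threshold: float) -> DetectionSet:
    """Greedy non-maximum suppression.

    Boxes are visited in descending score order (ties: larger area first, then
    input order); each kept box suppresses every remaining box whose IoU with
    it exceeds ``iou_threshold``. Kept boxes are an unmodified subset of the
    input, returned in the input's original order.
    """
    if dets.frame is not Frame.PLOT:
        raise ValueError("nms expects a plot-frame detection set")
    boxes = dets.boxes
    if not boxes:
        return DetectionSet(boxes=[], frame=dets.frame)

    order = _nms_order(boxes)
    arr = dets.as_array()
    x0, y0, x1, y1 = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
    areas = (x1 - x0) * (y1 - y0)

    suppressed = np.zeros(len(boxes), dtype=bool)
    keep: list[int] = []
    for idx in order:
        if suppressed[idx]:
            continue
        keep.append(idx)
        ix = np.minimum(x1, x1[idx]) - np.maximum(x0, x0[idx])
        iy = np.minimum(y1, y1[idx]) - np.maximum(y0, y0[idx])
        inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
        ious = inter / (areas + areas[idx] - inter)
        suppressed |= ious > iou_threshold
        suppressed[idx] = True  # kept, but no longer a candidate

    keep.sort()
    return DetectionSet(boxes=[boxes[i] for i in keep], frame=dets.frame)
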