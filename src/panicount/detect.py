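"""Detector contract and the deterministic reference blob detector.

The prediction workflow is detector-agnostic: anything exposing
``detect(tile) -> DetectionSet`` (tile frame, scores in [0, 1], already
deduplicated at the model's internal NMS IoU) can fill the contract — a
trained network wrapper, a file of pre-computed detections, or the built-in
colour-threshold blob detector used as the oracle on synthetic imagery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from skimage.measure import label, regionprops

from .boxes import DetectionSet, Frame, ScoredBox
from .locate import RgbImage

__all__ = [
    "Detector",
    "BlobDetectorConfig",
    "BlobDetector",
    "reference_blob_detect",
]


@runtime_checkable
class Detector(Protocol):
    """Contract every detection backend fulfils."""

    name: str
    conf_threshold: float  # backend's internal score floor
    nms_iou: float  # backend's internal NMS IoU

    def detect(self, tile: RgbImage) -> DetectionSet: ...


@dataclass(frozen=True)
class BlobDetectorConfig:
    """Colour-threshold settings for the reference detector.

    Panicles in synthetic scenes are rendered in a bright straw tone distinct
    from foliage and soil; a pixel is panicle-coloured when R >= ``min_red``,
    G >= ``min_green`` and B <= ``max_blue``. Components with bounding-box
    area outside [``min_area``, ``max_area``] px^2 are discarded.

    ``ignore_border`` drops components whose box touches the tile boundary:
    with a 25% tile overlap, every blob narrower than the overlap lies
    strictly inside at least one tile, so each is still reported — once per
    containing tile, as the identical plot-frame box — and merge-NMS removes
    the duplicates exactly. Partial border detections, by contrast, can
    overlap the whole-blob detection too little for NMS to catch.
    """

    min_red: int = 200
    min_green: int = 170
    max_blue: int = 190
    min_area: float = 20.0
    max_area: float = 4000.0
    fixed_score: float = 0.9
    ignore_border: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_area < self.max_area:
            raise ValueError("require 0 < min_area < max_area")
        if not 0.0 <= self.fixed_score <= 1.0:
            raise ValueError("fixed_score outside [0, 1]")


def reference_blob_detect(
    tile: RgbImage, cfg: BlobDetectorConfig = BlobDetectorConfig()
) -> DetectionSet:
    """Detect panicle-coloured blobs in one tile.

    Thresholds the panicle colour band, labels 8-connected components, and
    emits each surviving component's bounding box at the configured fixed
    score. Deterministic: identical tiles give identical detection sets,
    ordered by component label (top-left first).
    """
    px = tile.pixels
    if tile.channel_order.value == "BGR":
        px = px[..., ::-1]
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    panicle = (r >= cfg.min_red) & (g >= cfg.min_green) & (b <= cfg.max_blue)

    boxes: list[ScoredBox] = []
    h, w = panicle.shape
    for region in regionprops(label(panicle, connectivity=2)):
        y0, x0, y1, x1 = region.bbox  # half-open
        if cfg.ignore_border and (x0 == 0 or y0 == 0 or x1 == w or y1 == h):
            continue
        area = (x1 - x0) * (y1 - y0)
        if not cfg.min_area <= area <= cfg.max_area:
            continue
        boxes.append(
            ScoredBox(float(x0), float(y0), float(x1), float(y1), cfg.fixed_score)
        )
    return DetectionSet(boxes=boxes, frame=Frame.TILE)


@dataclass
class BlobDetector:
    """Reference detector object fulfilling the backend contract."""

    cfg: BlobDetectorConfig = BlobDetectorConfig()
    name: str = "reference-blob"
    conf_threshold: float = 0.0
    nms_iou: float = 0.5

    def detect(self, tile: RgbImage) -> DetectionSet:
        return reference_blob_detect(tile, self.cfg)
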