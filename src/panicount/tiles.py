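"""Tiling of plot images and merging of per-tile detections.

Large plot crops are split into detector-sized square tiles. Annotation uses
non-overlapping tiles (overlap 0); prediction uses a 25% overlap so objects
cut by one tile boundary are seen whole by a neighbour. Per-tile detections
are lifted into plot coordinates and deduplicated with greedy NMS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .boxes import DetectionSet, Frame, ScoredBox, nms

__all__ = [
    "Tile",
    "make_tiles",
    "to_global",
    "merge_tile_detections",
    "count_panicles",
    "DEFAULT_TILE_SIZE",
    "DEFAULT_OVERLAP_RATIO",
    "DEFAULT_CONF_THRESHOLD",
    "DEFAULT_MERGE_IOU",
]

DEFAULT_TILE_SIZE = 1000
DEFAULT_OVERLAP_RATIO = 0.25
DEFAULT_CONF_THRESHOLD = 0.3
DEFAULT_MERGE_IOU = 0.25


@dataclass(frozen=True)
class Tile:
    """A square (by default) sub-window of a plot image, plot coordinates."""

    x0: int
    y0: int
    size_x: int = DEFAULT_TILE_SIZE
    size_y: int = DEFAULT_TILE_SIZE


def _axis_offsets(extent: int, tile: int, stride: int) -> list[int]:
    offsets = list(range(0, extent - tile + 1, stride))
    if offsets[-1] != extent - tile:
        offsets.append(extent - tile)  # clamp final tile to the edge
    return offsets


def make_tiles(
    plot_w: int,
    plot_h: int,
    tile: int = DEFAULT_TILE_SIZE,
    overlap_ratio: float = DEFAULT_OVERLAP_RATIO,
) -> list[Tile]:
    """Tile a ``plot_w`` x ``plot_h`` image with square tiles.

    Stride is ``round(tile * (1 - overlap_ratio))``; offsets advance by the
    stride and the final offset on each axis is clamped to ``extent - tile``
    so the last tile aligns with the image edge (no padding). Full coverage
    is guaranteed.
    """
    if tile > plot_w or tile > plot_h:
        raise ValueError(f"tile {tile} larger than plot {plot_w}x{plot_h}")
    if not 0 <= overlap_ratio < 1:
        raise ValueError(f"overlap_ratio {overlap_ratio} outside [0, 1)")
    stride = max(1, round(tile * (1.0 - overlap_ratio)))
    xs = _axis_offsets(plot_w, tile, stride)
    ys = _axis_offsets(plot_h, tile, stride)
    return [Tile(x0=x, y0=y, size_x=tile, size_y=tile) for y in ys for x in xs]


def to_global(det: DetectionSet, tile: Tile, plot_w: int, plot_h: int) -> DetectionSet:
    """Lift a tile-frame detection set into plot coordinates.

    Boxes are translated by the tile origin and clipped to the plot extent.
    """
    if det.frame is not Frame.TILE:
        raise ValueError("to_global expects a tile-frame detection set")
    lifted: list[ScoredBox] = []
    for box in det.boxes:
        moved = box.translate(tile.x0, tile.y0)
        clipped = moved.clip(plot_w, plot_h)
        if clipped is not None:
            lifted.append(clipped)
    return DetectionSet(boxes=lifted, frame=Frame.PLOT)


def merge_tile_detections(
    per_tile: Sequence[DetectionSet],
    plot_w: int,
    plot_h: int,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
    merge_iou: float = DEFAULT_MERGE_IOU,
) -> DetectionSet:
    """Merge per-tile detections into one plot-level set.

    All sets are lifted to the plot frame, boxes below ``conf_threshold`` are
    dropped, and greedy NMS at ``merge_iou`` removes cross-tile duplicates.
    """
    boxes: list[ScoredBox] = []
    for det in per_tile:
        if det.frame is not Frame.TILE:
            raise ValueError("merge_tile_detections expects tile-frame sets")
        if det.source_tile is None:
            raise ValueError("detection set lacks its source tile")
        lifted = to_global(det, det.source_tile, plot_w, plot_h)
        boxes.extend(b for b in lifted.boxes if b.score >= conf_threshold)
    return nms(DetectionSet(boxes=boxes, frame=Frame.PLOT), merge_iou)


def count_panicles(dets: DetectionSet) -> int:
    """Panicle count of a plot = cardinality of its merged detection set."""
    if dets.frame is not Frame.PLOT:
        raise ValueError("count_panicles expects a plot-frame detection set")
    return len(dets)
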