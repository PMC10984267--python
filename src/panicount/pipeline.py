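"""End-to-end orchestration: locate → tile → detect → merge → count → traits.

One frame per (plot_id, date). Each frame is processed independently —
a failure on one frame is recorded and the run continues — and per-plot
counts are assembled into growth curves from which the trait table is built.
All stage parameters are captured in a structured run log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Union

import pandas as pd

from .boxes import DetectionSet
from .config import PipelineConfig
from .detect import BlobDetector, Detector
from .locate import PlotWindow, RgbImage, binarize_vegetation, compute_cive, crop_plot, locate_plot
from .tiles import count_panicles, make_tiles, merge_tile_detections
from .traits import DateLike, build_growth_curves, traits_table

__all__ = ["FrameResult", "PipelineResult", "process_frame", "run_pipeline"]

logger = logging.getLogger("panicount")


@dataclass
class FrameResult:
    """Outcome of one frame: window, merged detections, count — or an error."""

    plot_id: str
    date: DateLike
    window: Optional[PlotWindow] = None
    detections: Optional[DetectionSet] = None
    count: Optional[int] = None
    error: Optional[str] = None


@dataclass
class PipelineResult:
    """Per-frame results plus the assembled trait table."""

    frames: list[FrameResult]
    traits: pd.DataFrame
    config: PipelineConfig

    @property
    def failures(self) -> list[FrameResult]:
        return [f for f in self.frames if f.error is not None]


def _make_backend(config: PipelineConfig) -> Detector:
    if config.backend == "reference-blob":
        return BlobDetector()
    raise ValueError(
        f"unknown backend {config.backend!r}; pass a Detector object instead"
    )


def process_frame(
    image: RgbImage, config: PipelineConfig, backend: Optional[Detector] = None
) -> tuple[PlotWindow, DetectionSet, int]:
    """Run the single-frame workflow and return (window, detections, count)."""
    backend = backend or _make_backend(config)
    mask = binarize_vegetation(compute_cive(image))
    window = locate_plot(
        mask,
        height=config.plot_height,
        width=config.plot_width,
        smooth_window=config.smooth_window,
    )
    plot = crop_plot(image, window)
    tiles = make_tiles(
        plot_w=window.width,
        plot_h=window.height,
        tile=config.tile_size,
        overlap_ratio=config.overlap_ratio,
    )
    per_tile = []
    for tile in tiles:
        sub = RgbImage(
            pixels=plot.pixels[
                tile.y0 : tile.y0 + tile.size_y, tile.x0 : tile.x0 + tile.size_x
            ],
            channel_order=plot.channel_order,
        )
        det = backend.detect(sub)
        det.source_tile = tile
        per_tile.append(det)
    merged = merge_tile_detections(
        per_tile,
        plot_w=window.width,
        plot_h=window.height,
        conf_threshold=config.conf_threshold,
        merge_iou=config.merge_iou,
    )
    return window, merged, count_panicles(merged)


def run_pipeline(
    frames: Iterable[tuple[str, DateLike, Union[RgbImage, Callable[[], RgbImage]]]],
    config: PipelineConfig = PipelineConfig(),
    backend: Optional[Detector] = None,
) -> PipelineResult:
    """Process frames keyed by (plot_id, date) into a trait table.

    ``frames`` yields (plot_id, date, image) triples; the image entry may be
    a zero-argument callable (lazy loader) so large campaigns need not be
    held in memory. Per-frame failures are isolated: the failing frame gets
    an ``error`` entry and its plot simply lacks that date in its curve.
    """
    backend = backend or _make_backend(config)
    logger.info("pipeline start: config=%s", config.to_dict())
    results: list[FrameResult] = []
    for plot_id, date, image in frames:
        fr = FrameResult(plot_id=plot_id, date=date)
        try:
            img = image() if callable(image) else image
            window, merged, n = process_frame(img, config, backend)
            fr.window, fr.detections, fr.count = window, merged, n
            logger.info(
                "frame plot=%s date=%s window=(%d,%d) count=%d",
                plot_id, date, window.row0, window.col0, n,
            )
        except Exception as exc:  # isolate per-frame failures
            fr.error = f"{type(exc).__name__}: {exc}"
            logger.error("frame plot=%s date=%s failed: %s", plot_id, date, fr.error)
        results.append(fr)

    ok = [(f.plot_id, f.date, f.count) for f in results if f.error is None]
    if ok:
        curves = build_growth_curves(ok)
        for pid in list(curves):
            if len(curves[pid]) < 2:  # traits need >= 2 dates
                logger.warning("plot %s has < 2 usable dates; no traits", pid)
                del curves[pid]
        table = traits_table(
            curves, fractions=config.fractions, monotonize=config.monotonize
        )
    else:
        table = traits_table({})
    return PipelineResult(frames=results, traits=table, config=config)
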