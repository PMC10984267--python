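"""Central-plot extraction from aerial frames.

A frame is centered on one field plot but covers a larger area including
neighbouring plots and the bare-soil lanes between them. The plot is located
by (1) mapping each pixel to the Color Index of Vegetation Extraction
(CIVE = 0.441 R - 0.811 G + 0.385 B + 18.78754; green vegetation minimises
it), (2) Otsu-binarising the index so vegetation pixels become "white",
(3) counting white pixels per row and per column and smoothing the profiles
with a moving average, and (4) sliding a fixed-size window so that its two
boundary rows (and columns) fall on the profile minima — the soil lanes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Literal

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "ChannelOrder",
    "RgbImage",
    "CiveMap",
    "VegetationMask",
    "PixelProfile",
    "PlotWindow",
    "compute_cive",
    "binarize_vegetation",
    "white_pixel_profile",
    "locate_plot",
    "crop_plot",
]

# CIVE coefficients (R, G, B) and offset
_CIVE_R, _CIVE_G, _CIVE_B, _CIVE_C = 0.441, -0.811, 0.385, 18.78754

DEFAULT_PLOT_HEIGHT = 2000
DEFAULT_PLOT_WIDTH = 3800
DEFAULT_SMOOTH_WINDOW = 100


class ChannelOrder(str, Enum):
    RGB = "RGB"
    BGR = "BGR"


@dataclass
class RgbImage:
    """An 8-bit colour frame with a declared channel order."""

    pixels: np.ndarray  # (H, W, 3) uint8
    channel_order: ChannelOrder = ChannelOrder.RGB

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) image, got {self.pixels.shape}")
        if not isinstance(self.channel_order, ChannelOrder):
            self.channel_order = ChannelOrder(self.channel_order)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class CiveMap:
    """Per-pixel CIVE values for a frame."""

    values: np.ndarray  # (H, W) float64


@dataclass
class VegetationMask:
    """Boolean vegetation map: True where CIVE <= the Otsu threshold.

    ``degenerate`` flags a constant-valued index map, for which no threshold
    separates two classes; the mask is then all-False.
    """

    mask: np.ndarray  # (H, W) bool
    otsu_threshold: float
    degenerate: bool = False


@dataclass
class PixelProfile:
    """White-pixel counts per row or per column, raw and smoothed."""

    axis: Literal["row", "column"]
    raw_counts: np.ndarray  # int
    smoothed: np.ndarray  # float


@dataclass(frozen=True)
class PlotWindow:
    """Axis-aligned crop window, 0-based, half-open on both axes."""

    row0: int
    col0: int
    height: int = DEFAULT_PLOT_HEIGHT
    width: int = DEFAULT_PLOT_WIDTH

    def iou(self, other: "PlotWindow") -> float:
        iy = min(self.row0 + self.height, other.row0 + other.height) - max(
            self.row0, other.row0
        )
        ix = min(self.col0 + self.width, other.col0 + other.width) - max(
            self.col0, other.col0
        )
        if ix <= 0 or iy <= 0:
            return 0.0
        inter = ix * iy
        union = self.height * self.width + other.height * other.width - inter
        return inter / union


def compute_cive(image: RgbImage) -> CiveMap:
    """CIVE index per pixel: 0.441 R - 0.811 G + 0.385 B + 18.78754."""
    px = image.pixels.astype(np.float64)
    if image.channel_order is ChannelOrder.RGB:
        r, g, b = px[..., 0], px[..., 1], px[..., 2]
    elif image.channel_order is ChannelOrder.BGR:
        b, g, r = px[..., 0], px[..., 1], px[..., 2]
    else:  # pragma: no cover - enum exhausted
        raise ValueError(f"unknown channel order {image.channel_order!r}")
    return CiveMap(values=_CIVE_R * r + _CIVE_G * g + _CIVE_B * b + _CIVE_C)


def binarize_vegetation(cive: CiveMap) -> VegetationMask:
    """Otsu-threshold the CIVE map; vegetation = pixels at or below threshold.

    Otsu's criterion is histogram-based, so the continuous index is affinely
    rescaled to [0, 255], binned into 256 integer levels, thresholded, and the
    threshold mapped back to CIVE units. Greener pixels have *lower* CIVE, so
    the vegetation class is the low side of the threshold.
    """
    values = cive.values
    if not np.all(np.isfinite(values)):
        raise ValueError("CIVE map contains non-finite values")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        return VegetationMask(
            mask=np.zeros(values.shape, dtype=bool),
            otsu_threshold=float("nan"),
            degenerate=True,
        )
    scaled = np.round((values - vmin) * (255.0 / (vmax - vmin))).astype(np.uint8)
    t_scaled = threshold_otsu(scaled, nbins=256)
    threshold = vmin + float(t_scaled) * (vmax - vmin) / 255.0
    return VegetationMask(mask=values <= threshold, otsu_threshold=threshold)


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge windows truncated to valid range.

    For even ``window`` the center is taken to sit between samples, so index i
    averages ``x[i - window//2 + 1 : i + window//2 + 1]`` intersected with the
    array.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    before = (window - 1) // 2  # samples taken before i
    after = window // 2  # samples taken after i
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(idx - before, 0)
    hi = np.minimum(idx + after + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def white_pixel_profile(
    mask: VegetationMask,
    axis: Literal["row", "column"],
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> PixelProfile:
    """Count vegetation pixels per row or per column and smooth the counts."""
    m = mask.mask
    if m.size == 0:
        raise ValueError("empty mask")
    if axis == "row":
        raw = m.sum(axis=1)
    elif axis == "column":
        raw = m.sum(axis=0)
    else:
        raise ValueError(f"axis must be 'row' or 'column', got {axis!r}")
    raw = raw.astype(np.int64)
    return PixelProfile(
        axis=axis, raw_counts=raw, smoothed=moving_average(raw, smooth_window)
    )


TIE_TOLERANCE_FRACTION = 0.01


def _boundary_argmin(smoothed: np.ndarray, extent: int,
                     tie_frac: float = TIE_TOLERANCE_FRACTION) -> int:
    """Placement minimising smoothed[i] + smoothed[i + extent - 1].

    Near-tied placements break to the lower-median tied index: frames are
    centered on their plot, so the middle of a flat cost valley is the
    natural representative. When the window height equals the inter-lane
    pitch the valley floor is flat up to pixel noise, so placements within
    ``tie_frac`` of the cost range above the minimum count as tied (noise on
    a profile averaged over the smoothing window sits far below the valley
    depth, while the lane slopes clear the band within a pixel or two).
    """
    n = smoothed.size
    if extent > n:
        raise ValueError(f"window extent {extent} exceeds profile length {n}")
    cost = smoothed[: n - extent + 1] + smoothed[extent - 1 :]
    cmin = cost.min()
    tol = tie_frac * float(cost.max() - cmin) + 1e-9 * max(abs(cmin), 1.0)
    tied = np.flatnonzero(cost <= cmin + tol)
    return int(tied[(len(tied) - 1) // 2])


def locate_plot(
    mask: VegetationMask,
    height: int = DEFAULT_PLOT_HEIGHT,
    width: int = DEFAULT_PLOT_WIDTH,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> PlotWindow:
    """Find the window whose boundary rows/columns hold fewest white pixels.

    ``row0`` minimises ``smoothed_row[i] + smoothed_row[i + height - 1]`` over
    all in-bounds placements; ``col0`` likewise with the column profile.
    """
    H, W = mask.mask.shape
    if H < height or W < width:
        raise ValueError(
            f"image {H}x{W} smaller than plot window {height}x{width}"
        )
    rows = white_pixel_profile(mask, "row", smooth_window)
    cols = white_pixel_profile(mask, "column", smooth_window)
    return PlotWindow(
        row0=_boundary_argmin(rows.smoothed, height),
        col0=_boundary_argmin(cols.smoothed, width),
        height=height,
        width=width,
    )


def crop_plot(image: RgbImage, window: PlotWindow) -> RgbImage:
    """Copy the window's pixels out of the frame."""
    H, W = image.height, image.width
    if (
        window.row0 < 0
        or window.col0 < 0
        or window.row0 + window.height > H
        or window.col0 + window.width > W
    ):
        raise ValueError(f"window {window} outside image {H}x{W}")
    crop = image.pixels[
        window.row0 : window.row0 + window.height,
        window.col0 : window.col0 + window.width,
    ].copy()
    return RgbImage(pixels=crop, channel_order=image.channel_order)
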