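"""Seeded synthetic fixtures: field scenes and logistic count series.

Every pipeline stage gets a download-free oracle. Scenes emulate the
geometry of a drilled paddy trial — a grid of vegetated plots separated by
bare-soil lanes, the frame centered on one plot — with panicles rendered as
bright straw-toned elliptical blobs at recorded positions. Series emulate
logistic panicle-count growth sampled at the flight cadence, with analytic
heading-date truth derived from the noiseless logistic.

Realism is explicitly not the goal: tones are well separated so the
reference blob detector is a clean oracle, and pipeline correctness — not
photorealism — is what the fixtures certify. Generators are pure functions
of (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.draw import ellipse as _ellipse

from .boxes import ScoredBox
from .locate import ChannelOrder, PlotWindow, RgbImage
from .traits import GrowthCurve, TraitRecord

__all__ = [
    "SceneParams",
    "FieldScene",
    "generate_field_scene",
    "SeriesParams",
    "SimulatedSeries",
    "generate_series",
    "logistic_crossing",
]

# Rendered tones (R, G, B): soil lanes, foliage, panicle blobs.
SOIL_TONE = (125, 95, 65)
FOLIAGE_TONE = (65, 125, 55)
PANICLE_TONE = (235, 210, 120)


@dataclass(frozen=True)
class SceneParams:
    """Layout of a synthetic frame, in pixels.

    Defaults are a scaled-down frame keeping the real proportions: a plot of
    600 x 1000 px centered-ish in a 1000 x 1500 px frame, soil lanes of 50 px
    (>= the 40 px the locator is specified against), 25 panicles of 4–8 px
    semi-axes kept >= 20 px apart edge-to-edge and >= 30 px inside the plot
    boundary.
    """

    image_height: int = 1000
    image_width: int = 1500
    plot_height: int = 600
    plot_width: int = 1000
    gap: int = 50
    n_panicles: int = 25
    blob_semiaxis_min: float = 4.0
    blob_semiaxis_max: float = 8.0
    min_spacing: float = 20.0  # edge-to-edge, via bounding circles
    blob_margin: int = 30  # clearance inside the plot boundary
    noise_sd: float = 5.0
    edge_strip_min: int = 50  # neighbour-plot strip beyond each lane

    def __post_init__(self) -> None:
        room_h = self.image_height - self.plot_height - 2 * (self.gap + self.edge_strip_min)
        room_w = self.image_width - self.plot_width - 2 * (self.gap + self.edge_strip_min)
        if room_h < 0 or room_w < 0:
            raise ValueError("plot + lanes + edge strips do not fit in the frame")


@dataclass
class FieldScene:
    """A rendered frame plus its ground truth."""

    image: RgbImage
    true_plot: PlotWindow
    true_panicles: list[ScoredBox]  # image coordinates, score 1.0
    seed: int

    def panicles_in_plot_frame(self) -> list[ScoredBox]:
        """Ground-truth boxes relative to the true plot origin."""
        return [
            b.translate(-self.true_plot.col0, -self.true_plot.row0)
            for b in self.true_panicles
        ]


def _sample_positions(
    rng: np.random.Generator, params: SceneParams, n: int
) -> list[tuple[float, float, float, float]]:
    """(row, col, semi_r, semi_c) for n non-overlapping blobs, plot coords."""
    lo_r = params.blob_margin + params.blob_semiaxis_max
    hi_r = params.plot_height - params.blob_margin - params.blob_semiaxis_max
    lo_c = params.blob_margin + params.blob_semiaxis_max
    hi_c = params.plot_width - params.blob_margin - params.blob_semiaxis_max
    if hi_r <= lo_r or hi_c <= lo_c:
        raise ValueError("plot too small for blob margins")
    placed: list[tuple[float, float, float, float]] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 200 * max(n, 1):
            raise ValueError(
                f"could not place {n} blobs with spacing {params.min_spacing}"
            )
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        sr = rng.uniform(params.blob_semiaxis_min, params.blob_semiaxis_max)
        sc = rng.uniform(params.blob_semiaxis_min, params.blob_semiaxis_max)
        rad = max(sr, sc)
        ok = all(
            np.hypot(r - r2, c - c2) >= params.min_spacing + rad + max(sr2, sc2)
            for r2, c2, sr2, sc2 in placed
        )
        if ok:
            placed.append((r, c, sr, sc))
    return placed


def generate_field_scene(
    seed: int, params: SceneParams = SceneParams()
) -> FieldScene:
    """Render one frame: soil lanes, vegetated plot and neighbours, blobs.

    The frame is vegetation-toned everywhere except two horizontal and two
    vertical soil lanes bordering the plot; the plot sits at a seeded random
    offset. Panicle blobs are drawn only inside the plot, and their exact
    rendered pixel bounding boxes are recorded as ground truth.
    """
    rng = np.random.default_rng(seed)
    p = params
    H, W = p.image_height, p.image_width

    lo = p.gap + p.edge_strip_min
    r0 = int(rng.integers(lo, H - p.plot_height - lo + 1))
    c0 = int(rng.integers(lo, W - p.plot_width - lo + 1))

    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = FOLIAGE_TONE
    # soil lanes bordering the plot, spanning the full frame
    img[r0 - p.gap : r0, :] = SOIL_TONE
    img[r0 + p.plot_height : r0 + p.plot_height + p.gap, :] = SOIL_TONE
    img[:, c0 - p.gap : c0] = SOIL_TONE
    img[:, c0 + p.plot_width : c0 + p.plot_width + p.gap] = SOIL_TONE

    truth: list[ScoredBox] = []
    for r, c, sr, sc in _sample_positions(rng, p, p.n_panicles):
        rr, cc = _ellipse(r0 + r, c0 + c, sr, sc, shape=(H, W))
        img[rr, cc] = PANICLE_TONE
        truth.append(
            ScoredBox(
                x_min=float(cc.min()),
                y_min=float(rr.min()),
                x_max=float(cc.max() + 1),
                y_max=float(rr.max() + 1),
                score=1.0,
            )
        )

    img += rng.normal(0.0, p.noise_sd, img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return FieldScene(
        image=RgbImage(pixels=pixels, channel_order=ChannelOrder.RGB),
        true_plot=PlotWindow(
            row0=r0, col0=c0, height=p.plot_height, width=p.plot_width
        ),
        true_panicles=truth,
        seed=seed,
    )


def logistic_crossing(r: float, t0: float, fraction: float) -> float:
    """Time at which a logistic K/(1+exp(-r(t-t0))) reaches fraction * K."""
    return t0 + np.log(fraction / (1.0 - fraction)) / r


@dataclass(frozen=True)
class SeriesParams:
    """Logistic growth-curve parameters for one simulated plot.

    Defaults reflect plot-scale panicle counting: plateau counts in the low
    hundreds, heading spread over roughly a week (ln 36 / r days from 10% to
    80%), mid-heading near the middle of a 42-flight campaign, and counting
    noise of ~1.5% of the plateau — the scale of the few-panicle RMSE a tuned
    detector achieves on such plots.
    """

    K: float = 250.0
    r: float = 0.6
    t0: float = 20.0
    n_dates: int = 42
    sigma: Optional[float] = None  # absolute count noise; default 0.015 * K

    def __post_init__(self) -> None:
        if self.K <= 0 or self.r <= 0:
            raise ValueError("require K > 0 and r > 0")
        if self.n_dates < 2:
            raise ValueError("need at least two dates")

    @property
    def noise_sd(self) -> float:
        return 0.015 * self.K if self.sigma is None else self.sigma


@dataclass
class SimulatedSeries:
    """A noisy sampled growth curve plus its analytic truth.

    ``true_traits`` holds the noiseless-logistic trait values; heading dates
    are real-valued crossing times clipped to the sampled range.
    """

    curve: GrowthCurve
    true_traits: TraitRecord
    params: SeriesParams
    seed: int


def generate_series(
    seed: int,
    params: SeriesParams = SeriesParams(),
    plot_id: str = "sim",
) -> SimulatedSeries:
    """Sample a logistic count curve at days 0 .. n_dates-1 with noise.

    counts_t = round(max(0, K / (1 + exp(-r (t - t0))) + eps_t)),
    eps_t ~ Normal(0, sigma). Analytic heading dates are the exact logistic
    crossings t0 + ln(f/(1-f))/r clipped to the sampled day range, and the
    analytic heading stage is their 10%→80% difference, ln(36)/r days when
    no clipping occurs.
    """
    rng = np.random.default_rng(seed)
    p = params
    t = np.arange(p.n_dates)
    clean = p.K / (1.0 + np.exp(-p.r * (t - p.t0)))
    eps = rng.normal(0.0, p.noise_sd, p.n_dates)
    counts = np.round(np.maximum(0.0, clean + eps)).astype(np.int64)
    curve = GrowthCurve(plot_id=plot_id, days=t, counts=counts)

    def hd(f: float) -> float:
        return float(np.clip(logistic_crossing(p.r, p.t0, f), 0, p.n_dates - 1))

    true_traits = TraitRecord(
        plot_id=plot_id,
        max_count=int(round(p.K)),
        hd10=hd(0.10),
        hd30=hd(0.30),
        hd50=hd(0.50),
        hd80=hd(0.80),
        heading_stage=hd(0.80) - hd(0.10),
    )
    return SimulatedSeries(
        curve=curve, true_traits=true_traits, params=p, seed=seed
    )
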