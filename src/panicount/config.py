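"""Pipeline configuration: one object, YAML-loadable, fully logged."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .locate import ChannelOrder

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the locate→detect→count→traits pipeline.

    Defaults are the production values: a 3800 x 2000 px plot window, profile
    smoothing window 100, 1000 px tiles at 25% overlap, prediction confidence
    threshold 0.3, merge NMS IoU 0.25, and heading fractions 10/30/50/80%.
    """

    plot_height: int = 2000
    plot_width: int = 3800
    smooth_window: int = 100
    tile_size: int = 1000
    overlap_ratio: float = 0.25
    conf_threshold: float = 0.3
    merge_iou: float = 0.25
    fractions: tuple[float, ...] = (0.10, 0.30, 0.50, 0.80)
    backend: str = "reference-blob"
    channel_order: ChannelOrder = ChannelOrder.RGB
    monotonize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("overlap_ratio", "conf_threshold", "merge_iou"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not all(0.0 < f <= 1.0 for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")
        self.fractions = tuple(self.fractions)
        if not isinstance(self.channel_order, ChannelOrder):
            self.channel_order = ChannelOrder(self.channel_order)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_order"] = self.channel_order.value
        d["fractions"] = list(self.fractions)
        return d
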