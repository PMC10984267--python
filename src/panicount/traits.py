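"""Growth curves and heading-date trait extraction.

A plot's panicle count over the flight campaign traces a roughly logistic
growth curve. Six traits summarise it: the maximum panicle count, the dates
at which the count first best approximates 10%, 30%, 50% and 80% of that
maximum (the heading dates), and the heading-stage duration — the number of
days between the 10% and 80% heading dates.

The heading date for fraction f is the observed acquisition date x
minimising ``|count(x) - f * max_count|``; ties break to the earliest date
(a stage is "reached" at first attainment). No interpolation between flight
dates is performed by default, so trait resolution is bounded by flight
cadence; optional monotonic (running-maximum) preprocessing is available for
noisy curves but off by default.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "DateLike",
    "GrowthCurve",
    "TraitRecord",
    "DEFAULT_FRACTIONS",
    "build_growth_curves",
    "heading_date",
    "extract_traits",
    "traits_table",
]

DateLike = Union[int, str, _dt.date]

DEFAULT_FRACTIONS: tuple[float, ...] = (0.10, 0.30, 0.50, 0.80)


def _parse_date(d: DateLike) -> tuple[int, Optional[_dt.date]]:
    """Return (ordinal day, calendar date or None for bare day indices)."""
    if isinstance(d, bool):
        raise TypeError(f"invalid date {d!r}")
    if isinstance(d, (int, np.integer)):
        return int(d), None
    if isinstance(d, _dt.datetime):
        d = d.date()
    if isinstance(d, _dt.date):
        return d.toordinal(), d
    if isinstance(d, str):
        s = d.strip()
        if s.lstrip("+-").isdigit():  # bare day index serialised as text
            return int(s), None
        date = _dt.date.fromisoformat(s)
        return date.toordinal(), date
    raise TypeError(f"invalid date {d!r}")


@dataclass
class GrowthCurve:
    """Ordered (date, panicle count) series for one plot.

    Dates are held as integer day ordinals; ``calendar`` is True when they
    came in as ISO dates (and traits are reported back as ISO dates).
    """

    plot_id: str
    days: np.ndarray  # int, strictly increasing
    counts: np.ndarray  # int, >= 0
    calendar: bool = False

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.days.size != self.counts.size:
            raise ValueError("days and counts differ in length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError(f"plot {self.plot_id}: dates not strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError(f"plot {self.plot_id}: negative panicle count")

    def __len__(self) -> int:
        return self.days.size

    def monotonized(self) -> "GrowthCurve":
        """Running-maximum copy (optional preprocessing for noisy curves)."""
        return GrowthCurve(
            plot_id=self.plot_id,
            days=self.days.copy(),
            counts=np.maximum.accumulate(self.counts),
            calendar=self.calendar,
        )

    def _format_day(self, day: int) -> DateLike:
        return _dt.date.fromordinal(int(day)).isoformat() if self.calendar else int(day)


@dataclass
class TraitRecord:
    """The six heading-date-related traits of one plot.

    Heading dates are None when undefined (all-zero curve). ``heading_stage``
    is hd80 - hd10 in days.
    """

    plot_id: str
    max_count: int
    hd10: Optional[DateLike]
    hd30: Optional[DateLike]
    hd50: Optional[DateLike]
    hd80: Optional[DateLike]
    heading_stage: Optional[float]


def build_growth_curves(
    records: Iterable[tuple[str, DateLike, int]]
) -> dict[str, GrowthCurve]:
    """Group (plot_id, date, count) rows into per-plot sorted curves.

    Dates may be integer day indices or ISO-8601 strings/dates (consistently
    per plot). Duplicate (plot_id, date) pairs are rejected.
    """
    per_plot: dict[str, list[tuple[int, Optional[_dt.date], int]]] = {}
    for plot_id, date, count in records:
        day, cal = _parse_date(date)
        per_plot.setdefault(str(plot_id), []).append((day, cal, int(count)))
    curves: dict[str, GrowthCurve] = {}
    for plot_id, rows in per_plot.items():
        rows.sort(key=lambda r: r[0])
        days = [r[0] for r in rows]
        for a, b in zip(days, days[1:]):
            if a == b:
                dup = next(r[1] if r[1] else r[0] for r in rows if r[0] == a)
                raise ValueError(f"duplicate date {dup} for plot {plot_id!r}")
        calendar = rows[0][1] is not None
        curves[plot_id] = GrowthCurve(
            plot_id=plot_id,
            days=np.array(days),
            counts=np.array([r[2] for r in rows]),
            calendar=calendar,
        )
    return curves


def heading_date(curve: GrowthCurve, fraction: float) -> Optional[DateLike]:
    """Date whose count best approximates ``fraction`` of the curve maximum.

    Returns the earliest observed date minimising
    ``|count - fraction * max_count|``; None when the curve is all zero.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    if len(curve) == 0:
        raise ValueError("empty growth curve")
    max_count = int(curve.counts.max())
    if max_count == 0:
        return None
    resid = np.abs(curve.counts.astype(float) - fraction * max_count)
    day = curve.days[int(np.argmin(resid))]  # argmin takes the earliest tie
    return curve._format_day(day)


def extract_traits(
    curve: GrowthCurve,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    monotonize: bool = False,
) -> TraitRecord:
    """Extract the six traits from one growth curve.

    ``fractions`` must contain 0.10 and 0.80 (the heading-stage endpoints).
    An all-zero curve yields max_count 0 and missing heading traits.
    """
    if len(curve) < 2:
        raise ValueError(f"plot {curve.plot_id}: need >= 2 points for traits")
    work = curve.monotonized() if monotonize else curve
    max_count = int(curve.counts.max())  # maximum of the raw counts
    hd: dict[float, Optional[DateLike]] = {
        round(f, 2): heading_date(work, f) for f in fractions
    }
    hd10, hd80 = hd.get(0.10), hd.get(0.80)
    if hd10 is not None and hd80 is not None:
        d10, _ = _parse_date(hd10)
        d80, _ = _parse_date(hd80)
        stage: Optional[float] = float(d80 - d10)
    else:
        stage = None
    return TraitRecord(
        plot_id=curve.plot_id,
        max_count=max_count,
        hd10=hd10,
        hd30=hd.get(0.30),
        hd50=hd.get(0.50),
        hd80=hd.get(0.80),
        heading_stage=stage,
    )


def traits_table(
    curves: Union[dict[str, GrowthCurve], Iterable[GrowthCurve]],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    monotonize: bool = False,
) -> pd.DataFrame:
    """One row of traits per plot; missing traits as NA (empty in CSV)."""
    if isinstance(curves, dict):
        curves = [curves[k] for k in sorted(curves)]
    rows = []
    for curve in curves:
        t = extract_traits(curve, fractions=fractions, monotonize=monotonize)
        rows.append(
            {
                "plot_id": t.plot_id,
                "max_count": t.max_count,
                "hd10": t.hd10,
                "hd30": t.hd30,
                "hd50": t.hd50,
                "hd80": t.hd80,
                "heading_stage": t.heading_stage,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["plot_id", "max_count", "hd10", "hd30", "hd50", "hd80",
                 "heading_stage"],
    )
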