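"""Cross-year and cross-region summaries: percent change, CoV, spans.

These operate on per-100k rates (capacity per inhabitant is what makes
regions of different size comparable) or on any user-supplied regional
series, e.g. epidemic case or mortality rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError
from .eurostat_io import RegionRecord, per_100k

__all__ = [
    "RegionalSeries",
    "round_half_away",
    "percent_change",
    "coefficient_of_variation",
    "country_span",
    "count_increasing",
]


@dataclass(frozen=True)
class RegionalSeries:
    """A labelled list of (region, value) pairs sharing one unit."""

    label: str
    values: tuple[tuple[str, float], ...]
    unit: str = ""

    def __post_init__(self) -> None:
        if not self.values:
            raise DomainError(f"series {self.label!r} is empty")
        if not all(math.isfinite(v) for _, v in self.values):
            raise DomainError(f"series {self.label!r} contains non-finite values")


def round_half_away(x: float) -> float:
    """Round to the nearest integer, halves away from zero (as in '76%')."""
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def percent_change(v_old: float, v_new: float) -> float:
    """100 * (new - old) / old.  Use :func:`round_half_away` for reporting."""
    if v_old <= 0:
        raise DomainError(f"baseline must be positive, got {v_old}")
    return 100.0 * (v_new - v_old) / v_old


def coefficient_of_variation(
    s: RegionalSeries | Sequence[float], ddof: int = 1
) -> float:
    """Standard deviation divided by mean across regions.

    The sample (n-1) standard deviation is the default; pass ``ddof=0`` for
    the population form.
    """
    vals = np.asarray(
        [v for _, v in s.values] if isinstance(s, RegionalSeries) else list(s),
        dtype=float,
    )
    if vals.size < 2:
        raise DomainError("CoV needs at least two values")
    mean = vals.mean()
    if mean <= 0:
        raise DomainError(f"CoV undefined for non-positive mean {mean}")
    return float(vals.std(ddof=ddof) / mean)


def country_span(s: RegionalSeries) -> tuple[str, float, str, float]:
    """(min region, min value, max region, max value); ties break lexicographically."""
    ordered = sorted(s.values)  # lexicographic region order decides ties
    (min_r, min_v) = (max_r, max_v) = ordered[0]
    for r, v in ordered[1:]:
        if v < min_v:
            min_r, min_v = r, v
        if v > max_v:
            max_r, max_v = r, v
    return min_r, min_v, max_r, max_v


def count_increasing(
    panel: Iterable[RegionRecord], year_old: int, year_new: int
) -> tuple[int, list[str], list[str]]:
    """Regions whose beds per 100k strictly increased between two years.

    Returns ``(count, regions, skipped)`` where ``skipped`` lists regions
    missing one of the two years.
    """
    rates: dict[str, dict[int, float]] = {}
    for r in panel:
        rates.setdefault(r.nuts2, {})[r.year] = per_100k(r.beds, r.population)
    increased, skipped = [], []
    for geo in sorted(rates):
        ys = rates[geo]
        if year_old not in ys or year_new not in ys:
            skipped.append(geo)
        elif ys[year_new] > ys[year_old]:
            increased.append(geo)
    return len(increased), increased, skipped
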