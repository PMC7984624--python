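"""Barber-Johnson efficiency zones, centroid distance and diagram geometry.

The Barber-Johnson diagram plots the turnover interval (TOI, x-axis)
against the average length of stay (AvLOS, y-axis).  Points of equal bed
occupancy lie on rays through the origin with slope BOR/(1-BOR); points of
equal bed turnover lie on lines AvLOS + TOI = T/BTO.  A region is judged
efficient when 1 < TOI < 3 days and 75% < BOR < 85% (strict inequalities;
boundary values count as outside):

* GREEN  - both TOI and BOR inside their bands,
* YELLOW - exactly one inside,
* RED    - both outside.

The band centre (TOI = 2 days, BOR = 80%) serves as a centroid; the
Euclidean distance from it grades how far a region sits from ideal
management.  Because the two axes have different units the distance is
offered raw (TOI in days, BOR in percentage points) and band-normalised
(each deviation divided by its half-band width: 1 day, 5 points).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .errors import ConfigError, DomainError
from .indicators import BedIndicators

__all__ = [
    "EfficiencyThresholds",
    "Zone",
    "BJZone",
    "classify_bj",
    "centroid_distance",
    "bor_ray",
    "bto_isoline",
]


@dataclass(frozen=True)
class EfficiencyThresholds:
    """TOI/BOR target bands and their centroid (BOR as a fraction)."""

    toi_low: float = 1.0
    toi_high: float = 3.0
    bor_low: float = 0.75
    bor_high: float = 0.85
    centroid_toi: float = 2.0
    centroid_bor: float = 0.80

    def __post_init__(self) -> None:
        if not (self.toi_low < self.centroid_toi < self.toi_high):
            raise ConfigError("centroid TOI must lie strictly inside the TOI band")
        if not (self.bor_low < self.centroid_bor < self.bor_high):
            raise ConfigError("centroid BOR must lie strictly inside the BOR band")


class Zone(str, Enum):
    GREEN = "GREEN"
    YELLOW = "YELLOW"
    RED = "RED"


@dataclass(frozen=True)
class BJZone:
    """Zone membership plus the underlying per-indicator tests."""

    zone: Zone
    toi_in: bool
    bor_in: bool
    centroid_distance: float


def centroid_distance(
    ind: BedIndicators,
    t: EfficiencyThresholds = EfficiencyThresholds(),
    mode: str = "raw",
) -> float:
    """Euclidean distance of (TOI, BOR) from the band centroid.

    ``raw``: TOI in days, BOR in percentage points.  ``band``: each
    coordinate divided by its half-band width first, so one unit means one
    half-band in either direction.
    """
    dt = ind.toi - t.centroid_toi
    db = 100.0 * (ind.bor - t.centroid_bor)
    if mode == "raw":
        return math.hypot(dt, db)
    if mode == "band":
        half_toi = (t.toi_high - t.toi_low) / 2.0
        half_bor = 100.0 * (t.bor_high - t.bor_low) / 2.0
        return math.hypot(dt / half_toi, db / half_bor)
    raise ConfigError(f"unknown distance mode {mode!r} (use 'raw' or 'band')")


def classify_bj(
    ind: BedIndicators,
    t: EfficiencyThresholds = EfficiencyThresholds(),
    distance_mode: str = "raw",
) -> BJZone:
    """Assign the efficiency zone using strict open-interval membership."""
    toi_in = t.toi_low < ind.toi < t.toi_high
    bor_in = t.bor_low < ind.bor < t.bor_high
    if toi_in and bor_in:
        zone = Zone.GREEN
    elif toi_in or bor_in:
        zone = Zone.YELLOW
    else:
        zone = Zone.RED
    return BJZone(
        zone=zone,
        toi_in=toi_in,
        bor_in=bor_in,
        centroid_distance=centroid_distance(ind, t, distance_mode),
    )


def bor_ray(bor: float) -> float:
    """Slope of the constant-occupancy ray AvLOS = slope * TOI.

    Follows from BOR = AvLOS/(AvLOS + TOI).  Full occupancy (BOR == 1) has a
    vertical ray; ``math.inf`` is returned as the sentinel.
    """
    if not 0.0 <= bor <= 1.0:
        raise DomainError(f"bor must lie in [0, 1], got {bor}")
    if bor == 1.0:
        return math.inf
    return bor / (1.0 - bor)


def bto_isoline(bto: float, period_days: int = 365) -> float:
    """Intercept of the constant-turnover line AvLOS + TOI = T/BTO."""
    if bto <= 0:
        raise DomainError(f"bto must be positive, got {bto}")
    return period_days / bto
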