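"""The four bed-management indicators and their exact algebraic inverse.

With B beds, D discharges, O occupied bed-days and a period of T days:

    BOR   = O / (B T)        bed occupancy rate (fraction; reported as %)
    AvLOS = O / D            average length of stay (days)
    TOI   = (B T - O) / D    turnover interval (empty-bed days per discharge)
    BTO   = D / B            bed turnover (patients per bed per period)

These satisfy two accounting identities that the Barber-Johnson diagram is
built on:  AvLOS + TOI = T / BTO  and  BOR = AvLOS * BTO / T.

Occupied bed-days are not published by the regional hospital tables, so they
are derived as discharges x AvLOS, either per specialty (preferred when a
chapter breakdown exists) or from the all-diagnoses totals; the two modes
agree exactly when the total AvLOS is the discharge-weighted mean of the
specialty values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

__all__ = [
    "BedIndicators",
    "ActivityInput",
    "occupied_bed_days",
    "compute_indicators",
    "invert_indicators",
    "PERIOD_DAYS",
]

#: Default accounting period in days ("a year"; leap years ignored).
PERIOD_DAYS = 365


@dataclass(frozen=True)
class BedIndicators:
    """BOR (fraction), AvLOS (days), TOI (days), BTO (per period)."""

    bor: float
    avlos: float
    toi: float
    bto: float
    period_days: int = PERIOD_DAYS

    @property
    def bor_pct(self) -> float:
        """Occupancy as the percentage all reports print."""
        return 100.0 * self.bor


@dataclass(frozen=True)
class ActivityInput:
    """Raw activity of one structure over a period."""

    beds: float
    discharges: float
    occupied_bed_days: float
    period_days: int = PERIOD_DAYS

    def __post_init__(self) -> None:
        if self.beds <= 0:
            raise DomainError(f"beds must be positive, got {self.beds}")
        if self.discharges <= 0:
            raise DomainError("turnover undefined: discharges must be positive")
        if self.occupied_bed_days < 0:
            raise DomainError("occupied bed-days must be non-negative")
        if self.occupied_bed_days > self.beds * self.period_days * (1 + 1e-12):
            raise DomainError(
                f"occupied bed-days {self.occupied_bed_days} exceed capacity "
                f"{self.beds * self.period_days}"
            )


def occupied_bed_days(
    specialties=None,
    *,
    total_discharges: float | None = None,
    total_avlos: float | None = None,
) -> float:
    """Total in-patient days, as sum_j d_j * AvLOS_j or D * AvLOS.

    Pass ``specialties`` (an iterable of objects with ``discharges`` and
    ``avlos`` attributes, or of (discharges, avlos) pairs) for the
    per-chapter mode, or both totals for the all-diagnoses mode.
    """
    if specialties is not None:
        total = 0.0
        for s in specialties:
            d, a = (s.discharges, s.avlos) if hasattr(s, "discharges") else s
            if d < 0 or a < 0:
                raise DomainError("negative discharges or AvLOS")
            total += d * a
        return total
    if total_discharges is None or total_avlos is None:
        raise DomainError("need either specialties or both totals")
    if total_discharges < 0 or total_avlos < 0:
        raise DomainError("negative discharges or AvLOS")
    return total_discharges * total_avlos


def compute_indicators(a: ActivityInput) -> BedIndicators:
    """Forward map from raw activity to the four indicators."""
    b, d, o, t = a.beds, a.discharges, a.occupied_bed_days, a.period_days
    return BedIndicators(
        bor=o / (b * t),
        avlos=o / d,
        toi=max(b * t - o, 0.0) / d,
        bto=d / b,
        period_days=t,
    )


def invert_indicators(
    bor: float, toi: float, beds: float, period_days: int = PERIOD_DAYS
) -> tuple[float, float]:
    """Exact inverse: recover (discharges, avlos) from (BOR, TOI) and beds.

    From the identities, AvLOS = TOI * BOR / (1 - BOR) and
    D = B T (1 - BOR) / TOI.  The degenerate fully-occupied case
    (BOR == 1, TOI == 0) has infinitely many preimages; the convention used
    is one patient per bed for the whole period (D = B, AvLOS = T).
    """
    if not 0.0 <= bor <= 1.0:
        raise DomainError(f"bor must lie in [0, 1], got {bor}")
    if beds <= 0:
        raise DomainError("beds must be positive")
    if bor == 1.0:
        if toi != 0.0:
            raise DomainError("bor == 1 forces toi == 0")
        return float(beds), float(period_days)
    if toi <= 0.0 or bor <= 0.0:
        raise DomainError(f"inconsistent (bor, toi) = ({bor}, {toi})")
    avlos = toi * bor / (1.0 - bor)
    discharges = beds * period_days * (1.0 - bor) / toi
    return discharges, avlos


def check_identities(ind: BedIndicators, rel_tol: float = 1e-9) -> bool:
    """True iff both accounting identities hold to relative tolerance."""
    lhs = ind.avlos + ind.toi
    rhs = ind.period_days / ind.bto
    ok1 = math.isclose(lhs, rhs, rel_tol=rel_tol, abs_tol=1e-12)
    ok2 = math.isclose(
        ind.bor, ind.avlos * ind.bto / ind.period_days, rel_tol=rel_tol, abs_tol=1e-12
    )
    return ok1 and ok2
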