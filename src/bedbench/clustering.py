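"""Combined bed-management x case-mix/performance cluster matrix.

Crossing the three Barber-Johnson zones with the four CMI/PI quadrants
gives a 3x4 grid of 12 cells that reads a region's bed management (x-axis)
jointly with the complexity and performance of the cases it treats
(y-axis).  The full grid is exposed; any coarser grouping is a
configuration-supplied mapping from cell id to group label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .barber_johnson import BJZone, Zone
from .casemix import Quadrant
from .dispersion import round_half_away

__all__ = [
    "OverallCluster",
    "combine_classification",
    "country_distribution",
    "match_report",
    "CELL_IDS",
]

_ZONE_TEXT = {
    Zone.GREEN: "efficient management of beds",
    Zone.YELLOW: "one bed indicator outside the threshold",
    Zone.RED: "both bed indicators outside the thresholds",
}
_QUAD_TEXT = {
    Quadrant.GREEN: "efficiently manage high complexity cases",
    Quadrant.YELLOW: "efficiently manage low complexity cases",
    Quadrant.ORANGE: "high complexity cases with low performance",
    Quadrant.RED: "low complexity cases with low performance",
}

#: The 12 cell identifiers, zone-major.
CELL_IDS = tuple(f"{z.value}|{q.value}" for z in Zone for q in Quadrant)


@dataclass(frozen=True)
class OverallCluster:
    bj_zone: Zone
    quadrant: Quadrant
    cell_id: str
    label: str


def combine_classification(bj: BJZone | Zone, q: Quadrant) -> OverallCluster:
    """Deterministic cell assignment on the 3x4 grid (a bijection of inputs)."""
    zone = bj.zone if isinstance(bj, BJZone) else Zone(bj)
    q = Quadrant(q)
    return OverallCluster(
        bj_zone=zone,
        quadrant=q,
        cell_id=f"{zone.value}|{q.value}",
        label=f"{_ZONE_TEXT[zone]} / {_QUAD_TEXT[q]}",
    )


def country_distribution(
    tagged: Iterable[tuple[str, str]] | Mapping | pd.DataFrame,
    by: str = "class",
) -> pd.DataFrame:
    """Counts and integer percentages of regions per (country, class).

    ``tagged`` is an iterable of (country, class-label) pairs or a DataFrame
    with columns ``country`` and ``by``.  Percentages are of the country's
    region total, rounded to the nearest integer (half away from zero), as
    headline figures are customarily printed.
    """
    if isinstance(tagged, pd.DataFrame):
        df = tagged[["country", by]].rename(columns={by: "label"})
    else:
        df = pd.DataFrame(list(tagged), columns=["country", "label"])
    if df.empty:
        return pd.DataFrame(columns=["country", "label", "count", "pct"])
    counts = (
        df.groupby(["country", "label"], sort=True).size().reset_index(name="count")
    )
    totals = counts.groupby("country")["count"].transform("sum")
    counts["pct"] = [
        int(round_half_away(100.0 * c / t)) for c, t in zip(counts["count"], totals)
    ]
    return counts


def match_report(
    observed: pd.DataFrame,
    reference: pd.DataFrame,
    on: tuple[str, ...] = ("zone", "quadrant"),
    key: str = "region",
) -> pd.DataFrame:
    """Per-region agreement between a computed classification and a reference.

    Intended for comparing a run against an external reference table (e.g. a
    later data vintage, which may have revised some regions): the result
    reports match/mismatch per region and label column rather than failing,
    with regions present on only one side marked unmatched.
    """
    merged = observed.merge(reference, on=key, how="outer", suffixes=("", "_ref"), indicator=True)
    out = merged[[key, "_merge"]].rename(columns={"_merge": "presence"})
    out["presence"] = out["presence"].map(
        {"both": "both", "left_only": "observed_only", "right_only": "reference_only"}
    )
    for col in on:
        out[col] = merged.get(col)
        out[f"{col}_ref"] = merged.get(f"{col}_ref")
        out[f"{col}_match"] = (merged.get(col) == merged.get(f"{col}_ref")) & (
            out["presence"] == "both"
        )
    return out
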