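r"""Reading and writing Eurostat bulk-download style TSV extracts.

The bulk-download dialect: the first header field is a comma-joined list of
dimension names whose last element carries a ``\time`` suffix (e.g.
``unit,icd10,geo\time``); the remaining header fields are years.  Each data
row starts with the comma-joined dimension codes and continues with one
token per year.  A missing value is the sentinel ``:``; observation flags
(single letters b, e, p, u, d) follow the value after a space, e.g.
``580 e``.  A plain long-format CSV reader is provided as well, since
published analyses rarely state which export they used.

Region handling follows the NUTS-2 convention: geo codes of length 4 are
regions, 2-letter codes are national aggregates.  The region filter drops
aggregates, keeps only configured countries and removes configured
exclusions (by full code or prefix) such as the autonomous cities of Ceuta
and Melilla (ES63, ES64) and the French overseas regions.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .casemix import SpecialtyStats
from .errors import AssemblyError, DomainError, ParseError

__all__ = [
    "EurostatCell",
    "RegionRecord",
    "RegionFilter",
    "default_region_filter",
    "parse_eurostat_tsv",
    "write_eurostat_tsv",
    "read_long_csv",
    "filter_regions",
    "assemble_panel",
    "per_100k",
    "cells_to_frame",
    "read_population_csv",
    "write_panel",
    "read_panel",
]

VALID_FLAGS = frozenset("bepud")
MISSING = ":"


@dataclass(frozen=True)
class EurostatCell:
    """One (series, year) observation of a Eurostat table.

    ``dims`` is the ordered tuple of (dimension-name, code) pairs, e.g.
    ``(("unit", "NR"), ("icd10", "TOTAL"), ("geo", "ITC4"))``.  ``value`` is
    ``None`` exactly when the raw token was the ``:`` sentinel.
    """

    dataset_code: str
    dims: tuple[tuple[str, str], ...]
    year: int
    value: float | None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        names = [n for n, _ in self.dims]
        if "geo" not in names:
            raise DomainError("EurostatCell requires a geo dimension")
        if not self.flags <= VALID_FLAGS:
            raise DomainError(f"invalid flags {set(self.flags) - VALID_FLAGS}")

    @property
    def geo(self) -> str:
        return dict(self.dims)["geo"]

    def dim(self, name: str) -> str:
        return dict(self.dims)[name]


@dataclass(frozen=True)
class RegionRecord:
    """One region-year of hospital capacity and activity."""

    nuts2: str
    country: str
    year: int
    population: float
    beds: float
    total_discharges: float
    total_avlos: float
    specialties: tuple[SpecialtyStats, ...] = ()

    def __post_init__(self) -> None:
        if self.country != self.nuts2[:2]:
            raise DomainError(f"country {self.country!r} is not the prefix of {self.nuts2!r}")
        for v in (self.population, self.beds, self.total_discharges, self.total_avlos):
            if not (math.isfinite(v) and v >= 0):
                raise DomainError(f"{self.nuts2} {self.year}: non-finite or negative value")

    @property
    def coverage(self) -> float:
        """Fraction of total discharges covered by the specialty breakdown."""
        if self.total_discharges <= 0:
            return 0.0
        return sum(s.discharges for s in self.specialties) / self.total_discharges


# ---------------------------------------------------------------------------
# Bulk TSV dialect
# ---------------------------------------------------------------------------

def _parse_token(token: str, where: str) -> tuple[float | None, frozenset[str]]:
    parts = token.strip().split()
    if not parts:
        raise ParseError(f"empty value token at {where}")
    head, flag_parts = parts[0], parts[1:]
    flags = frozenset("".join(flag_parts))
    if not flags <= VALID_FLAGS:
        raise ParseError(f"unknown flag(s) {''.join(sorted(flags - VALID_FLAGS))!r} at {where}")
    if head == MISSING:
        return None, flags
    try:
        return float(head), flags
    except ValueError:
        raise ParseError(f"non-numeric token {token.strip()!r} at {where}") from None


def parse_eurostat_tsv(stream, dataset_code: str) -> list[EurostatCell]:
    """Parse a bulk-download TSV into cells, one per (row, year) token.

    ``stream`` may be a text file object, a path, or a string of TSV text.
    """
    if isinstance(stream, Path):
        stream = io.StringIO(stream.read_text())
    elif isinstance(stream, str):
        # a string is TSV text unless it names an existing file
        text = stream
        if "\t" not in stream and "\n" not in stream and Path(stream).is_file():
            text = Path(stream).read_text()
        stream = io.StringIO(text)
    lines = [ln.rstrip("\n") for ln in stream if ln.strip()]
    if not lines:
        raise ParseError("empty input (line 1)")
    header = lines[0].split("\t")
    dim_field = header[0].strip()
    if "\\time" not in dim_field:
        raise ParseError(r"malformed header (line 1): first field must end in '\time'")
    dim_names = [d.strip() for d in dim_field.replace("\\time", "").split(",")]
    if not all(dim_names):
        raise ParseError("malformed header (line 1): empty dimension name")
    try:
        years = [int(y.strip()) for y in header[1:]]
    except ValueError:
        raise ParseError("malformed header (line 1): non-integer year column") from None

    cells: list[EurostatCell] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        codes = [c.strip() for c in fields[0].split(",")]
        if len(codes) != len(dim_names):
            raise ParseError(
                f"row at line {lineno}: {len(codes)} dimension codes for {len(dim_names)} dimensions"
            )
        if len(fields) - 1 != len(years):
            raise ParseError(f"row at line {lineno}: expected {len(years)} value columns")
        dims = tuple(zip(dim_names, codes))
        for col, (year, token) in enumerate(zip(years, fields[1:]), start=2):
            if not token.strip():
                continue
            value, flags = _parse_token(token, f"line {lineno}, column {col}")
            cells.append(EurostatCell(dataset_code, dims, year, value, flags))
    return cells


def _format_value(cell: EurostatCell) -> str:
    if cell.value is None:
        head = MISSING
    else:
        v = float(cell.value)  # repr of a Python float is round-trip exact
        head = str(int(v)) if v == int(v) and abs(v) < 1e16 else repr(v)
    if cell.flags:
        return head + " " + "".join(sorted(cell.flags))
    return head


def write_eurostat_tsv(cells: Iterable[EurostatCell], stream) -> None:
    """Serialise cells back to the bulk dialect (round-trip identity with parse)."""
    cells = list(cells)
    if not cells:
        raise DomainError("cannot write an empty cell list")
    codes = {c.dataset_code for c in cells}
    dim_sets = {tuple(n for n, _ in c.dims) for c in cells}
    if len(codes) > 1 or len(dim_sets) > 1:
        raise DomainError("cells must share one dataset code and one dimension set")
    dim_names = next(iter(dim_sets))
    years = sorted({c.year for c in cells}, reverse=True)
    rows: dict[tuple[str, ...], dict[int, EurostatCell]] = {}
    for c in cells:
        rows.setdefault(tuple(code for _, code in c.dims), {})[c.year] = c

    close = False
    if isinstance(stream, (str, Path)):
        stream = open(stream, "w")
        close = True
    try:
        header = ",".join(list(dim_names[:-1]) + [dim_names[-1] + "\\time"])
        stream.write("\t".join([header] + [str(y) for y in years]) + "\n")
        for codes_key in rows:
            tokens = [
                _format_value(rows[codes_key][y]) if y in rows[codes_key] else ""
                for y in years
            ]
            stream.write("\t".join([",".join(codes_key)] + tokens) + "\n")
    finally:
        if close:
            stream.close()


def read_long_csv(source, dataset_code: str) -> list[EurostatCell]:
    """Read a long-format CSV (columns: dims..., year, value[, flags]) into cells."""
    df = pd.read_csv(source, dtype=str)
    required = {"geo", "year", "value"}
    if not required <= set(df.columns):
        raise ParseError(f"long CSV must contain columns {sorted(required)}")
    dim_cols = [c for c in df.columns if c not in ("year", "value", "flags")]
    cells = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        dims = tuple((c, str(d[c])) for c in dim_cols)
        raw = str(d["value"]).strip()
        value = None if raw in (MISSING, "", "nan") else float(raw)
        flags = frozenset(str(d.get("flags") or "").replace("nan", ""))
        cells.append(EurostatCell(dataset_code, dims, int(d["year"]), value, flags))
    return cells


def cells_to_frame(cells: Iterable[EurostatCell]) -> pd.DataFrame:
    """Tabular view of a cell list (one row per cell)."""
    recs = []
    for c in cells:
        rec = dict(c.dims)
        rec.update(year=c.year, value=c.value, flags="".join(sorted(c.flags)))
        recs.append(rec)
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Region inclusion rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionFilter:
    """Which NUTS-2 regions enter the analysis.

    Exclusions are configuration, not code, because NUTS revisions renumber
    regions; ``nuts_vintage`` records which revision the codes refer to.
    """

    countries: tuple[str, ...]
    exclude_geo: frozenset[str] = frozenset()
    exclude_prefixes: tuple[str, ...] = ()
    nuts_vintage: str = "NUTS-2016"


def default_region_filter() -> RegionFilter:
    """The four-country study filter: DE, ES, FR, IT; continental regions only.

    Ceuta and Melilla (ES63, ES64) and the French overseas regions (FRY* in
    NUTS-2016; FRA*/FR9* in earlier vintages) are excluded; Corse, the
    Canary and Balearic Islands stay in.
    """
    return RegionFilter(
        countries=("DE", "ES", "FR", "IT"),
        exclude_geo=frozenset({"ES63", "ES64", "FR91", "FR92", "FR93", "FR94"}),
        exclude_prefixes=("FRY", "FRA"),
    )


def filter_regions(cells: Iterable[EurostatCell], rules: RegionFilter) -> list[EurostatCell]:
    """Keep only NUTS-2 cells of the configured countries, minus exclusions.

    National aggregates (2-letter geo codes) and sub-NUTS-2 codes are
    dropped.  Idempotent and order-preserving.
    """
    out = []
    for c in cells:
        geo = c.geo
        if len(geo) != 4:
            continue
        if geo[:2] not in rules.countries:
            continue
        if geo in rules.exclude_geo:
            continue
        if any(geo.startswith(p) for p in rules.exclude_prefixes):
            continue
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# Panel assembly
# ---------------------------------------------------------------------------

def per_100k(count: float, population: float) -> float:
    """Rate per 100,000 inhabitants."""
    if population <= 0:
        raise DomainError(f"population must be positive, got {population}")
    return 100_000.0 * count / population


def read_population_csv(source) -> dict[tuple[str, int], float]:
    """Read a (geo, year, population) CSV into a lookup mapping."""
    df = pd.read_csv(source, float_precision="round_trip")
    return {
        (str(r.geo), int(r.year)): float(r.population)
        for r in df.itertuples(index=False)
    }


def _index_by_geo_year(cells, icd_dim=None, total_code="TOTAL"):
    totals: dict[tuple[str, int], float] = {}
    by_chapter: dict[tuple[str, int], dict[str, float]] = {}
    for c in cells:
        if c.value is None:
            continue
        key = (c.geo, c.year)
        if icd_dim is None:
            totals.setdefault(key, c.value)
            continue
        code = c.dim(icd_dim)
        if code == total_code:
            totals.setdefault(key, c.value)
        else:
            by_chapter.setdefault(key, {})[code] = c.value
    return totals, by_chapter


def assemble_panel(
    beds: Iterable[EurostatCell],
    discharges: Iterable[EurostatCell],
    avlos: Iterable[EurostatCell],
    population: Mapping[tuple[str, int], float],
    *,
    icd_dim: str = "icd10",
    total_code: str = "TOTAL",
) -> tuple[list[RegionRecord], list[dict]]:
    """Join bed, discharge, AvLOS and population inputs into region-year records.

    A record is produced for every (geo, year) with beds, population and the
    all-diagnoses totals; ICD-chapter specialties are attached where both the
    discharge count and the AvLOS are present (coverage < 1 otherwise).
    Regions missing a required input are skipped and reported, never
    imputed: every numeric field traces to exactly one input cell.

    Returns ``(records, skipped)`` where ``skipped`` is a list of
    ``{"geo":, "year":, "reason":}`` dicts.
    """
    beds_tot, _ = _index_by_geo_year(beds)
    disch_tot, disch_ch = _index_by_geo_year(discharges, icd_dim, total_code)
    avlos_tot, avlos_ch = _index_by_geo_year(avlos, icd_dim, total_code)

    keys = sorted(set(beds_tot) | set(disch_tot) | set(avlos_tot))
    if not keys:
        raise AssemblyError("no overlapping (geo, year) keys across the inputs")

    records: list[RegionRecord] = []
    skipped: list[dict] = []

    def skip(geo, year, reason):
        skipped.append({"geo": geo, "year": year, "reason": reason})

    for geo, year in keys:
        missing = [
            name
            for name, table in (
                ("beds", beds_tot),
                ("discharges", disch_tot),
                ("avlos", avlos_tot),
            )
            if (geo, year) not in table
        ]
        if (geo, year) not in population:
            missing.append("population")
        if missing:
            skip(geo, year, "missing " + ", ".join(missing))
            continue
        chapters = sorted(
            set(disch_ch.get((geo, year), {})) & set(avlos_ch.get((geo, year), {}))
        )
        specs = tuple(
            SpecialtyStats(
                specialty=ch,
                discharges=disch_ch[(geo, year)][ch],
                avlos=avlos_ch[(geo, year)][ch],
            )
            for ch in chapters
        )
        records.append(
            RegionRecord(
                nuts2=geo,
                country=geo[:2],
                year=year,
                population=population[(geo, year)],
                beds=beds_tot[(geo, year)],
                total_discharges=disch_tot[(geo, year)],
                total_avlos=avlos_tot[(geo, year)],
                specialties=specs,
            )
        )
    if not records:
        raise AssemblyError("empty panel: every region-year was skipped")
    return records, skipped


# ---------------------------------------------------------------------------
# Canonical panel serialisation (CSV pair + JSON skip report)
# ---------------------------------------------------------------------------

def panel_to_frames(records: Iterable[RegionRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into a region-year header table and a specialty table."""
    records = list(records)
    head = pd.DataFrame(
        {
            "geo": [r.nuts2 for r in records],
            "year": [r.year for r in records],
            "population": [r.population for r in records],
            "beds": [r.beds for r in records],
            "total_discharges": [r.total_discharges for r in records],
            "total_avlos": [r.total_avlos for r in records],
        }
    )
    rows = [
        {
            "geo": r.nuts2,
            "year": r.year,
            "specialty": s.specialty,
            "discharges": s.discharges,
            "avlos": s.avlos,
        }
        for r in records
        for s in r.specialties
    ]
    spec = pd.DataFrame(rows, columns=["geo", "year", "specialty", "discharges", "avlos"])
    return head, spec


def write_panel(records: Iterable[RegionRecord], directory, skipped: list[dict] | None = None) -> None:
    """Write the canonical panel: regions.csv, specialties.csv, skip_report.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    head, spec = panel_to_frames(records)
    head.to_csv(directory / "regions.csv", index=False)
    spec.to_csv(directory / "specialties.csv", index=False)
    if skipped is not None:
        (directory / "skip_report.json").write_text(json.dumps(skipped, indent=2))


def read_panel(directory) -> list[RegionRecord]:
    """Read back a canonical panel written by :func:`write_panel`."""
    directory = Path(directory)
    head = pd.read_csv(directory / "regions.csv", float_precision="round_trip")
    spec = pd.read_csv(directory / "specialties.csv", float_precision="round_trip")
    by_key: dict[tuple[str, int], list[SpecialtyStats]] = {}
    for r in spec.itertuples(index=False):
        by_key.setdefault((str(r.geo), int(r.year)), []).append(
            SpecialtyStats(str(r.specialty), float(r.discharges), float(r.avlos))
        )
    return [
        RegionRecord(
            nuts2=str(r.geo),
            country=str(r.geo)[:2],
            year=int(r.year),
            population=float(r.population),
            beds=float(r.beds),
            total_discharges=float(r.total_discharges),
            total_avlos=float(r.total_avlos),
            specialties=tuple(by_key.get((str(r.geo), int(r.year)), ())),
        )
        for r in head.itertuples(index=False)
    ]
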