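"""End-to-end pipeline: ingest, indicators, classifications, summaries.

The pipeline reproduces the regional analysis flow: read the three
Eurostat-style extracts plus populations, apply the region inclusion rules,
assemble region-year records, compute the four bed-management indicators,
classify Barber-Johnson zones, build the pooled multi-country benchmark,
compute CMI/PI with quadrants, combine both classifications into the 3x4
cluster grid, and summarise per country (distributions, per-100k spans,
percent changes, coefficient of variation).  Everything is deterministic
given inputs and configuration, and every number in the report is produced
by exactly one operation of the other modules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .barber_johnson import EfficiencyThresholds, classify_bj
from .casemix import build_benchmark, casemix_result, pi_cmi_ratio
from .clustering import combine_classification, country_distribution
from .dispersion import (
    RegionalSeries,
    coefficient_of_variation,
    count_increasing,
    country_span,
    percent_change,
    round_half_away,
)
from .errors import BedbenchError, ConfigError
from .eurostat_io import (
    RegionFilter,
    assemble_panel,
    default_region_filter,
    filter_regions,
    parse_eurostat_tsv,
    per_100k,
    read_population_csv,
)
from .indicators import ActivityInput, PERIOD_DAYS, compute_indicators, occupied_bed_days
from .synthetic import AVLOS_CODE, BEDS_CODE, DISCH_CODE

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]

log = logging.getLogger("bedbench")


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, years, thresholds and output location of one pipeline run."""

    beds_path: Path
    discharges_path: Path
    avlos_path: Path
    population_path: Path
    years: tuple[int, int] = (2012, 2017)
    classify_year: int | None = None  # defaults to the later year
    thresholds: EfficiencyThresholds = field(default_factory=EfficiencyThresholds)
    distance_mode: str = "raw"
    region_filter: RegionFilter | None = None  # None = keep all NUTS-2 regions
    occupied_mode: str = "auto"  # 'specialties' | 'totals' | 'auto'
    period_days: int = PERIOD_DAYS
    output_dir: Path | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.years[0] == self.years[1]:
            raise ConfigError("the two comparison years must be distinct")
        if self.occupied_mode not in ("specialties", "totals", "auto"):
            raise ConfigError(f"unknown occupied_mode {self.occupied_mode!r}")

    @property
    def analysis_year(self) -> int:
        return self.classify_year if self.classify_year is not None else max(self.years)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("beds_path", "discharges_path", "avlos_path", "population_path", "output_dir"):
            if key in raw:
                kwargs[key] = Path(raw.pop(key))
        if "years" in raw:
            kwargs["years"] = tuple(raw.pop("years"))
        if "thresholds" in raw:
            kwargs["thresholds"] = EfficiencyThresholds(**raw.pop("thresholds"))
        if "region_filter" in raw:
            rf = raw.pop("region_filter")
            if rf == "default":
                kwargs["region_filter"] = default_region_filter()
            elif rf is not None:
                rf = dict(rf)
                rf["countries"] = tuple(rf.get("countries", ()))
                rf["exclude_geo"] = frozenset(rf.get("exclude_geo", ()))
                rf["exclude_prefixes"] = tuple(rf.get("exclude_prefixes", ()))
                kwargs["region_filter"] = RegionFilter(**rf)
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass
class ReportBundle:
    """All tables a pipeline run produces."""

    region_table: pd.DataFrame
    zone_distribution: pd.DataFrame
    quadrant_distribution: pd.DataFrame
    cell_distribution: pd.DataFrame
    country_summary: pd.DataFrame
    increasing_regions: list[str]
    skipped: list[dict]

    def write(self, directory) -> None:
        """Write the bundle as CSV/JSON files (byte-identical across reruns)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.region_table.to_csv(directory / "regions.csv", index=False)
        self.zone_distribution.to_csv(directory / "zone_distribution.csv", index=False)
        self.quadrant_distribution.to_csv(directory / "quadrant_distribution.csv", index=False)
        self.cell_distribution.to_csv(directory / "cell_distribution.csv", index=False)
        self.country_summary.to_csv(directory / "country_summary.csv", index=False)
        (directory / "report.json").write_text(
            json.dumps(
                {
                    "increasing_regions": self.increasing_regions,
                    "skipped": self.skipped,
                },
                indent=2,
                sort_keys=True,
            )
        )


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise BedbenchError(f"pipeline stage {name!r} failed: {exc}") from exc

    return _Ctx()


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Run the full analysis.  Outputs are written only after every stage
    succeeded, so a failing run leaves no partial report behind."""
    logging.basicConfig(level=cfg.log_level)

    for name, code, path in (
        ("beds", BEDS_CODE, cfg.beds_path),
        ("discharges", DISCH_CODE, cfg.discharges_path),
        ("avlos", AVLOS_CODE, cfg.avlos_path),
        ("population", "population", cfg.population_path),
    ):
        if not Path(path).is_file():
            raise ConfigError(f"missing input for dataset {code} ({name}): {path}")

    with _stage("ingest"):
        beds = parse_eurostat_tsv(Path(cfg.beds_path), BEDS_CODE)
        disch = parse_eurostat_tsv(Path(cfg.discharges_path), DISCH_CODE)
        avlos = parse_eurostat_tsv(Path(cfg.avlos_path), AVLOS_CODE)
        population = read_population_csv(cfg.population_path)
        if cfg.region_filter is not None:
            beds = filter_regions(beds, cfg.region_filter)
            disch = filter_regions(disch, cfg.region_filter)
            avlos = filter_regions(avlos, cfg.region_filter)
        log.info("parsed %d/%d/%d cells (beds/discharges/avlos)", len(beds), len(disch), len(avlos))

    with _stage("assemble"):
        records, skipped = assemble_panel(beds, disch, avlos, population)
        log.info("assembled %d region-years, skipped %d", len(records), len(skipped))

    year = cfg.analysis_year
    current = [r for r in records if r.year == year]
    if not current:
        raise BedbenchError(f"pipeline stage 'assemble' failed: no records for year {year}")

    with _stage("indicators"):
        rows = []
        indicators = {}
        for rec in current:
            use_spec = cfg.occupied_mode == "specialties" or (
                cfg.occupied_mode == "auto" and rec.specialties and rec.coverage > 0.999
            )
            occ = (
                occupied_bed_days(rec.specialties)
                if use_spec
                else occupied_bed_days(
                    total_discharges=rec.total_discharges, total_avlos=rec.total_avlos
                )
            )
            try:
                ind = compute_indicators(
                    ActivityInput(
                        beds=rec.beds,
                        discharges=rec.total_discharges,
                        occupied_bed_days=occ,
                        period_days=cfg.period_days,
                    )
                )
            except BedbenchError as e:
                skipped.append({"geo": rec.nuts2, "year": rec.year, "reason": str(e)})
                continue
            indicators[rec.nuts2] = (rec, ind, occ)

    with _stage("classify"):
        bench = build_benchmark(
            [rec for rec, _, _ in indicators.values() if rec.specialties]
        )
        for geo in sorted(indicators):
            rec, ind, occ = indicators[geo]
            bj = classify_bj(ind, cfg.thresholds, cfg.distance_mode)
            cm = casemix_result(rec.specialties, bench) if rec.specialties else None
            cluster = combine_classification(bj, cm.quadrant) if cm else None
            rows.append(
                {
                    "region": rec.nuts2,
                    "country": rec.country,
                    "year": rec.year,
                    "population": rec.population,
                    "beds": rec.beds,
                    "beds_per_100k": per_100k(rec.beds, rec.population),
                    "discharges": rec.total_discharges,
                    "occupied_bed_days": occ,
                    "bor_pct": ind.bor_pct,
                    "avlos": ind.avlos,
                    "toi": ind.toi,
                    "bto": ind.bto,
                    "zone": bj.zone.value,
                    "centroid_distance": bj.centroid_distance,
                    "cmi": cm.cmi if cm else float("nan"),
                    "pi": cm.pi if cm else float("nan"),
                    "quadrant": cm.quadrant.value if cm else "",
                    "pi_cmi_ratio": pi_cmi_ratio(cm.cmi, cm.pi) if cm else float("nan"),
                    "coverage": cm.coverage if cm else 0.0,
                    "cell_id": cluster.cell_id if cluster else "",
                    "cell_label": cluster.label if cluster else "",
                }
            )
        region_table = pd.DataFrame(rows)

    with _stage("summaries"):
        zone_dist = country_distribution(region_table, by="zone")
        quad_dist = country_distribution(region_table[region_table.quadrant != ""], by="quadrant")
        cell_dist = country_distribution(region_table[region_table.cell_id != ""], by="cell_id")

        summary_rows = []
        y0, y1 = min(cfg.years), max(cfg.years)
        for country in sorted({r.country for r in records}):
            rates = {
                yy: [
                    (r.nuts2, per_100k(r.beds, r.population))
                    for r in records
                    if r.country == country and r.year == yy
                ]
                for yy in (y0, y1)
            }
            # country aggregate rate: pooled beds over pooled population
            agg = {}
            for yy in (y0, y1):
                recs = [r for r in records if r.country == country and r.year == yy]
                if recs:
                    agg[yy] = per_100k(sum(r.beds for r in recs), sum(r.population for r in recs))
            row = {"country": country}
            if rates[y1]:
                series = RegionalSeries(f"beds_per_100k_{country}", tuple(rates[y1]))
                mn_r, mn_v, mx_r, mx_v = country_span(series)
                row.update(
                    min_region=mn_r,
                    min_beds_per_100k=mn_v,
                    max_region=mx_r,
                    max_beds_per_100k=mx_v,
                )
                if len(rates[y1]) >= 2:
                    row["cov_beds_per_100k"] = coefficient_of_variation(series)
            if y0 in agg and y1 in agg:
                change = percent_change(agg[y0], agg[y1])
                row.update(
                    beds_per_100k_old=agg[y0],
                    beds_per_100k_new=agg[y1],
                    pct_change=change,
                    pct_change_rounded=int(round_half_away(change)),
                )
            summary_rows.append(row)
        country_summary = pd.DataFrame(summary_rows)
        _, increasing, _ = count_increasing(records, y0, y1)

    bundle = ReportBundle(
        region_table=region_table,
        zone_distribution=zone_dist,
        quadrant_distribution=quad_dist,
        cell_distribution=cell_dist,
        country_summary=country_summary,
        increasing_regions=increasing,
        skipped=skipped,
    )
    if cfg.output_dir is not None:
        bundle.write(cfg.output_dir)
    return bundle
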