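"""Synthetic multi-country hospital-activity panels with known ground truth.

The generator emulates the regional extracts the pipeline consumes (bed
stocks, per-chapter discharges and AvLOS, populations, several countries,
two reference years) while placing every region at an exactly known point
of both classification diagrams, so that label-recovery through the full
ingest-and-classify pipeline can be tested without any download.

Construction, per region-year:

1. The intended quadrant fixes the sides of the CMI and PI targets; a
   specialty profile hitting them against a fixed design benchmark is built
   by exponential tilting of the reference shares (CMI, via bisection) and
   uniform AvLOS scaling (PI, exact by linearity).
2. The profile pins the region's total AvLOS ``a`` (= CMI * PI * AvLOS_ALL
   of the design benchmark), and the bed-accounting identities then tie BOR
   and TOI together: TOI = a (1-BOR)/BOR.  The intended Barber-Johnson zone
   is realised by sampling BOR inside the zone-feasible interval (with a
   margin keeping placements off the strict-inequality boundaries) and
   recovering discharges through the exact inverse of the indicator map.
3. The analysis pipeline pools its benchmark from the panel itself, which
   shifts each region's achieved CMI/PI away from the design targets (a
   pooled benchmark forces the pool-weighted mean of both indices to 1).
   Ground truth is therefore the achieved value against the pooled
   benchmark; a deterministic repair loop pushes any region whose achieved
   quadrant drifted across a boundary further from 1 and regenerates it,
   so intended and achieved labels agree exactly on return.

Optional multiplicative lognormal noise on discharges and AvLOS is applied
after ground-truth labelling, with labels re-derived, to study recovery
degradation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .barber_johnson import EfficiencyThresholds, Zone, classify_bj
from .casemix import (
    Benchmark,
    Quadrant,
    SpecialtyStats,
    build_benchmark,
    classify_quadrant,
    compute_cmi,
    compute_pi,
)
from .errors import DomainError, GenerationError
from .eurostat_io import EurostatCell, RegionRecord, write_eurostat_tsv
from .indicators import (
    ActivityInput,
    PERIOD_DAYS,
    compute_indicators,
    invert_indicators,
    occupied_bed_days,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "design_benchmark",
    "gen_region_at",
    "gen_specialty_profile",
    "gen_panel",
    "export_fixture",
    "ground_truth_frame",
    "BEDS_CODE",
    "DISCH_CODE",
    "AVLOS_CODE",
]

# Dataset codes of the emulated extracts.
BEDS_CODE = "HLTH_RS_BDSRG"
DISCH_CODE = "HLTH_CO_DISCH1T"
AVLOS_CODE = "HLTH_CO_INPSTT"


@dataclass(frozen=True)
class SyntheticConfig:
    """Design of a synthetic panel.

    Defaults mirror the four-country study setting: region counts per
    country as included in the analysis (DE 16, ES 19, FR 22, IT 21), zone
    and quadrant mixes close to the observed cross-country distribution,
    bed densities spanning the reported per-100k range.
    """

    countries: tuple[tuple[str, int], ...] = (
        ("DE", 16),
        ("ES", 19),
        ("FR", 22),
        ("IT", 21),
    )
    zone_mix: tuple[tuple[Zone, float], ...] = (
        (Zone.GREEN, 0.45),
        (Zone.YELLOW, 0.25),
        (Zone.RED, 0.30),
    )
    quadrant_mix: tuple[tuple[Quadrant, float], ...] = (
        (Quadrant.GREEN, 0.33),
        (Quadrant.YELLOW, 0.45),
        (Quadrant.ORANGE, 0.08),
        (Quadrant.RED, 0.14),
    )
    beds_per_100k_range: tuple[float, float] = (219.0, 1285.0)
    population_range: tuple[float, float] = (3e5, 1.2e7)
    n_specialties: int = 10
    noise_sd: float = 0.0
    seed: int = 0
    years: tuple[int, ...] = (2012, 2017)
    period_days: int = PERIOD_DAYS
    thresholds: EfficiencyThresholds = field(default_factory=EfficiencyThresholds)

    def __post_init__(self) -> None:
        for name, mix in (("zone_mix", self.zone_mix), ("quadrant_mix", self.quadrant_mix)):
            total = sum(p for _, p in mix)
            if abs(total - 1.0) > 1e-9 or any(p < 0 for _, p in mix):
                raise DomainError(f"{name} proportions must be non-negative and sum to 1")
        if self.n_specialties < 2:
            raise DomainError("need at least two specialties")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Exact placement and labels of one generated region-year.

    ``zone``/``quadrant`` are the labels a perfect classifier recovers from
    the emitted data (re-derived after noise when noise is on);
    ``intended_zone``/``intended_quadrant`` are the stratified design labels
    (identical to the former when ``noise_sd == 0``).
    """

    region: str
    country: str
    year: int
    zone: Zone
    quadrant: Quadrant
    intended_zone: Zone
    intended_quadrant: Quadrant
    bor: float
    toi: float
    cmi: float
    pi: float

    @property
    def cell_id(self) -> str:
        return f"{self.zone.value}|{self.quadrant.value}"


def design_benchmark(n_specialties: int) -> Benchmark:
    """Fixed reference profile: chapter AvLOS from 4 to 13 days, shares
    decaying geometrically (common conditions dominate discharge counts)."""
    codes = [f"CH{j + 1:02d}" for j in range(n_specialties)]
    avlos = np.linspace(4.0, 13.0, n_specialties)
    weights = np.exp(-0.2 * np.arange(n_specialties))
    shares = weights / weights.sum()
    return Benchmark(
        specialties=tuple(codes),
        ref_avlos={c: float(a) for c, a in zip(codes, avlos)},
        ref_discharges={c: float(s) for c, s in zip(codes, shares)},
    )


def gen_region_at(
    bor: float, toi: float, beds: float, period_days: int = PERIOD_DAYS
) -> tuple[float, float]:
    """(discharges, avlos) of a region sitting exactly at (BOR, TOI).

    Thin wrapper over the closed-form inverse of the indicator map; the
    recomputed indicators of the result equal the inputs to float precision.
    """
    return invert_indicators(bor, toi, beds, period_days)


def gen_specialty_profile(
    b: Benchmark,
    cmi_target: float,
    pi_target: float,
    tol: float = 1e-6,
    max_steps: int = 60,
    total_discharges: float = 1.0,
) -> list[SpecialtyStats]:
    """Specialty profile hitting (CMI, PI) targets against benchmark ``b``.

    PI is hit exactly by uniform scaling (AvLOS_j = pi_target * AvLOS_j^REF,
    exact because PI is linear in the structure AvLOS).  CMI is hit to
    ``tol`` by an exponential tilt of the reference shares,
    w_j(theta) ~ share_j * exp(theta * AvLOS_j^REF); CMI(theta) is
    continuous and strictly increasing, so bisection converges.
    """
    if pi_target <= 0:
        raise DomainError("pi_target must be positive")
    codes = list(b.specialties)
    a = np.array([b.ref_avlos[c] for c in codes])
    s = np.array([b.ref_share[c] for c in codes])
    lo_att, hi_att = a.min() / b.overall_avlos, a.max() / b.overall_avlos
    if not lo_att < cmi_target < hi_att:
        raise DomainError(
            f"cmi_target {cmi_target} outside attainable range ({lo_att:.6g}, {hi_att:.6g})"
        )

    def shares_at(theta: float) -> np.ndarray:
        w = s * np.exp(theta * (a - a.mean()))  # centring keeps exponents small
        return w / w.sum()

    def cmi_at(theta: float) -> float:
        return float(shares_at(theta) @ a / b.overall_avlos)

    if cmi_target == 1.0:
        theta = 0.0
    else:
        lo, hi = -1.0, 1.0
        for _ in range(200):
            if cmi_at(lo) <= cmi_target:
                break
            lo *= 2.0
        for _ in range(200):
            if cmi_at(hi) >= cmi_target:
                break
            hi *= 2.0
        theta = 0.0
        for _ in range(max_steps):
            theta = 0.5 * (lo + hi)
            c = cmi_at(theta)
            if abs(c - cmi_target) <= tol:
                break
            if c < cmi_target:
                lo = theta
            else:
                hi = theta
    w = shares_at(theta)
    return [
        SpecialtyStats(c, total_discharges * float(wj), pi_target * float(aj))
        for c, wj, aj in zip(codes, w, a)
    ]


# ---------------------------------------------------------------------------
# Zone-feasible (BOR, TOI) sampling
# ---------------------------------------------------------------------------

_BOR_MARGIN = 0.003   # keep BOR off the strict-inequality band edges
_TOI_MARGIN = 0.02    # same for TOI, in days
_TOI_CAP = 30.0       # realism cap on empty-bed days
_BOR_CAP = 0.98


def _intersect(a: list[tuple[float, float]], b: list[tuple[float, float]]):
    out = []
    for lo1, hi1 in a:
        for lo2, hi2 in b:
            lo, hi = max(lo1, lo2), min(hi1, hi2)
            if hi > lo:
                out.append((lo, hi))
    return out


def _zone_bor_intervals(
    zone: Zone, avlos: float, t: EfficiencyThresholds
) -> list[tuple[float, float]]:
    """BOR intervals realising ``zone`` for a region with total AvLOS fixed.

    TOI is tied to BOR by TOI = avlos (1-BOR)/BOR, so each zone becomes a
    union of BOR intervals.  Margins keep samples strictly inside/outside
    the bands.
    """

    def bor_of_toi(toi: float) -> float:
        return avlos / (avlos + toi)

    lo_glob = max(bor_of_toi(_TOI_CAP), 0.02)
    hi_glob = min(_BOR_CAP, bor_of_toi(_TOI_MARGIN))
    domain = [(lo_glob, hi_glob)]

    bor_in = [(t.bor_low + _BOR_MARGIN, t.bor_high - _BOR_MARGIN)]
    bor_out = [(lo_glob, t.bor_low - _BOR_MARGIN), (t.bor_high + _BOR_MARGIN, hi_glob)]
    # TOI decreasing in BOR: toi in-band <=> bor in (bor_of(toi_high), bor_of(toi_low))
    toi_in = [(bor_of_toi(t.toi_high - _TOI_MARGIN), bor_of_toi(t.toi_low + _TOI_MARGIN))]
    toi_out = [
        (lo_glob, bor_of_toi(t.toi_high + _TOI_MARGIN)),
        (bor_of_toi(t.toi_low - _TOI_MARGIN), hi_glob),
    ]

    if zone is Zone.GREEN:
        pieces = _intersect(bor_in, toi_in)
    elif zone is Zone.YELLOW:
        pieces = _intersect(bor_in, toi_out) + _intersect(bor_out, toi_in)
    else:
        pieces = _intersect(bor_out, toi_out)
    return _intersect(pieces, domain)


def _sample_placement(
    rng: np.random.Generator, zone: Zone, avlos: float, t: EfficiencyThresholds
) -> tuple[float, float]:
    pieces = _zone_bor_intervals(zone, avlos, t)
    if not pieces:
        raise GenerationError(
            f"no (BOR, TOI) placement realises zone {zone.value} at AvLOS {avlos:.3g}"
        )
    lengths = np.array([hi - lo for lo, hi in pieces])
    lo, hi = pieces[rng.choice(len(pieces), p=lengths / lengths.sum())]
    bor = float(rng.uniform(lo, hi))
    toi = avlos * (1.0 - bor) / bor
    return bor, toi


# ---------------------------------------------------------------------------
# Stratified label assignment
# ---------------------------------------------------------------------------

def _largest_remainder(mix: Sequence[tuple[object, float]], n: int) -> dict:
    """Apportion n units to classes by quota with largest-remainder rounding."""
    quotas = [(label, n * p) for label, p in mix]
    counts = {label: math.floor(q) for label, q in quotas}
    short = n - sum(counts.values())
    by_frac = sorted(quotas, key=lambda lq: (-(lq[1] - math.floor(lq[1])), str(lq[0])))
    for label, _ in by_frac[:short]:
        counts[label] += 1
    return counts


def _cell_counts(cfg: SyntheticConfig, n: int) -> list[tuple[Zone, Quadrant]]:
    """Pair zone and quadrant labels so both marginals match their mixes
    exactly; quadrant budgets are spread over zones by controlled rounding."""
    zone_counts = _largest_remainder(cfg.zone_mix, n)
    quad_budget = _largest_remainder(cfg.quadrant_mix, n)
    quads = [q for q, _ in cfg.quadrant_mix]
    pairs: list[tuple[Zone, Quadrant]] = []
    remaining = n
    zones = [z for z, _ in cfg.zone_mix]
    for i, z in enumerate(zones):
        m = zone_counts[z]
        if i == len(zones) - 1:
            alloc = dict(quad_budget)
        else:
            mix = [(q, quad_budget[q] / remaining if remaining else 0.0) for q in quads]
            alloc = _largest_remainder(mix, m)
            for q in quads:  # never exceed the remaining global budget
                over = alloc[q] - quad_budget[q]
                if over > 0:
                    alloc[q] -= over
            deficit = m - sum(alloc.values())
            for q in quads:
                if deficit <= 0:
                    break
                room = quad_budget[q] - alloc[q]
                take = min(room, deficit)
                alloc[q] += take
                deficit -= take
        for q in quads:
            pairs.extend([(z, q)] * alloc[q])
            quad_budget[q] -= alloc[q]
        remaining -= m
    return pairs


# ---------------------------------------------------------------------------
# Panel generation
# ---------------------------------------------------------------------------

_DIST_LO, _DIST_HI = 0.07, 0.15   # initial |target - 1| for CMI and PI
_DIST_CAP = 0.28                  # repair never pushes targets further than this
_REPAIR_FACTOR = 1.5
_MAX_REPAIR_ROUNDS = 30


def _signed_target(side_high: bool, dist: float) -> float:
    return 1.0 + dist if side_high else 1.0 - dist


def gen_panel(cfg: SyntheticConfig) -> tuple[list[RegionRecord], list[GroundTruth]]:
    """Generate the panel and its ground truth.

    Reproducible bit-for-bit for a fixed config; zone and quadrant label
    frequencies match the configured mixes exactly per year (largest-
    remainder apportionment where counts do not divide evenly).
    """
    rng = np.random.default_rng(cfg.seed)
    bench0 = design_benchmark(cfg.n_specialties)
    regions = [
        (f"{cc}{i + 1:02d}", cc) for cc, k in cfg.countries for i in range(k)
    ]
    n = len(regions)

    all_records: list[RegionRecord] = []
    all_truths: list[GroundTruth] = []
    for year in cfg.years:
        pairs = _cell_counts(cfg, n)
        order = rng.permutation(n)
        assignment = [pairs[i] for i in order]

        pops = rng.uniform(*cfg.population_range, size=n)
        bed_rates = rng.uniform(*cfg.beds_per_100k_range, size=n)
        dists_cmi = rng.uniform(_DIST_LO, _DIST_HI, size=n)
        dists_pi = rng.uniform(_DIST_LO, _DIST_HI, size=n)

        lo_att = min(bench0.ref_avlos.values())
        hi_att = max(bench0.ref_avlos.values())
        cap_lo = min(_DIST_CAP, 1.0 - lo_att / bench0.overall_avlos - 0.02)
        cap_hi = min(_DIST_CAP, hi_att / bench0.overall_avlos - 1.0 - 0.02)

        def build_region(i: int) -> RegionRecord:
            code, country = regions[i]
            zone, quad = assignment[i]
            cmi_high = quad in (Quadrant.GREEN, Quadrant.ORANGE)
            pi_high = quad in (Quadrant.ORANGE, Quadrant.RED)
            cmi_t = _signed_target(cmi_high, min(dists_cmi[i], cap_hi if cmi_high else cap_lo))
            pi_t = _signed_target(pi_high, min(dists_pi[i], _DIST_CAP))
            profile = gen_specialty_profile(bench0, cmi_t, pi_t)
            avlos_total = sum(p.discharges * p.avlos for p in profile)  # unit discharges
            bor, toi = _sample_placement(rng, zone, avlos_total, cfg.thresholds)
            beds = bed_rates[i] * pops[i] / 1e5
            discharges, avlos = invert_indicators(bor, toi, beds, cfg.period_days)
            specs = tuple(
                SpecialtyStats(p.specialty, discharges * p.discharges, p.avlos)
                for p in profile
            )
            return RegionRecord(
                nuts2=code,
                country=country,
                year=year,
                population=float(pops[i]),
                beds=float(beds),
                total_discharges=float(discharges),
                total_avlos=float(avlos),
                specialties=specs,
            )

        records = [build_region(i) for i in range(n)]

        # Self-consistency repair: achieved CMI/PI against the pooled
        # benchmark must fall in the intended quadrant for every region.
        for _ in range(_MAX_REPAIR_ROUNDS):
            pooled = build_benchmark(records)
            bad = []
            for i, rec in enumerate(records):
                cmi = compute_cmi(rec.specialties, pooled)
                pi = compute_pi(rec.specialties, pooled)
                if classify_quadrant(cmi, pi) is not assignment[i][1]:
                    bad.append(i)
            if not bad:
                break
            for i in bad:
                dists_cmi[i] = min(dists_cmi[i] * _REPAIR_FACTOR, _DIST_CAP)
                dists_pi[i] = min(dists_pi[i] * _REPAIR_FACTOR, _DIST_CAP)
                records[i] = build_region(i)
        else:
            raise GenerationError(
                "quadrant mix could not be realised against the pooled benchmark "
                "(a pooled reference forces the discharge-weighted mean of CMI and "
                "PI to 1, so a mix cannot put every region on one side)"
            )

        if cfg.noise_sd > 0:
            records = [_apply_noise(rec, rng, cfg) for rec in records]

        pooled = build_benchmark(records)
        for i, rec in enumerate(records):
            ind = compute_indicators(
                ActivityInput(
                    beds=rec.beds,
                    discharges=rec.total_discharges,
                    occupied_bed_days=occupied_bed_days(rec.specialties),
                    period_days=cfg.period_days,
                )
            )
            zone = classify_bj(ind, cfg.thresholds).zone
            cmi = compute_cmi(rec.specialties, pooled)
            pi = compute_pi(rec.specialties, pooled)
            quad = classify_quadrant(cmi, pi)
            if cfg.noise_sd == 0:
                assert zone is assignment[i][0] and quad is assignment[i][1]
            all_truths.append(
                GroundTruth(
                    region=rec.nuts2,
                    country=rec.country,
                    year=year,
                    zone=zone,
                    quadrant=quad,
                    intended_zone=assignment[i][0],
                    intended_quadrant=assignment[i][1],
                    bor=ind.bor,
                    toi=ind.toi,
                    cmi=cmi,
                    pi=pi,
                )
            )
        all_records.extend(records)
    return all_records, all_truths


def _apply_noise(
    rec: RegionRecord, rng: np.random.Generator, cfg: SyntheticConfig
) -> RegionRecord:
    """Multiplicative lognormal noise on per-chapter discharges and AvLOS.

    Counts and durations are positive, hence the multiplicative model.  If
    the perturbed occupancy would exceed capacity, the AvLOS vector is
    scaled back so occupied days stay below 98% of bed-days.
    """
    sd = cfg.noise_sd
    specs = [
        SpecialtyStats(
            s.specialty,
            s.discharges * float(rng.lognormal(0.0, sd)),
            s.avlos * float(rng.lognormal(0.0, sd)),
        )
        for s in rec.specialties
    ]
    total_d = sum(s.discharges for s in specs)
    occupied = sum(s.discharges * s.avlos for s in specs)
    cap = 0.98 * rec.beds * cfg.period_days
    if occupied > cap:
        shrink = cap / occupied
        specs = [
            SpecialtyStats(s.specialty, s.discharges, s.avlos * shrink) for s in specs
        ]
        occupied = cap
    return replace(
        rec,
        specialties=tuple(specs),
        total_discharges=total_d,
        total_avlos=occupied / total_d,
    )


def ground_truth_frame(truths: Sequence[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": [t.region for t in truths],
            "country": [t.country for t in truths],
            "year": [t.year for t in truths],
            "zone": [t.zone.value for t in truths],
            "quadrant": [t.quadrant.value for t in truths],
            "cell_id": [t.cell_id for t in truths],
            "intended_zone": [t.intended_zone.value for t in truths],
            "intended_quadrant": [t.intended_quadrant.value for t in truths],
            "bor": [t.bor for t in truths],
            "toi": [t.toi for t in truths],
            "cmi": [t.cmi for t in truths],
            "pi": [t.pi for t in truths],
        }
    )


# ---------------------------------------------------------------------------
# Fixture export (Eurostat-dialect files)
# ---------------------------------------------------------------------------

def export_fixture(
    records: Sequence[RegionRecord],
    directory,
    truths: Sequence[GroundTruth] | None = None,
    missing_rate: float = 0.0,
    missing_seed: int = 0,
) -> dict[str, Path]:
    """Write the panel as Eurostat-dialect TSVs plus a population CSV.

    Files: ``beds.tsv`` (dims unit,geo), ``discharges.tsv`` and
    ``avlos.tsv`` (dims unit,icd10,geo; chapter rows plus TOTAL),
    ``population.csv`` and, when ground truth is given,
    ``ground_truth.csv``.  Values are written with round-trip-exact float
    formatting, so re-ingesting reproduces the panel bit for bit.

    ``missing_rate`` > 0 replaces that fraction of chapter (discharge,
    AvLOS) cell pairs with the ``:`` sentinel, to exercise partial-coverage
    handling downstream; totals are never blanked.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    miss_rng = np.random.default_rng(missing_seed)

    beds_cells, disch_cells, avlos_cells = [], [], []
    pop_rows = []
    for rec in records:
        beds_cells.append(
            EurostatCell(BEDS_CODE, (("unit", "NR"), ("geo", rec.nuts2)), rec.year, rec.beds)
        )
        pop_rows.append({"geo": rec.nuts2, "year": rec.year, "population": rec.population})
        disch_cells.append(
            EurostatCell(
                DISCH_CODE,
                (("unit", "NR"), ("icd10", "TOTAL"), ("geo", rec.nuts2)),
                rec.year,
                rec.total_discharges,
            )
        )
        avlos_cells.append(
            EurostatCell(
                AVLOS_CODE,
                (("unit", "DAY"), ("icd10", "TOTAL"), ("geo", rec.nuts2)),
                rec.year,
                rec.total_avlos,
            )
        )
        for s in rec.specialties:
            blank = missing_rate > 0 and miss_rng.random() < missing_rate
            disch_cells.append(
                EurostatCell(
                    DISCH_CODE,
                    (("unit", "NR"), ("icd10", s.specialty), ("geo", rec.nuts2)),
                    rec.year,
                    None if blank else s.discharges,
                )
            )
            avlos_cells.append(
                EurostatCell(
                    AVLOS_CODE,
                    (("unit", "DAY"), ("icd10", s.specialty), ("geo", rec.nuts2)),
                    rec.year,
                    None if blank else s.avlos,
                )
            )

    paths = {
        "beds": directory / "beds.tsv",
        "discharges": directory / "discharges.tsv",
        "avlos": directory / "avlos.tsv",
        "population": directory / "population.csv",
    }
    write_eurostat_tsv(beds_cells, paths["beds"])
    write_eurostat_tsv(disch_cells, paths["discharges"])
    write_eurostat_tsv(avlos_cells, paths["avlos"])
    pd.DataFrame(pop_rows).drop_duplicates().to_csv(paths["population"], index=False)
    if truths is not None:
        paths["ground_truth"] = directory / "ground_truth.csv"
        ground_truth_frame(truths).to_csv(paths["ground_truth"], index=False)
    return paths
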