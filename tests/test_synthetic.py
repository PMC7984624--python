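"""Synthetic panel generator: exact placements, target hitting, recovery."""

import numpy as np
import pytest

from bedbench.barber_johnson import EfficiencyThresholds, Zone, classify_bj
from bedbench.casemix import Benchmark, Quadrant, build_benchmark, compute_cmi, compute_pi
from bedbench.errors import DomainError
from bedbench.eurostat_io import assemble_panel, parse_eurostat_tsv, read_population_csv
from bedbench.indicators import ActivityInput, compute_indicators
from bedbench.synthetic import (
    AVLOS_CODE,
    BEDS_CODE,
    DISCH_CODE,
    SyntheticConfig,
    design_benchmark,
    export_fixture,
    gen_panel,
    gen_region_at,
    gen_specialty_profile,
)

SMALL = SyntheticConfig(
    countries=(("AA", 6), ("BB", 6), ("CC", 8)),
    years=(2017,),
    seed=11,
)


class TestGenRegionAt:
    def test_green_centroid_placement(self):
        d, avlos = gen_region_at(0.80, 2.0, 100)
        assert d == pytest.approx(3650.0) and avlos == pytest.approx(8.0)
        ind = compute_indicators(ActivityInput(100, d, d * avlos))
        assert classify_bj(ind).zone is Zone.GREEN

    def test_red_placement(self):
        d, avlos = gen_region_at(0.70, 0.9, 100)
        ind = compute_indicators(ActivityInput(100, d, d * avlos))
        assert classify_bj(ind).zone is Zone.RED


class TestSpecialtyProfile:
    BENCH = Benchmark(
        specialties=("A", "B"),
        ref_avlos={"A": 4.0, "B": 10.0},
        ref_discharges={"A": 500.0, "B": 500.0},
    )

    def test_neutral_targets_return_benchmark_profile(self):
        profile = gen_specialty_profile(self.BENCH, 1.0, 1.0)
        shares = {p.specialty: p.discharges for p in profile}
        assert shares["A"] == pytest.approx(0.5) and shares["B"] == pytest.approx(0.5)
        assert [p.avlos for p in profile] == [4.0, 10.0]

    def test_recovers_worked_example_shares(self):
        # CMI = 8.8/7 against this benchmark is achieved by shares (0.2, 0.8)
        profile = gen_specialty_profile(self.BENCH, 8.8 / 7, 1.0, tol=1e-9)
        shares = {p.specialty: p.discharges for p in profile}
        assert shares["A"] == pytest.approx(0.2, abs=1e-6)
        assert shares["B"] == pytest.approx(0.8, abs=1e-6)

    def test_random_targets_hit_within_tolerance(self):
        bench = design_benchmark(8)
        rng = np.random.default_rng(5)
        lo = min(bench.ref_avlos.values()) / bench.overall_avlos
        hi = max(bench.ref_avlos.values()) / bench.overall_avlos
        for _ in range(50):
            cmi_t = rng.uniform(lo + 0.02, hi - 0.02)
            pi_t = rng.uniform(0.5, 1.5)
            profile = gen_specialty_profile(bench, cmi_t, pi_t, tol=1e-6)
            assert compute_cmi(profile, bench) == pytest.approx(cmi_t, abs=1e-6)
            # PI is exact by linearity of the formula in structure AvLOS
            assert compute_pi(profile, bench) == pytest.approx(pi_t, rel=1e-12)

    def test_unattainable_target_names_bounds(self):
        with pytest.raises(DomainError, match="attainable"):
            gen_specialty_profile(self.BENCH, 5.0, 1.0)


class TestGenPanel:
    def test_stratified_zone_counts_largest_remainder(self):
        cfg = SyntheticConfig(
            countries=(("AA", 20),),
            zone_mix=((Zone.GREEN, 0.5), (Zone.YELLOW, 0.25), (Zone.RED, 0.25)),
            years=(2017,),
            seed=0,
        )
        _, truths = gen_panel(cfg)
        counts = {z: sum(t.zone is z for t in truths) for z in Zone}
        assert counts == {Zone.GREEN: 10, Zone.YELLOW: 5, Zone.RED: 5}

    def test_same_seed_identical_panels(self):
        r1, t1 = gen_panel(SMALL)
        r2, t2 = gen_panel(SMALL)
        assert r1 == r2 and t1 == t2

    def test_noise_free_labels_are_exact(self):
        records, truths = gen_panel(SMALL)
        pooled = build_benchmark(records)
        by_region = {r.nuts2: r for r in records}
        for t in truths:
            rec = by_region[t.region]
            ind = compute_indicators(
                ActivityInput(
                    rec.beds,
                    rec.total_discharges,
                    sum(s.discharges * s.avlos for s in rec.specialties),
                )
            )
            assert classify_bj(ind).zone is t.zone is t.intended_zone
            cmi = compute_cmi(rec.specialties, pooled)
            pi = compute_pi(rec.specialties, pooled)
            assert cmi == pytest.approx(t.cmi, rel=1e-12)
            assert pi == pytest.approx(t.pi, rel=1e-12)

    def test_quadrant_mix_respected(self):
        _, truths = gen_panel(SMALL)
        mix = dict(SMALL.quadrant_mix)
        n = len(truths)
        for q, p in mix.items():
            count = sum(t.quadrant is q for t in truths)
            assert abs(count - p * n) < 1  # largest-remainder apportionment

    def test_noise_degrades_recovery_monotonically(self):
        """Agreement with the intended labels falls as noise grows."""
        rates = []
        for sd in (0.0, 0.08, 0.3):
            hits = total = 0
            for seed in (1, 2, 3):
                cfg = SyntheticConfig(
                    countries=(("AA", 10), ("BB", 10)),
                    years=(2017,),
                    noise_sd=sd,
                    seed=seed,
                )
                _, truths = gen_panel(cfg)
                hits += sum(
                    t.zone is t.intended_zone and t.quadrant is t.intended_quadrant
                    for t in truths
                )
                total += len(truths)
            rates.append(hits / total)
        assert rates[0] == 1.0
        assert rates[0] >= rates[1] >= rates[2]
        assert rates[2] < 1.0


class TestExportFixture:
    def test_round_trip_equals_original_panel(self, tmp_path):
        records, truths = gen_panel(SMALL)
        paths = export_fixture(records, tmp_path, truths)
        beds = parse_eurostat_tsv(paths["beds"], BEDS_CODE)
        disch = parse_eurostat_tsv(paths["discharges"], DISCH_CODE)
        avlos = parse_eurostat_tsv(paths["avlos"], AVLOS_CODE)
        pop = read_population_csv(paths["population"])
        rebuilt, skipped = assemble_panel(beds, disch, avlos, pop)
        assert not skipped
        assert sorted(rebuilt, key=lambda r: (r.nuts2, r.year)) == sorted(
            records, key=lambda r: (r.nuts2, r.year)
        )

    def test_missing_injection_writes_sentinels(self, tmp_path):
        records, _ = gen_panel(SMALL)
        paths = export_fixture(records, tmp_path, missing_rate=0.3, missing_seed=1)
        text = paths["discharges"].read_text()
        assert "\t:" in text or ":\t" in text
        # totals survive, so assembly still succeeds with partial coverage
        rebuilt, _ = assemble_panel(
            parse_eurostat_tsv(paths["beds"], BEDS_CODE),
            parse_eurostat_tsv(paths["discharges"], DISCH_CODE),
            parse_eurostat_tsv(paths["avlos"], AVLOS_CODE),
            read_population_csv(paths["population"]),
        )
        assert len(rebuilt) == len(records)
        assert any(r.coverage < 1 for r in rebuilt)
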