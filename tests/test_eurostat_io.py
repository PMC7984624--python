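"""Eurostat-dialect parsing, region filtering and panel assembly."""

import io

import pytest
from hypothesis import given
from hypothesis import strategies as st

from bedbench.casemix import SpecialtyStats
from bedbench.errors import AssemblyError, DomainError, ParseError
from bedbench.eurostat_io import (
    EurostatCell,
    RegionFilter,
    assemble_panel,
    default_region_filter,
    filter_regions,
    parse_eurostat_tsv,
    per_100k,
    read_long_csv,
    write_eurostat_tsv,
)

FIXTURE = (
    "unit,icd10,geo\\time\t2017\t2012\n"
    "NR,TOTAL,ITC4\t318\t342\n"
    "NR,TOTAL,DE11\t580 e\t:\n"
)


class TestParse:
    def test_one_cell_per_row_year(self):
        cells = parse_eurostat_tsv(FIXTURE, "HLTH_RS_BDSRG")
        assert len(cells) == 4
        itc4 = {c.year: c for c in cells if c.geo == "ITC4"}
        assert itc4[2017].value == 318 and itc4[2012].value == 342
        assert itc4[2017].dim("unit") == "NR" and itc4[2017].dim("icd10") == "TOTAL"

    def test_flagged_value_and_missing_sentinel(self):
        cells = {(c.geo, c.year): c for c in parse_eurostat_tsv(FIXTURE, "X")}
        flagged = cells[("DE11", 2017)]
        assert flagged.value == 580 and flagged.flags == frozenset("e")
        missing = cells[("DE11", 2012)]
        assert missing.value is None and missing.flags == frozenset()

    @pytest.mark.parametrize(
        "text, fragment",
        [
            ("unit,geo\t2017\nNR,IT\t1\n", "header"),  # no \time suffix
            ("unit,geo\\time\tabc\nNR,IT\t1\n", "header"),  # non-integer year
            ("unit,geo\\time\t2017\nNR,IT\tx9\n", "line 2"),  # bad token
            ("unit,geo\\time\t2017\nNR,IT,Z9\t3\n", "line 2"),  # dim mismatch
        ],
    )
    def test_malformed_inputs_name_the_location(self, text, fragment):
        with pytest.raises(ParseError, match=fragment):
            parse_eurostat_tsv(text, "X")


def _cells_strategy():
    geo = st.sampled_from(["DE11", "ITC4", "ES51", "FRK2"])
    year = st.sampled_from([2012, 2017])
    value = st.one_of(
        st.none(),
        st.integers(0, 10_000).map(float),
        st.floats(0, 1e5, allow_nan=False).map(lambda v: float(repr(v))),
    )
    flags = st.sets(st.sampled_from("bepud")).map(frozenset)
    cell = st.builds(
        lambda g, y, v, f: EurostatCell("DS", (("unit", "NR"), ("geo", g)), y, v, f),
        geo, year, value, flags,
    )
    return st.lists(cell, min_size=1, max_size=8, unique_by=lambda c: (c.geo, c.year))


class TestWrite:
    @given(_cells_strategy())
    def test_round_trip_identity(self, cells):
        buf = io.StringIO()
        write_eurostat_tsv(cells, buf)
        reparsed = parse_eurostat_tsv(buf.getvalue(), "DS")
        assert sorted(reparsed, key=lambda c: (c.geo, c.year)) == sorted(
            cells, key=lambda c: (c.geo, c.year)
        )

    def test_missing_value_serialised_as_sentinel(self):
        cell = EurostatCell("DS", (("geo", "DE11"),), 2017, None)
        buf = io.StringIO()
        write_eurostat_tsv([cell], buf)
        assert buf.getvalue().splitlines()[1] == "DE11\t:"

    def test_heterogeneous_dimension_sets_rejected(self):
        a = EurostatCell("DS", (("geo", "DE11"),), 2017, 1.0)
        b = EurostatCell("DS", (("unit", "NR"), ("geo", "DE11")), 2017, 1.0)
        with pytest.raises(DomainError):
            write_eurostat_tsv([a, b], io.StringIO())


class TestLongCsv:
    def test_reads_dialect_equivalent_cells(self):
        csv = "unit,icd10,geo,year,value\nNR,TOTAL,ITC4,2017,318\nNR,TOTAL,ITC4,2012,:\n"
        cells = read_long_csv(io.StringIO(csv), "DS")
        assert cells[0].value == 318 and cells[1].value is None
        assert cells[0].geo == "ITC4"


class TestFilterRegions:
    def _mk(self, geo):
        return EurostatCell("DS", (("geo", geo),), 2017, 1.0)

    def test_ceuta_melilla_excluded(self):
        cells = [self._mk(g) for g in ("ES63", "ES64", "ES11")]
        kept = filter_regions(cells, default_region_filter())
        assert [c.geo for c in kept] == ["ES11"]

    def test_french_overseas_dropped_corse_kept(self):
        cells = [self._mk(g) for g in ("FRY1", "FRA2", "FR91", "FRM0")]
        kept = filter_regions(cells, default_region_filter())
        assert [c.geo for c in kept] == ["FRM0"]  # Corse

    def test_national_aggregates_dropped(self):
        cells = [self._mk("DE"), self._mk("DE11")]
        kept = filter_regions(cells, default_region_filter())
        assert [c.geo for c in kept] == ["DE11"]

    def test_idempotent_and_order_preserving(self):
        cells = [self._mk(g) for g in ("IT", "ITC4", "ES63", "DE11", "XX11")]
        once = filter_regions(cells, default_region_filter())
        assert filter_regions(once, default_region_filter()) == once
        assert [c.geo for c in once] == ["ITC4", "DE11"]


def _cell(code, dims, year, value):
    return EurostatCell(code, dims, year, value)


def _fixture_cells(missing_avlos_chapter=False, missing_beds_geo=None):
    geos = ["DE11", "ES11", "ITC4"]
    beds, disch, avlos = [], [], []
    for geo in geos:
        for year in (2012, 2017):
            if geo != missing_beds_geo:
                beds.append(_cell("B", (("unit", "NR"), ("geo", geo)), year, 500.0))
            for icd, d, a in (("TOTAL", 400.0, 8.0), ("CH01", 100.0, 2.0), ("CH02", 300.0, 10.0)):
                disch.append(
                    _cell("D", (("unit", "NR"), ("icd10", icd), ("geo", geo)), year, d)
                )
                blank = missing_avlos_chapter and geo == "DE11" and year == 2017 and icd == "CH02"
                avlos.append(
                    _cell(
                        "A",
                        (("unit", "DAY"), ("icd10", icd), ("geo", geo)),
                        year,
                        None if blank else a,
                    )
                )
    pop = {(g, y): 1_000_000.0 for g in geos for y in (2012, 2017)}
    return beds, disch, avlos, pop


class TestAssemble:
    def test_complete_inputs_give_one_record_per_region_year(self):
        records, skipped = assemble_panel(*_fixture_cells())
        assert len(records) == 6 and not skipped
        rec = next(r for r in records if r.nuts2 == "ITC4" and r.year == 2017)
        assert rec.beds == 500 and rec.total_discharges == 400
        assert {s.specialty for s in rec.specialties} == {"CH01", "CH02"}
        assert rec.coverage == 1.0

    def test_missing_chapter_avlos_shrinks_coverage_not_record(self):
        records, skipped = assemble_panel(*_fixture_cells(missing_avlos_chapter=True))
        rec = next(r for r in records if r.nuts2 == "DE11" and r.year == 2017)
        assert {s.specialty for s in rec.specialties} == {"CH01"}
        assert 0 < rec.coverage < 1
        assert not skipped

    def test_missing_beds_skips_region_with_report(self):
        records, skipped = assemble_panel(*_fixture_cells(missing_beds_geo="ES11"))
        assert all(r.nuts2 != "ES11" for r in records)
        assert {(s["geo"], s["year"]) for s in skipped} == {("ES11", 2012), ("ES11", 2017)}
        assert all("beds" in s["reason"] for s in skipped)

    def test_empty_intersection_raises(self):
        with pytest.raises(AssemblyError):
            assemble_panel([], [], [], {})

    def test_values_trace_to_inputs(self):
        """No field of a record is invented: each one matches an input cell."""
        beds, disch, avlos, pop = _fixture_cells()
        records, _ = assemble_panel(beds, disch, avlos, pop)
        disch_idx = {
            (c.geo, c.year, c.dim("icd10")): c.value for c in disch if c.value is not None
        }
        for r in records:
            assert r.total_discharges == disch_idx[(r.nuts2, r.year, "TOTAL")]
            for s in r.specialties:
                assert s.discharges == disch_idx[(r.nuts2, r.year, s.specialty)]


class TestPer100k:
    @pytest.mark.parametrize(
        "count, pop, expected",
        [(580, 100_000, 580.0), (0, 5, 0.0), (23_200, 4_000_000, 580.0)],
    )
    def test_rate(self, count, pop, expected):
        assert per_100k(count, pop) == pytest.approx(expected)

    def test_non_positive_population_rejected(self):
        with pytest.raises(DomainError):
            per_100k(1, 0)
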