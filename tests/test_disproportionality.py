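import math

import pytest
from hypothesis import given, strategies as st

from pvror.disproportionality import (
    STATINS,
    build_table,
    compute_signal,
    is_significant,
    remove_statin_reports,
    ror_ci,
    ror_point,
    round_half_up,
    solve_b,
    subgroup_tables,
    zero_cell_reason,
)
from pvror.exposure import default_dictionary
from pvror.model import ContingencyTable, DrugEntry, ReportFlags, SignalResult


class TestRorPoint:
    def test_symmetric_table_is_null(self):
        assert ror_point(ContingencyTable(5, 5, 5, 5)) == 1.0

    def test_reconstructed_meropenem_table(self):
        assert round_half_up(ror_point(ContingencyTable(7, 665, 7678, 2326609))) == 3.19

    def test_zero_cell_undefined_without_correction(self):
        table = ContingencyTable(0, 10, 7685, 2327264)
        assert ror_point(table) is None
        assert zero_cell_reason(table) == "zero_cell:a"

    def test_haldane_anscombe_correction(self):
        table = ContingencyTable(0, 10, 10, 100)
        expected = (0.5 * 100.5) / (10.5 * 10.5)
        assert ror_point(table, correction=True) == pytest.approx(expected)


class TestRorCI:
    @pytest.mark.parametrize(
        "table,low,high",
        [
            (ContingencyTable(7, 665, 7678, 2326609), 1.51, 6.72),
            (ContingencyTable(5, 176, 7680, 2327098), 3.54, 20.94),
        ],
    )
    def test_reconstructed_tables_reproduce_published_bounds(self, table, low, high):
        got_low, got_high = ror_ci(table)
        assert round_half_up(got_low) == low
        assert round_half_up(got_high) == high

    def test_null_table_interval_contains_one(self):
        low, high = ror_ci(ContingencyTable(5, 5, 5, 5))
        assert low < 1.0 < high

    def test_undefined_with_zero_cell(self):
        assert ror_ci(ContingencyTable(3, 0, 5, 7)) is None


_cells = st.integers(1, 300)


@given(a=_cells, b=_cells, c=_cells, d=_cells)
def test_reciprocity_swapping_event_columns(a, b, c, d):
    """a<->b, c<->d maps ROR -> 1/ROR and (low, high) -> (1/high, 1/low)."""
    table = ContingencyTable(a, b, c, d)
    swapped = ContingencyTable(b, a, d, c)
    assert ror_point(swapped) == pytest.approx(1.0 / ror_point(table))
    low, high = ror_ci(table)
    s_low, s_high = ror_ci(swapped)
    assert s_low == pytest.approx(1.0 / high)
    assert s_high == pytest.approx(1.0 / low)


@given(a=_cells, b=_cells, c=_cells, d=_cells, k=st.integers(2, 10))
def test_ci_brackets_point_and_narrows_with_scale(a, b, c, d, k):
    table = ContingencyTable(a, b, c, d)
    point = ror_point(table)
    low, high = ror_ci(table)
    assert low <= point <= high
    scaled = ContingencyTable(k * a, k * b, k * c, k * d)
    s_low, s_high = ror_ci(scaled)
    assert math.log(s_high) - math.log(s_low) < math.log(high) - math.log(low)


class TestSolveB:
    @pytest.mark.parametrize(
        "a,c,n,ror,expected",
        [
            (7, 7678, 2_334_959, 3.19, 665),
            (12, 7673, 2_334_959, 2.61, 1394),
            (1, 1, 4, 1.0, 1),
        ],
    )
    def test_examples(self, a, c, n, ror, expected):
        assert solve_b(a, c, n, ror) == expected

    @given(a=st.integers(1, 50), b=st.integers(1, 2000), c=st.integers(1, 2000), d=st.integers(1000, 10**6))
    def test_recovers_b_from_exact_ror(self, a, b, c, d):
        table = ContingencyTable(a, b, c, d)
        assert solve_b(a, c, table.n, ror_point(table)) == b

    def test_no_positive_solution_is_error(self):
        with pytest.raises(ValueError):
            solve_b(5, 5, 12, 1000.0)
        with pytest.raises(ValueError):
            solve_b(0, 5, 100, 2.0)


class TestSignificance:
    def _result(self, ci_low, ci_high=30.0, ror=None):
        if ror is None:
            ror = math.sqrt(ci_low * ci_high)
        return SignalResult(
            drug="X",
            variant="crude",
            table=ContingencyTable(1, 1, 1, 1),
            ror=ror,
            ci_low=ci_low,
            ci_high=ci_high,
            significant=ci_low > 1.0,
        )

    def test_lower_bound_above_one_is_significant(self):
        assert is_significant(self._result(1.51))

    def test_lower_bound_below_one_is_not(self):
        assert not is_significant(self._result(0.54))

    def test_exactly_one_is_not_significant(self):
        assert not is_significant(self._result(1.0))

    def test_undefined_estimate_is_not_significant(self):
        result = compute_signal("X", "crude", ContingencyTable(0, 5, 5, 5))
        assert result.ror is None and result.reason == "zero_cell:a"
        assert not is_significant(result)


class TestBuildTable:
    def test_direct_count(self):
        flags = [ReportFlags(str(i), is_event=i < 3) for i in range(10)]
        exposures = [
            frozenset({"X"}) if i in (0, 1, 3, 4, 5) else frozenset() for i in range(10)
        ]
        assert build_table(flags, exposures, "X") == ContingencyTable(2, 3, 1, 4)

    def test_unexposed_drug_gives_zero_exposed_cells(self):
        flags = [ReportFlags("1", True), ReportFlags("2", False)]
        exposures = [frozenset(), frozenset()]
        assert build_table(flags, exposures, "X") == ContingencyTable(0, 0, 1, 1)

    def test_cells_partition_the_report_set(self):
        flags = [ReportFlags(str(i), is_event=i % 4 == 0) for i in range(57)]
        exposures = [frozenset({"X"}) if i % 3 == 0 else frozenset() for i in range(57)]
        assert build_table(flags, exposures, "X").n == 57

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="same report set"):
            build_table([ReportFlags("1", True)], [], "X")


class TestSubgroupTables:
    def _fixture(self):
        # 7 exposed event reports, 4 with the condition; plus background.
        flags, exposures = [], []
        for i in range(7):
            flags.append(ReportFlags(f"e{i}", is_event=True, has_hepatic=i < 4))
            exposures.append(frozenset({"MEROPENEM"}))
        for i in range(13):
            flags.append(ReportFlags(f"b{i}", is_event=False, has_hepatic=i < 2))
            exposures.append(frozenset({"MEROPENEM"}) if i < 5 else frozenset())
        for i in range(10):
            flags.append(ReportFlags(f"u{i}", is_event=i < 3, has_hepatic=False))
            exposures.append(frozenset())
        return flags, exposures

    def test_stratum_a_cells_split_the_event_reports(self):
        flags, exposures = self._fixture()
        with_table, without_table = subgroup_tables(flags, exposures, "MEROPENEM", "hepatic")
        assert with_table.a == 4 and without_table.a == 3
        # comparator = all other reports, including the drug's other stratum
        assert with_table.n == without_table.n == len(flags)
        assert with_table.a + with_table.b + without_table.a + without_table.b == 12

    def test_condition_absent_everywhere(self):
        flags = [ReportFlags(str(i), is_event=i == 0) for i in range(6)]
        exposures = [frozenset({"X"}) if i < 2 else frozenset() for i in range(6)]
        with_table, _ = subgroup_tables(flags, exposures, "X", "aki")
        assert with_table.a == with_table.b == 0

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="condition"):
            subgroup_tables([], [], "X", "renal")


class TestRemoveStatinReports:
    def test_any_role_code_triggers_removal(self, make_report):
        dictionary = default_dictionary()
        concomitant = make_report(
            primary_id="1", drugs=(DrugEntry("PS", "MERREM"), DrugEntry("C", "ZOCOR"))
        )
        suspect = make_report(primary_id="2", drugs=(DrugEntry("PS", "LIPITOR"),))
        clean = make_report(primary_id="3", drugs=(DrugEntry("PS", "MERREM"),))
        survivors = remove_statin_reports([concomitant, suspect, clean], STATINS, dictionary)
        assert [r.primary_id for r in survivors] == ["3"]
        assert survivors[0] == clean

    def test_planted_co_reporting_matches_manifest(self, tmp_path):
        from pvror.dedup import deduplicate
        from pvror.faers_io import assemble_reports, read_table
        from pvror.synthetic import DrugSpec, GeneratorConfig, generate

        config = GeneratorConfig(
            n_cases=400,
            drug_catalog={"MEROPENEM": DrugSpec(0.3, 1.0)},
            statin_corr=0.3,
            statin_bg_rate=0.3,
            seed=11,
        )
        manifest = generate(config, tmp_path)
        reports = deduplicate(
            assemble_reports(
                read_table(tmp_path / "demo.txt", "demo"),
                read_table(tmp_path / "drug.txt", "drug"),
                read_table(tmp_path / "reac.txt", "reac"),
            )
        )
        survivors = remove_statin_reports(reports, STATINS, default_dictionary())
        expected = int((~manifest.truth()["statin"]).sum())
        assert len(survivors) == expected
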