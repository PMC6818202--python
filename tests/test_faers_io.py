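import datetime

import pytest
from hypothesis import given, strategies as st

from pvror.faers_io import (
    RawDemoRow,
    RawDrugRow,
    RawReacRow,
    assemble_reports,
    parse_faers_date,
    read_table,
    read_term_list,
    write_table,
)

DEMO_HEADER = "primaryid$caseid$caseversion$fda_dt$age$age_cod$sex$event_dt$reporter_country"


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


class TestReadDemo:
    def test_row_count_matches_data_lines(self, tmp_path):
        path = tmp_path / "demo.txt"
        write_lines(
            path,
            [
                DEMO_HEADER,
                "10000011$1000001$1$20150601$45$YR$F$20150501$US",
                "10000021$1000002$1$20160601$60$YR$M$20160501$JP",
            ],
        )
        rows = read_table(path, "demo")
        assert len(rows) == 2
        assert rows[0] == RawDemoRow(
            primary_id="10000011",
            case_id="1000001",
            case_version=1,
            receipt_date=datetime.date(2015, 6, 1),
            age=(45.0, "YR"),
            sex="F",
            event_date=datetime.date(2015, 5, 1),
            reporter_country="US",
        )

    @pytest.mark.parametrize("raw", ["2015", "201506", "", "20151332", "APRIL"])
    def test_partial_or_invalid_dates_become_missing(self, tmp_path, raw):
        path = tmp_path / "demo.txt"
        write_lines(path, [DEMO_HEADER, f"10000011$1000001$1$20150601$45$YR$F${raw}$US"])
        (row,) = read_table(path, "demo")
        assert row.event_date is None

    def test_unparseable_age_becomes_missing(self, tmp_path):
        path = tmp_path / "demo.txt"
        write_lines(path, [DEMO_HEADER, "10000011$1000001$1$20150601$FORTY$YR$F$20150501$US"])
        (row,) = read_table(path, "demo")
        assert row.age is None

    def test_duplicate_primaryid_is_hard_error(self, tmp_path):
        path = tmp_path / "demo.txt"
        write_lines(
            path,
            [
                DEMO_HEADER,
                "10000011$1000001$1$20150601$45$YR$F$20150501$US",
                "10000011$1000001$2$20150701$45$YR$F$20150501$US",
            ],
        )
        with pytest.raises(ValueError, match="duplicate primaryid"):
            read_table(path, "demo")

    def test_missing_required_column_names_the_column(self, tmp_path):
        path = tmp_path / "demo.txt"
        write_lines(path, ["primaryid$caseid$caseversion", "10000011$1000001$1"])
        with pytest.raises(ValueError, match="fda_dt"):
            read_table(path, "demo")

    def test_empty_file_yields_empty_sequence(self, tmp_path, caplog):
        path = tmp_path / "demo.txt"
        path.write_text("", encoding="utf-8")
        with caplog.at_level("WARNING"):
            assert read_table(path, "demo") == []
        assert any("empty" in rec.message for rec in caplog.records)


class TestReadDrugReac:
    def test_ps_role_and_case_normalization(self, tmp_path):
        path = tmp_path / "drug.txt"
        write_lines(
            path,
            [
                "primaryid$drug_seq$role_cod$drugname$prod_ai",
                "10000011$1$ps$ cubicin $DAPTOMYCIN",
                "10000011$2$C$lipitor$",
            ],
        )
        rows = read_table(path, "drug")
        assert [r.role_code for r in rows] == ["PS", "C"]
        assert rows[0].verbatim_name == "CUBICIN"
        assert rows[1].active_ingredient is None

    def test_unknown_role_is_logged_skip_not_error(self, tmp_path, caplog):
        path = tmp_path / "drug.txt"
        write_lines(
            path,
            [
                "primaryid$drug_seq$role_cod$drugname$prod_ai",
                "10000011$1$XX$CUBICIN$",
                "10000011$2$PS$CUBICIN$",
            ],
        )
        with caplog.at_level("WARNING"):
            rows = read_table(path, "drug")
        assert len(rows) == 1 and rows[0].role_code == "PS"
        assert any("skipped" in rec.message for rec in caplog.records)

    def test_reac_rows_trimmed_uppercased(self, tmp_path):
        path = tmp_path / "reac.txt"
        write_lines(path, ["primaryid$pt", "10000011$ Rhabdomyolysis ", "10000011$PYREXIA"])
        rows = read_table(path, "reac")
        assert [r.preferred_term for r in rows] == ["RHABDOMYOLYSIS", "PYREXIA"]

    def test_legacy_dialect_needs_column_map(self, tmp_path):
        path = tmp_path / "reac.txt"
        write_lines(path, ["isr$pt_legacy", "1$PYREXIA"])
        with pytest.raises(ValueError, match="column_map"):
            read_table(path, "reac", dialect="legacy")
        rows = read_table(
            path, "reac", dialect="legacy", column_map={"primaryid": "isr", "pt": "pt_legacy"}
        )
        assert rows == [RawReacRow(primary_id="1", preferred_term="PYREXIA")]


class TestTermList:
    def test_paper_style_aki_list(self, tmp_path):
        path = tmp_path / "terms.txt"
        write_lines(
            path,
            [
                "# acute renal failure terms",
                "Renal failure acute",
                "Acute kidney injury",
                "Anuria",
                "Oliguria",
            ],
        )
        terms = read_term_list(path)
        assert len(terms) == 4
        assert "RENAL FAILURE ACUTE" in terms

    def test_duplicates_collapse_and_single_term(self, tmp_path):
        path = tmp_path / "terms.txt"
        write_lines(path, ["Rhabdomyolysis", "RHABDOMYOLYSIS", "  rhabdomyolysis "])
        assert read_term_list(path) == frozenset({"RHABDOMYOLYSIS"})

    def test_empty_term_list_is_hard_error(self, tmp_path):
        path = tmp_path / "terms.txt"
        write_lines(path, ["# only a comment", ""])
        with pytest.raises(ValueError, match="no terms"):
            read_term_list(path)


@pytest.mark.parametrize(
    "value,expected",
    [("20150601", datetime.date(2015, 6, 1)), ("2015", None), ("20150230", None), (" ", None)],
)
def test_parse_faers_date(value, expected):
    assert parse_faers_date(value) == expected


_ids = st.integers(1, 10_000).map(lambda i: f"9{i:05d}1")
_upper = st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ", min_size=1, max_size=12)
_dates = st.one_of(st.none(), st.dates(datetime.date(2004, 1, 1), datetime.date(2017, 12, 31)))


@st.composite
def demo_rows(draw):
    age = draw(st.one_of(st.none(), st.tuples(st.integers(0, 120).map(float), st.just("YR"))))
    return RawDemoRow(
        primary_id=draw(_ids),
        case_id=draw(_ids),
        case_version=draw(st.one_of(st.none(), st.integers(1, 9))),
        receipt_date=draw(_dates),
        age=age,
        sex=draw(st.sampled_from([None, "M", "F", "UNK"])),
        event_date=draw(_dates),
        reporter_country=draw(st.one_of(st.none(), _upper)),
    )


@st.composite
def drug_rows(draw):
    return RawDrugRow(
        primary_id=draw(_ids),
        drug_seq=draw(st.integers(1, 9)),
        role_code=draw(st.sampled_from(["PS", "SS", "C", "I"])),
        verbatim_name=draw(_upper),
        active_ingredient=draw(st.one_of(st.none(), _upper)),
    )


class TestRoundTrip:
    """Writing a parsed table and re-reading it yields identical rows."""

    @given(st.lists(demo_rows(), max_size=20, unique_by=lambda r: r.primary_id))
    def test_demo(self, tmp_path_factory, rows):
        path = tmp_path_factory.mktemp("rt") / "demo.txt"
        write_table(rows, path, "demo")
        assert read_table(path, "demo") == rows

    @given(st.lists(drug_rows(), max_size=20))
    def test_drug(self, tmp_path_factory, rows):
        path = tmp_path_factory.mktemp("rt") / "drug.txt"
        write_table(rows, path, "drug")
        assert read_table(path, "drug") == rows

    @given(st.lists(st.builds(RawReacRow, primary_id=_ids, preferred_term=_upper), max_size=20))
    def test_reac(self, tmp_path_factory, rows):
        path = tmp_path_factory.mktemp("rt") / "reac.txt"
        write_table(rows, path, "reac")
        assert read_table(path, "reac") == rows


class TestAssemble:
    def test_join_and_reaction_set_semantics(self):
        demo = [
            RawDemoRow("1", "C1", 1, None, None, None, None, None),
            RawDemoRow("2", "C2", 1, None, None, None, None, None),
        ]
        drugs = [
            RawDrugRow("1", 2, "C", "LIPITOR", None),
            RawDrugRow("1", 1, "PS", "CUBICIN", "DAPTOMYCIN"),
        ]
        reacs = [
            RawReacRow("1", "RHABDOMYOLYSIS"),
            RawReacRow("1", "RHABDOMYOLYSIS"),
            RawReacRow("1", "PYREXIA"),
        ]
        reports = assemble_reports(demo, drugs, reacs)
        assert [r.primary_id for r in reports] == ["1", "2"]
        # drug order follows drug_seq; repeated PTs collapse to a set
        assert [d.verbatim_name for d in reports[0].drugs] == ["CUBICIN", "LIPITOR"]
        assert reports[0].reactions == frozenset({"RHABDOMYOLYSIS", "PYREXIA"})
        assert reports[1].drugs == () and reports[1].reactions == frozenset()

    def test_orphan_rows_dropped_with_warning(self, caplog):
        demo = [RawDemoRow("1", "C1", 1, None, None, None, None, None)]
        with caplog.at_level("WARNING"):
            reports = assemble_reports(
                demo, [RawDrugRow("99", 1, "PS", "X", None)], [RawReacRow("99", "PYREXIA")]
            )
        assert reports[0].drugs == ()
        assert sum("unknown primaryid" in rec.message for rec in caplog.records) == 2
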