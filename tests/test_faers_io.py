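"""Reader, de-duplication, case-extraction and normalization behaviour."""

import datetime

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from faerspv import faers_io, synth
from faerspv.errors import ConfigurationError, SchemaError
from faerspv.faers_io import (
    CaseReport,
    DrugEntry,
    assemble_reports,
    deduplicate,
    extract_cases,
    load_atc_table,
    load_corpus,
    normalize_drugs,
    read_ascii_table,
)

SCHEMA = {"DEMO": ["primaryid", "caseid", "age", "sex"]}


def _write(tmp_path, text, name="DEMO24Q1.txt"):
    path = tmp_path / name
    path.write_text(text, encoding="latin-1")
    return path


class TestReadAsciiTable:
    def test_splits_dollar_delimited_fields(self, tmp_path):
        path = _write(tmp_path, "primaryid$caseid$age$sex\n1001$500$56$F\n")
        rows, log = read_ascii_table(path, "DEMO", schema=SCHEMA)
        assert len(rows) == 1 and log.n_rows == 1
        assert rows[0].primaryid == "1001" and rows[0].caseid == "500"
        assert rows[0].payload == {"primaryid": "1001", "caseid": "500", "age": "56", "sex": "F"}

    def test_empty_fields_become_absent(self, tmp_path):
        path = _write(tmp_path, "primaryid$caseid$age$sex\n1001$500$$\n")
        rows, _ = read_ascii_table(path, "DEMO", schema=SCHEMA)
        assert "age" not in rows[0].payload and "sex" not in rows[0].payload

    def test_malformed_line_skipped_and_counted(self, tmp_path):
        path = _write(tmp_path, "primaryid$caseid$age$sex\n1$2$3\n1001$500$56$F\n")
        rows, log = read_ascii_table(path, "DEMO", schema=SCHEMA)
        assert len(rows) == 1
        assert log.n_skipped == 1 and log.skipped_lines == [2]

    def test_missing_columns_raise_schema_error(self, tmp_path):
        path = _write(tmp_path, "primaryid$caseid\n1$2\n")
        with pytest.raises(SchemaError, match="age"):
            read_ascii_table(path, "DEMO", schema=SCHEMA)

    def test_unreadable_file_raises(self, tmp_path):
        with pytest.raises(OSError):
            read_ascii_table(tmp_path / "nope.txt", "DEMO", schema=SCHEMA)


def _rep(caseid, version_date, primaryid):
    return CaseReport(primaryid=primaryid, caseid=caseid, version_date=version_date)


class TestDeduplicate:
    def test_latest_version_retained(self):
        reports = [_rep("7", "20200101", "71"), _rep("7", "20210101", "72")]
        out, log = deduplicate(reports)
        assert [r.primaryid for r in out] == ["72"]
        assert log.n_removed == 1

    def test_distinct_caseids_all_retained(self):
        reports = [_rep("1", "20200101", "11"), _rep("2", "20200101", "21")]
        out, _ = deduplicate(reports)
        assert len(out) == 2

    def test_tie_broken_by_numeric_primaryid(self):
        # zero-padded comparison: 100 > 99 despite "100" < "99" lexically
        reports = [_rep("7", "20200101", "99"), _rep("7", "20200101", "100")]
        out, _ = deduplicate(reports)
        assert out[0].primaryid == "100"

    def test_empty_input(self):
        out, log = deduplicate([])
        assert out == [] and log.n_in == 0

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 5),  # caseid pool
                st.sampled_from(["20190101", "20200101", "20210101"]),
                st.integers(1, 999),
            ),
            max_size=30,
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_idempotent(self, triples):
        reports = [_rep(str(c), v, str(p)) for c, v, p in triples]
        once, _ = deduplicate(reports)
        twice, _ = deduplicate(once)
        assert once == twice

    def test_duplicate_injection_bookkeeping(self, small_corpus):
        _, reports, truth = small_corpus
        out, log = deduplicate(reports)
        assert len(out) == truth.n_unique_reports
        assert log.n_removed == truth.n_duplicates
        assert len({r.caseid for r in out}) == len(out)


class TestExtractCases:
    def _report(self, pts, role="PS"):
        return CaseReport(
            primaryid="1", caseid="1",
            drugs=[DrugEntry(drugname_raw="X", role=role)],
            reaction_pts=set(pts),
        )

    def test_pt_match_with_ps_drug_is_case(self):
        assert extract_cases([self._report({"Hepatotoxicity", "Nausea"})], "hepatotoxicity") == [True]

    def test_concomitant_only_is_not_a_case(self):
        assert extract_cases([self._report({"Hepatotoxicity"}, role="C")], "Hepatotoxicity") == [False]

    def test_substring_pt_does_not_match(self):
        assert extract_cases([self._report({"Hepatotoxicity aggravated"})], "Hepatotoxicity") == [False]

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            extract_cases([], "  ")

    def test_monotone_under_noncase_removal(self, small_analysis):
        _, reports, flags, _ = small_analysis
        kept = [r for r, f in zip(reports, flags) if f]
        assert extract_cases(kept, "Hepatotoxicity") == [True] * len(kept)

    def test_flags_match_generator_truth(self, small_analysis):
        _, reports, flags, truth = small_analysis
        assert sum(flags) == truth.n_cases


class TestNormalizeDrugs:
    def _table(self):
        return load_atc_table(
            pd.DataFrame(
                [{"drugname": "mercaptopurine", "norm_name": "mercaptopurine",
                  "atc_code": "L01BB02"}]
            )
        )

    def test_trailing_punctuation_and_case_folded(self):
        rep = CaseReport(
            primaryid="1", caseid="1",
            drugs=[DrugEntry(drugname_raw="MERCAPTOPURINE.", role="PS")],
        )
        log = normalize_drugs([rep], self._table())
        assert rep.drugs[0].drugname_norm == "mercaptopurine"
        assert rep.drugs[0].atc_code == "L01BB02"
        assert log.n_unmapped == 0

    def test_unmapped_left_absent_and_tallied(self):
        rep = CaseReport(
            primaryid="1", caseid="1",
            drugs=[DrugEntry(drugname_raw="UNKNOWN DRUG 12", role="PS")],
        )
        log = normalize_drugs([rep], self._table())
        assert rep.drugs[0].drugname_norm is None
        assert log.n_unmapped == 1 and log.unmapped_names["UNKNOWN DRUG 12"] == 1

    def test_conflicting_mapping_rejected(self):
        df = pd.DataFrame(
            [
                {"drugname": "Foo", "norm_name": "foo", "atc_code": "A1"},
                {"drugname": "FOO ", "norm_name": "foo", "atc_code": "A2"},
            ]
        )
        with pytest.raises(ConfigurationError):
            load_atc_table(df)

    def test_generator_roster_fully_mapped(self, small_corpus):
        cfg, reports, _ = small_corpus
        log = normalize_drugs(reports, load_atc_table(synth.make_atc_table(cfg)))
        assert log.n_unmapped == 0


class TestAssembly:
    def test_age_unit_codes_converted_to_years(self, tmp_path):
        header = "$".join(faers_io.TABLE_SCHEMAS["DEMO"])
        blank = {c: "" for c in faers_io.TABLE_SCHEMAS["DEMO"]}
        rows = []
        for pid, age, cod in [("1", "56", "YR"), ("2", "6", "DEC"), ("3", "18", "MON"),
                              ("4", "26", "WK"), ("5", "365.25", "DY"), ("6", "130", "YR")]:
            row = dict(blank, primaryid=pid, caseid=pid, age=age, age_cod=cod)
            rows.append("$".join(row[c] for c in faers_io.TABLE_SCHEMAS["DEMO"]))
        path = _write(tmp_path, header + "\n" + "\n".join(rows) + "\n")
        parsed, _ = read_ascii_table(path, "DEMO")
        reports = assemble_reports({"DEMO": parsed})
        ages = [r.age_years for r in reports]
        assert ages[0] == 56 and ages[1] == 60
        assert ages[2] == pytest.approx(1.5) and ages[3] == pytest.approx(0.5)
        assert ages[4] == pytest.approx(1.0)
        assert ages[5] is None  # implausible (>120 years) mapped to absent

    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_corpus_round_trip_exact(self, tmp_path, seed):
        """write_corpus -> read_ascii_table -> assemble reproduces every field."""
        cfg = synth.demo_config(n_reports=300, seed=seed)
        reports, _ = synth.generate(cfg)
        synth.write_corpus(reports, tmp_path / "corpus")
        tables, _ = load_corpus(tmp_path / "corpus")
        back = assemble_reports(tables)
        key = lambda r: r.primaryid.zfill(20)
        assert sorted(back, key=key) == sorted(reports, key=key)

    def test_event_date_parsing_matches_raw(self, small_corpus):
        _, reports, _ = small_corpus
        for rep in reports[:200]:
            if rep.event_dt is not None:
                assert isinstance(rep.event_dt, datetime.date)
                assert rep.event_dt_raw is not None and len(rep.event_dt_raw) == 8
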