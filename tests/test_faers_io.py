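import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvsignal import faers_io


def _write(tmp_path, name, lines):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadQuarter:
    def test_row_count_equals_data_lines(self, tmp_path):
        path = _write(tmp_path, "DEMO.txt", [
            "primaryid$caseid$fda_dt$sex$age$age_cod",
            "11$1$20200101$F$40$YR",
            "21$2$20210315$M$65$YR",
        ])
        frame, issues = faers_io.read_quarter(path, "demo")
        assert len(frame) == 2
        assert issues["malformed_lines"] == 0

    def test_role_cod_case_normalized(self, tmp_path):
        path = _write(tmp_path, "DRUG.txt", [
            "primaryid$drugname$role_cod",
            "11$GABAPENTIN$ps",
        ])
        frame, _ = faers_io.read_quarter(path, "drug")
        assert frame.loc[0, "role_cod"] == "PS"

    def test_invalid_calendar_date_flagged_missing(self, tmp_path):
        # month 13 does not exist -> value kept as row, date flagged missing
        path = _write(tmp_path, "DEMO.txt", [
            "primaryid$caseid$fda_dt",
            "11$1$20251301",
            "21$2$20240229",  # 2024 is a leap year: valid
        ])
        frame, issues = faers_io.read_quarter(path, "demo")
        assert len(frame) == 2
        assert issues["invalid_fda_dt"] == 1
        assert np.isnan(frame.loc[0, "fda_dt"])
        assert frame.loc[1, "fda_dt"] == 20240229

    def test_missing_required_column_is_hard_error(self, tmp_path):
        path = _write(tmp_path, "REAC.txt", ["primaryid$caseid", "11$1"])
        with pytest.raises(ValueError, match="pt"):
            faers_io.read_quarter(path, "reac")

    def test_malformed_lines_counted_then_fatal_above_threshold(self, tmp_path):
        lines = ["primaryid$caseid", "11$1", "badline"]
        path = _write(tmp_path, "DEMO.txt", lines)
        frame, issues = faers_io.read_quarter(path, "demo", max_error_rate=0.6)
        assert len(frame) == 1 and issues["malformed_lines"] == 1
        with pytest.raises(ValueError, match="malformed"):
            faers_io.read_quarter(path, "demo", max_error_rate=0.2)

    def test_unknown_outcome_codes_preserved(self, tmp_path):
        path = _write(tmp_path, "OUTC.txt", [
            "primaryid$outc_cod", "11$HO", "21$XX",
        ])
        frame, issues = faers_io.read_quarter(path, "outc")
        assert issues["unknown_outc_cod"] == 1
        assert list(frame["outc_cod"]) == ["HO", "XX"]


@pytest.mark.parametrize(
    "age, cod, expected",
    [
        (730, "DY", 730 / 365.25),
        (6, "DEC", 60.0),
        (18, "MON", 1.5),
        (26, "WK", 26 / 52.1775),
        (8766, "HR", 1.0),
        (45, "YR", 45.0),
        (45, None, None),    # unit missing: conservative, not assumed years
        (45, "??", None),
        (-3, "YR", None),    # negative age
        (None, "YR", None),
    ],
)
def test_convert_age(age, cod, expected):
    result = faers_io.convert_age(age, cod)
    if expected is None:
        assert result is None
    else:
        assert result == pytest.approx(expected, rel=1e-12)


class TestDeduplicate:
    def _demo(self, rows):
        return pd.DataFrame(rows, columns=["primaryid", "caseid", "fda_dt"])

    def test_latest_fda_dt_survives(self):
        out = faers_io.deduplicate(
            self._demo([("1", "C1", 20200101), ("2", "C1", 20210101)])
        )
        assert list(out["primaryid"]) == ["2"]

    def test_fda_dt_tie_broken_by_higher_primaryid(self):
        out = faers_io.deduplicate(
            self._demo([("2", "C1", 20200101), ("1", "C1", 20200101)])
        )
        assert list(out["primaryid"]) == ["2"]

    def test_numeric_primaryid_comparison_not_lexicographic(self):
        out = faers_io.deduplicate(
            self._demo([("9", "C1", 20200101), ("10", "C1", 20200101)])
        )
        assert list(out["primaryid"]) == ["10"]

    def test_distinct_cases_untouched(self):
        out = faers_io.deduplicate(
            self._demo([("1", "C1", 20200101), ("2", "C2", 20200101)])
        )
        assert len(out) == 2

    def test_dated_report_beats_undated(self):
        out = faers_io.deduplicate(
            self._demo([("5", "C1", np.nan), ("1", "C1", 20190101)])
        )
        assert list(out["primaryid"]) == ["1"]

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 99),            # primaryid
                st.integers(1, 5),             # caseid
                st.sampled_from([20200101.0, 20210101.0, np.nan]),
            ),
            min_size=1,
            max_size=20,
            unique_by=lambda t: t[0],
        )
    )
    def test_idempotent_and_one_row_per_case(self, rows):
        demo = pd.DataFrame(
            [(str(p), f"C{c}", d) for p, c, d in rows],
            columns=["primaryid", "caseid", "fda_dt"],
        )
        once = faers_io.deduplicate(demo)
        assert len(once) == demo["caseid"].nunique()
        twice = faers_io.deduplicate(once)
        pd.testing.assert_frame_equal(once, twice)


class TestLinkCase:
    def _tables(self):
        demo = pd.DataFrame(
            {"primaryid": ["2"], "caseid": ["C1"], "fda_dt": [20210101.0],
             "sex": ["F"], "age_years": [40.0]}
        )
        drug = pd.DataFrame(
            {"primaryid": ["2", "2", "1"],
             "drugname": ["GABAPENTIN", "IBUPROFEN", "GABAPENTIN"],
             "role_cod": ["PS", "C", "PS"]}
        )
        reac = pd.DataFrame(
            {"primaryid": ["2", "2", "2", "2", "1"],
             "pt": ["Osteopenia", "NAUSEA", "nausea ", "RASH", "FALL"]}
        )
        outc = pd.DataFrame({"primaryid": ["1"], "outc_cod": ["HO"]})
        return demo, drug, reac, outc

    def test_join_cardinality_and_orphan_drop(self):
        demo, drug, reac, outc = self._tables()
        cd = faers_io.link_case(demo, drug, reac, outc)
        assert cd.n_cases == 1
        assert len(cd.drugs) == 2           # rows for eliminated P1 dropped
        assert cd.meta["orphan_drug_rows_dropped"] == 1
        assert cd.meta["orphan_reac_rows_dropped"] == 1
        assert cd.meta["orphan_outc_rows_dropped"] == 1

    def test_reaction_set_semantics_and_uppercasing(self):
        demo, drug, reac, outc = self._tables()
        cd = faers_io.link_case(demo, drug, reac, outc)
        rep = next(cd.iter_reports())
        assert rep.reactions == frozenset({"OSTEOPENIA", "NAUSEA", "RASH"})

    def test_never_invents_cases(self):
        demo, drug, reac, outc = self._tables()
        cd = faers_io.link_case(demo, drug, reac, outc)
        demo_ids = set(demo["primaryid"])
        assert all(rep.primaryid in demo_ids for rep in cd.iter_reports())

    def test_zero_reaction_cases_retained_and_counted(self):
        demo = pd.DataFrame(
            {"primaryid": ["1", "2"], "caseid": ["C1", "C2"],
             "fda_dt": [np.nan, np.nan], "sex": ["UNK", "F"],
             "age_years": [np.nan, np.nan]}
        )
        drug = pd.DataFrame({"primaryid": ["1"], "drugname": ["X"],
                             "role_cod": ["PS"]})
        reac = pd.DataFrame({"primaryid": ["2"], "pt": ["RASH"]})
        cd = faers_io.link_case(demo, drug, reac,
                                pd.DataFrame(columns=["primaryid", "outc_cod"]))
        assert cd.n_cases == 2
        assert cd.meta["cases_without_reactions"] == 1


def test_intermediate_format_round_trip(small_case_data, tmp_path):
    path = tmp_path / "cases.csv"
    faers_io.write_cases(small_case_data, path)
    back = faers_io.read_cases(path)
    orig = {r.primaryid: r for r in small_case_data.iter_reports()}
    new = {r.primaryid: r for r in back.iter_reports()}
    assert orig.keys() == new.keys()
    for pid, rep in orig.items():
        got = new[pid]
        assert got.caseid == rep.caseid
        assert got.fda_dt == rep.fda_dt
        assert got.sex == rep.sex
        assert (got.age_years is None and rep.age_years is None) or (
            got.age_years == pytest.approx(rep.age_years, abs=0)
        )
        assert got.reactions == rep.reactions
        assert got.outcomes == rep.outcomes
        assert sorted(got.drugs) == sorted(rep.drugs)
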