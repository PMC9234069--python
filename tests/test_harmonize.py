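import numpy as np
import pandas as pd
import pytest

from cohortpheno.definitions import parse_condition
from cohortpheno.harmonize import (evaluate_touchscreen, harmonize_all,
                                   harmonize_death, harmonize_gp,
                                   harmonize_hesin, harmonize_self_report,
                                   load_harmonized, save_harmonized)
from cohortpheno.ukb_io import CatalogEntry, FieldCatalog


def _rec(rows, columns):
    df = pd.DataFrame(rows, columns=columns)
    df["identifier"] = df["identifier"].astype(np.int64)
    for c in columns:
        if c not in ("identifier",):
            df[c] = df[c].astype(str)
    return df


class TestHarmonizeHesin:
    def test_dates_and_epidur(self, settings):
        master = _rec([[9001, "0", "2010-01-01", "2010-01-11", "2010-01-01",
                        "2010-01-11"]],
                      ["identifier", "ins_index", "epistart", "epiend",
                       "admidate", "disdate"])
        diag = _rec([[9001, "0", "1", "I480", ""]],
                    ["identifier", "ins_index", "level", "diag_icd10",
                     "diag_icd9"])
        out = harmonize_hesin(master, diag, None, settings)
        ep = out["hesin_icd10"].iloc[0]
        assert ep["eventdate"] == pd.Timestamp("2010-01-01")
        assert ep["epidur"] == 10
        assert ep["event"] == 1
        assert ep["classification"] == "icd10"

    def test_missing_start_falls_back_to_admission(self, settings):
        master = _rec([[9001, "0", "", "", "2011-05-01", ""]],
                      ["identifier", "ins_index", "epistart", "epiend",
                       "admidate", "disdate"])
        diag = _rec([[9001, "0", "1", "E110", ""]],
                    ["identifier", "ins_index", "level", "diag_icd10",
                     "diag_icd9"])
        out = harmonize_hesin(master, diag, None, settings)
        assert out["hesin_icd10"].iloc[0]["eventdate"] == pd.Timestamp("2011-05-01")

    def test_orphan_diag_dropped_with_warning(self, settings, caplog):
        master = _rec([[9001, "0", "2010-01-01", "", "2010-01-01", ""]],
                      ["identifier", "ins_index", "epistart", "epiend",
                       "admidate", "disdate"])
        diag = _rec([[9001, "0", "1", "I480", ""], [9002, "5", "1", "E110", ""]],
                    ["identifier", "ins_index", "level", "diag_icd10",
                     "diag_icd9"])
        out = harmonize_hesin(master, diag, None, settings)
        assert len(out["hesin_icd10"]) == 1
        assert any("orphan" in r.message for r in caplog.records)

    def test_icd9_and_oper(self, settings):
        master = _rec([[9001, "0", "2010-01-01", "", "2010-01-01", ""]],
                      ["identifier", "ins_index", "epistart", "epiend",
                       "admidate", "disdate"])
        diag = _rec([[9001, "0", "1", "", "4273"]],
                    ["identifier", "ins_index", "level", "diag_icd10",
                     "diag_icd9"])
        oper = _rec([[9001, "0", "1", "K401"]],
                    ["identifier", "ins_index", "level", "oper4"])
        out = harmonize_hesin(master, diag, oper, settings)
        assert out["hesin_icd9"].iloc[0]["classification"] == "icd9"
        assert out["hesin_oper4"].iloc[0]["classification"] == "opcs4"


class TestHarmonizeGP:
    def test_read2_episode(self, settings):
        gp = _rec([[9001, "1", "2005-06-01", "G573.", ""]],
                  ["identifier", "data_provider", "event_dt", "read_2", "read_3"])
        out = harmonize_gp(gp, None, settings)
        ep = out["gpclinical.read2"].iloc[0]
        assert (ep["classification"], ep["event"]) == ("read2", 1)
        assert ep["code"] == "G573."

    def test_both_columns_two_episodes(self, settings):
        gp = _rec([[9001, "1", "2005-06-01", "G573.", "X202R"]],
                  ["identifier", "data_provider", "event_dt", "read_2", "read_3"])
        out = harmonize_gp(gp, None, settings)
        assert len(out["gpclinical.read2"]) == 1
        assert len(out["gpclinical.read3"]) == 1

    def test_empty_codes_no_episode(self, settings):
        gp = _rec([[9001, "1", "2005-06-01", "", ""]],
                  ["identifier", "data_provider", "event_dt", "read_2", "read_3"])
        assert harmonize_gp(gp, None, settings) == {}

    def test_scripts(self, settings):
        scripts = _rec([[9001, "2", "2012-01-05", "met00001"]],
                       ["identifier", "data_provider", "issue_date", "drug_code"])
        out = harmonize_gp(None, scripts, settings)
        ep = out["gpscripts"].iloc[0]
        assert (ep[".id"], ep["classification"]) == ("gpscripts", "dmd")


class TestHarmonizeDeath:
    def _death(self):
        return _rec([[9001, "0", "2020-03-01"]],
                    ["identifier", "ins_index", "date_of_death"])

    def test_primary_cause(self, settings):
        cause = _rec([[9001, "0", "0", "1", "I50"]],
                     ["identifier", "ins_index", "arr_index", "level",
                      "cause_icd10"])
        out = harmonize_death(self._death(), cause, settings)
        ep = out["tte.death.icd10.primary"].iloc[0]
        assert ep["eventdate"] == pd.Timestamp("2020-03-01")
        assert ep["event"] == 1

    def test_contributory_cause(self, settings):
        cause = _rec([[9001, "0", "1", "2", "E119"]],
                     ["identifier", "ins_index", "arr_index", "level",
                      "cause_icd10"])
        out = harmonize_death(self._death(), cause, settings)
        assert "tte.death.icd10.secondary" in out
        assert "tte.death.icd10.primary" not in out

    def test_cause_without_date_dropped(self, settings, caplog):
        cause = _rec([[9002, "0", "0", "1", "I50"]],
                     ["identifier", "ins_index", "arr_index", "level",
                      "cause_icd10"])
        out = harmonize_death(self._death(), cause, settings)
        assert out == {}
        assert any("lacking a death date" in r.message for r in caplog.records)


def _participants(**cols):
    base = {"identifier": [9001],
            "f.53.0.0": [pd.Timestamp("2008-01-15")],
            "f.34.0.0": [1950], "f.52.0.0": [pd.NA]}
    base.update(cols)
    return pd.DataFrame(base)


def _catalog(extra=()):
    entries = {"identifier": CatalogEntry(0, 0, 0, "integer"),
               "f.53.0.0": CatalogEntry(53, 0, 0, "date"),
               "f.34.0.0": CatalogEntry(34, 0, 0, "integer"),
               "f.52.0.0": CatalogEntry(52, 0, 0, "integer")}
    for label, fid, vtype in extra:
        entries[label] = CatalogEntry(fid, 0, int(label.split(".")[-1]), vtype)
    return FieldCatalog(entries)


class TestHarmonizeSelfReport:
    def test_year_gives_midyear_event2(self, settings):
        part = _participants(**{"f.20002.0.0": ["1223"], "f.20008.0.0": [2005.0]})
        cat = _catalog([("f.20002.0.0", 20002, "categorical"),
                        ("f.20008.0.0", 20008, "real")])
        ep = harmonize_self_report(part, cat, settings)["sr_20002"].iloc[0]
        assert ep["eventdate"] == pd.Timestamp("2005-07-01")
        assert ep["event"] == 2

    def test_operation_year_gives_event1(self, settings):
        part = _participants(**{"f.20004.0.0": ["1095"], "f.20010.0.0": [2010.0]})
        cat = _catalog([("f.20004.0.0", 20004, "categorical"),
                        ("f.20010.0.0", 20010, "real")])
        ep = harmonize_self_report(part, cat, settings)["sr_20004"].iloc[0]
        assert ep["event"] == 1
        assert ep["eventdate"] == pd.Timestamp("2010-07-01")

    def test_negative_timing_imputes_visit_event0(self, settings):
        part = _participants(**{"f.20002.0.0": ["1223"], "f.20008.0.0": [-1.0]})
        cat = _catalog([("f.20002.0.0", 20002, "categorical"),
                        ("f.20008.0.0", 20008, "real")])
        ep = harmonize_self_report(part, cat, settings)["sr_20002"].iloc[0]
        assert ep["eventdate"] == pd.Timestamp("2008-01-15")
        assert ep["event"] == 0

    def test_fractional_interpolated_year(self, settings):
        part = _participants(**{"f.20002.0.0": ["1223"], "f.20008.0.0": [2004.5]})
        cat = _catalog([("f.20002.0.0", 20002, "categorical"),
                        ("f.20008.0.0", 20008, "real")])
        ep = harmonize_self_report(part, cat, settings)["sr_20002"].iloc[0]
        assert ep["eventdate"].year == 2004
        assert ep["eventdate"].month == 7

    def test_missing_code_no_episode(self, settings):
        part = _participants(**{"f.20002.0.0": [None], "f.20008.0.0": [2005.0]})
        cat = _catalog([("f.20002.0.0", 20002, "categorical"),
                        ("f.20008.0.0", 20008, "real")])
        assert harmonize_self_report(part, cat, settings) == {}


class TestEvaluateTouchscreen:
    def test_equality_visit_date_event0(self, settings):
        part = _participants(**{"f.6177.0.0": [3.0]})
        cat = _catalog([("f.6177.0.0", 6177, "categorical")])
        ep = evaluate_touchscreen(part, parse_condition("6177=3"), cat, settings)
        assert len(ep) == 1
        row = ep.iloc[0]
        assert (row["code"], row["event"]) == ("6177=3", 0)
        assert row["eventdate"] == pd.Timestamp("2008-01-15")

    def test_age_field_derives_date(self, settings):
        # birth year 1950, no month -> July 1; + 40 x 365.25 days = 1990-07-01
        part = _participants(**{"f.4041.0.0": [1.0], "f.2976.0.0": [40.0]})
        cat = _catalog([("f.4041.0.0", 4041, "categorical"),
                        ("f.2976.0.0", 2976, "real")])
        ep = evaluate_touchscreen(part, parse_condition("4041=1[2976]"), cat,
                                  settings)
        row = ep.iloc[0]
        assert abs((row["eventdate"] - pd.Timestamp("1990-07-01")).days) <= 1
        assert row["event"] == 2

    def test_negative_special_code_never_matches(self, settings):
        part = _participants(**{"f.6177.0.0": [-3.0]})
        cat = _catalog([("f.6177.0.0", 6177, "categorical")])
        ep = evaluate_touchscreen(part, parse_condition("6177!=0"), cat, settings)
        assert len(ep) == 0

    def test_ordering_comparator(self, settings):
        part = _participants(**{"f.21003.0.0": [55.0]})
        cat = _catalog([("f.21003.0.0", 21003, "integer")])
        assert len(evaluate_touchscreen(part, parse_condition("21003>=40"),
                                        cat, settings)) == 1
        assert len(evaluate_touchscreen(part, parse_condition("21003>60"),
                                        cat, settings)) == 0

    def test_uncoercible_value_fatal(self, settings):
        part = _participants(**{"f.21003.0.0": [55.0]})
        cat = _catalog([("f.21003.0.0", 21003, "integer")])
        from cohortpheno.definitions import ParseError
        with pytest.raises(ParseError):
            evaluate_touchscreen(part, parse_condition("21003=abc"), cat, settings)


class TestHarmonizeAll:
    def test_three_components(self, harmonized):
        assert len(harmonized.components()) == 3

    def test_at_least_six_sources(self, harmonized):
        assert len(harmonized.episodes) >= 6

    def test_withdrawals_absent_everywhere(self, harmonized, cohort):
        manifest, truth, _ = cohort
        withdrawn = {int(line) for line in
                     manifest["withdrawals"].read_text().split()}
        assert withdrawn, "fixture should have withdrawals"
        assert not withdrawn & set(harmonized.identifiers.tolist())
        for df in harmonized.episodes.values():
            assert not withdrawn & set(df["identifier"].tolist())
        assert not withdrawn & set(harmonized.participants["identifier"])

    def test_minimal_main_and_metadata_only(self, cohort, settings):
        manifest, _, _ = cohort
        data = harmonize_all(manifest["main"], manifest["metadata"],
                             None, settings)
        assert len(data.components()) == 3
        record_sources = [s for s in data.episodes
                          if s.startswith(("hesin", "gp", "tte"))]
        assert record_sources == []

    def test_episode_identifiers_subset_of_vector(self, harmonized):
        ids = set(harmonized.identifiers.tolist())
        for df in harmonized.episodes.values():
            assert set(df["identifier"]) <= ids

    def test_event_flags_per_source(self, harmonized):
        for source, df in harmonized.episodes.items():
            flags = set(df["event"].tolist())
            if source.startswith(("hesin", "gp", "tte")):
                assert flags == {1}, source
            elif source == "sr_20004":
                assert flags <= {0, 1}, source
            elif source == "sr_20003":
                assert flags == {0}, source
            elif source.startswith("sr_"):
                assert flags <= {0, 2}, source
            elif source == "ts":
                assert flags <= {0, 2}, source

    def test_epidur_only_on_hospital_episodes(self, harmonized):
        for source, df in harmonized.episodes.items():
            if not source.startswith("hesin"):
                assert df["epidur"].isna().all(), source

    def test_eventdate_always_present(self, harmonized):
        for df in harmonized.episodes.values():
            assert df["eventdate"].notna().all()


class TestSaveLoadRoundTrip:
    def test_lossless(self, harmonized, tmp_path):
        save_harmonized(harmonized, tmp_path / "h")
        back = load_harmonized(tmp_path / "h")
        assert set(back.episodes) == set(harmonized.episodes)
        for source in harmonized.episodes:
            a = harmonized.episodes[source].reset_index(drop=True)
            b = back.episodes[source].reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        assert np.array_equal(back.identifiers, harmonized.identifiers)
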