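import numpy as np
import pandas as pd
import pytest

from cohortpheno.ascertain import (CASECONTROL_COLUMNS, event_stats,
                                   get_cases_controls, get_cases_controls_batch,
                                   individual_timeline, match_episodes,
                                   source_overlap_matrix, summarize_participant,
                                   timeline_counts)
from cohortpheno.definitions import Definition, DefinitionSet
from cohortpheno.harmonize import EPISODE_COLUMNS, HarmonizedData

from _oracle import oracle_match_set, oracle_statuses

REF = pd.Timestamp("2010-01-01")


def _events(rows):
    """rows: (source, identifier, code, classification, date, event, epidur)"""
    df = pd.DataFrame(rows, columns=EPISODE_COLUMNS)
    df["identifier"] = df["identifier"].astype(np.int64)
    df["eventdate"] = pd.to_datetime(df["eventdate"])
    df["event"] = df["event"].astype(np.int64)
    df["epidur"] = pd.array(df["epidur"], dtype="Int64")
    return df


class TestMatchEpisodes:
    def test_code_set_lookup(self, defset, harmonized, settings):
        matched = match_episodes(defset["DmT2"], harmonized, settings)
        assert len(matched)
        icd10 = matched[matched["classification"] == "icd10"]
        assert set(icd10["code"]) <= {"E11", "E110", "E119"}

    def test_no_match_absent(self, defset, harmonized, settings):
        matched = match_episodes(defset["DmT2"], harmonized, settings)
        hits = set(matched["identifier"])
        everyone = set(harmonized.identifiers.tolist())
        assert hits < everyone

    def test_min_instances_filter(self, defset, harmonized, settings):
        loose = match_episodes(defset["DmT2"], harmonized, settings)
        strict_settings = settings.with_min_instances("gpclinical.read2", 99)
        strict = match_episodes(defset["DmT2"], harmonized, strict_settings)
        assert not len(strict[strict[".id"] == "gpclinical.read2"])
        other = loose[loose[".id"] != "gpclinical.read2"]
        pd.testing.assert_frame_equal(
            strict.reset_index(drop=True), other.reset_index(drop=True))

    def test_oracle_equivalence_per_trait(self, defset, harmonized, settings):
        for trait in ("DmT2", "Af", "RxDm", "Ht"):
            matched = match_episodes(defset[trait], harmonized, settings)
            assert set(matched["identifier"]) == \
                oracle_match_set(defset[trait], harmonized, settings)


class TestSummarizeParticipant:
    def test_prevalent_single_event(self):
        ev = _events([("hesin_icd10", 1, "E11", "icd10",
                       REF - pd.Timedelta(days=365), 1, 3)])
        rec = summarize_participant(ev, REF)
        assert rec["Hx"] == 2 and rec["Any"] == 2
        assert rec["Hx_days"] == 365
        assert rec["first_diagnosis_days"] == -365
        assert rec["Fu"] == 1

    def test_incident_only(self):
        ev = _events([
            ("hesin_icd10", 1, "E11", "icd10", REF + pd.Timedelta(days=100), 1, None),
            ("hesin_icd10", 1, "E11", "icd10", REF + pd.Timedelta(days=200), 1, None)])
        rec = summarize_participant(ev, REF)
        assert (rec["Fu"], rec["Fu_days"], rec["Hx"]) == (2, 100, 1)
        assert rec["first_diagnosis_days"] == 100

    def test_epidur_aggregates(self):
        ev = _events([
            ("hesin_icd10", 1, "E11", "icd10", REF - pd.Timedelta(days=10), 1, 3),
            ("hesin_icd10", 1, "E11", "icd10", REF - pd.Timedelta(days=20), 1, 5),
            ("hesin_icd10", 1, "E11", "icd10", REF - pd.Timedelta(days=30), 1, 10)])
        rec = summarize_participant(ev, REF)
        assert (rec["sum.epidur"], rec["median.epidur"], rec["max.epidur"]) == \
            (18, 5, 10)
        assert rec["count"] == 3

    def test_event_on_reference_counts_hx_and_ref(self):
        ev = _events([("gpclinical.read2", 1, "C10F1", "read2", REF, 1, None)])
        rec = summarize_participant(ev, REF)
        assert (rec["Hx"], rec["Ref"]) == (2, 2)
        assert rec["Hx_days"] == 0

    def test_ref_window(self):
        ev = _events([("gpclinical.read2", 1, "C10F1", "read2",
                       REF + pd.Timedelta(days=1), 1, None)])
        assert summarize_participant(ev, REF)["Ref"] == 1
        assert summarize_participant(ev, REF, window_days=1)["Ref"] == 2

    def test_death_fields(self):
        ev = _events([
            ("hesin_icd10", 1, "I50", "icd10", REF - pd.Timedelta(days=9), 1, None),
            ("tte.death.icd10.primary", 1, "I50", "icd10",
             REF + pd.Timedelta(days=400), 1, None)])
        rec = summarize_participant(ev, REF)
        assert (rec["Death_primary"], rec["Death_any"]) == (2, 2)
        assert rec["survival_days"] == 400

    def test_empty_events_error(self):
        with pytest.raises(ValueError):
            summarize_participant(_events([]), REF)

    def test_sixteen_fields(self):
        ev = _events([("hesin_icd10", 1, "E11", "icd10", REF, 1, None)])
        rec = summarize_participant(ev, REF)
        assert list(rec.index) == CASECONTROL_COLUMNS
        assert len(rec) == 16


class TestGetCasesControls:
    def test_status_table_shape(self, defset, harmonized, settings,
                                reference_dates):
        res = get_cases_controls(defset, "DmT2", harmonized, settings,
                                 reference_dates)
        assert list(res.status.columns) == CASECONTROL_COLUMNS
        assert res.status.shape[1] == 16

    def test_three_components(self, defset, harmonized, settings,
                              reference_dates):
        res = get_cases_controls(defset, "DmT2", harmonized, settings,
                                 reference_dates)
        assert len(res.components()) == 3

    def test_status_partition(self, defset, harmonized, settings,
                              reference_dates):
        res = get_cases_controls(defset, "DmRxT2", harmonized, settings,
                                 reference_dates)
        assert not res.status["identifier"].duplicated().any()
        assert set(res.status["identifier"]) == set(harmonized.identifiers.tolist())
        assert set(res.statuses.unique()) <= {2, 1, -1, -2}

    def test_oracle_equivalence(self, defset, harmonized, settings,
                                reference_dates):
        for trait in ("DmT2", "DmRxT2", "Af", "Hf"):
            res = get_cases_controls(defset, trait, harmonized, settings,
                                     reference_dates)
            expected = oracle_statuses(defset, trait, harmonized, settings,
                                       harmonized.identifiers.tolist())
            assert res.statuses.to_dict() == expected

    def test_randomized_composites_match_oracle(self, defset, harmonized,
                                                settings, reference_dates):
        rng = np.random.default_rng(7)
        base = ["DmT2", "DmT1", "RxDm", "Af", "Hf", "Ht", "Cabg"]
        for i in range(25):
            pick = lambda: [t for t in base if rng.random() < 0.3]  # noqa: E731
            comp = Definition(
                trait="RND",
                include_definitions=pick() or [str(rng.choice(base))],
                exclude_from_cases=pick(),
                exclude_from_controls=pick(),
                study_population=(str(rng.choice(base))
                                  if rng.random() < 0.3 else None))
            rnd_set = DefinitionSet(list(defset.definitions) + [comp])
            res = get_cases_controls(rnd_set, "RND", harmonized, settings,
                                     reference_dates)
            expected = oracle_statuses(rnd_set, "RND", harmonized, settings,
                                       harmonized.identifiers.tolist())
            assert res.statuses.to_dict() == expected, f"composite #{i}"

    def test_consistency_hx_days(self, defset, harmonized, settings,
                                 reference_dates):
        res = get_cases_controls(defset, "DmT2", harmonized, settings,
                                 reference_dates)
        cases = res.status[res.status["first_diagnosis_days"].notna()]
        pre = cases[cases["first_diagnosis_days"] < 0]
        assert (pre["Hx_days"] == -pre["first_diagnosis_days"]).all()
        assert (pre["Hx"].abs() == 2).all()

    def test_count_iff_case(self, defset, harmonized, settings, reference_dates):
        res = get_cases_controls(defset, "DmT2", harmonized, settings,
                                 reference_dates)
        assert ((res.status["count"] >= 1) ==
                (res.status["Any"].abs() == 2)).all()

    def test_determinism(self, defset, harmonized, settings, reference_dates):
        a = get_cases_controls(defset, "DmRxT2", harmonized, settings,
                               reference_dates)
        b = get_cases_controls(defset, "DmRxT2", harmonized, settings,
                               reference_dates)
        pd.testing.assert_frame_equal(a.status, b.status)
        pd.testing.assert_frame_equal(a.case_events, b.case_events)

    def test_unknown_trait_fatal(self, defset, harmonized, settings,
                                 reference_dates):
        with pytest.raises(KeyError):
            get_cases_controls(defset, "Ghost", harmonized, settings,
                               reference_dates)

    def test_case_events_only_included_cases(self, defset, harmonized, settings,
                                             reference_dates):
        res = get_cases_controls(defset, "DmRxT2", harmonized, settings,
                                 reference_dates)
        included = set(res.status.loc[res.status["Any"] == 2, "identifier"])
        assert set(res.case_events["identifier"]) <= included

    def test_case_summary_is_cases_only(self, defset, harmonized, settings,
                                        reference_dates):
        res = get_cases_controls(defset, "DmRxT2", harmonized, settings,
                                 reference_dates)
        assert (res.case_summary["Any"].abs() == 2).all()
        assert list(res.case_summary.columns) == CASECONTROL_COLUMNS

    def test_single_reference_date(self, defset, harmonized, settings):
        res = get_cases_controls(defset, "DmT2", harmonized, settings,
                                 "2009-01-01")
        assert (res.status["reference_date"] == pd.Timestamp("2009-01-01")).all()

    def test_batch_prefixing(self, defset, harmonized, settings,
                             reference_dates):
        wide = get_cases_controls_batch(defset, ["DmT2", "Af"], harmonized,
                                        settings, reference_dates)
        assert "DmT2_0_Hx" in wide.columns
        assert "Af_0_Any" in wide.columns
        assert wide["identifier"].is_unique


class TestEventStats:
    def test_counts(self):
        ev = _events([
            ("hesin_icd10", 1, "E119", "icd10", REF, 1, None),
            ("hesin_icd10", 1, "E119", "icd10", REF, 1, None),
            ("hesin_icd10", 2, "E119", "icd10", REF, 1, None),
            ("hesin_icd10", 3, "E110", "icd10", REF, 1, None)])
        stats = event_stats(ev)
        top = stats.iloc[0]
        assert (top["code"], top["event_count"], top["participant_count"]) == \
            ("E119", 3, 2)
        assert (stats["participant_count"] <= 3).all()

    def test_empty(self):
        assert len(event_stats(_events([]))) == 0

    def test_cohort_bound(self, defset, harmonized, settings, reference_dates):
        res = get_cases_controls(defset, "DmT2", harmonized, settings,
                                 reference_dates)
        stats = event_stats(res.case_events)
        n_cases = res.case_events["identifier"].nunique()
        assert (stats["participant_count"] <= n_cases).all()
        assert (stats["participant_fraction"] <= 1).all()


class TestOverlapAndTimeline:
    def test_overlap_rows_have_evidence(self, defset, harmonized, settings,
                                        reference_dates):
        table = source_overlap_matrix(defset["DmT2"], harmonized,
                                      reference_dates, settings)
        if len(table):
            assert table.any(axis=1).all()  # row sums >= 1

    def test_overlap_two_sources(self):
        episodes = {
            "hesin_icd10": _events([("hesin_icd10", 1, "E11", "icd10",
                                     "2008-01-01", 1, None)]),
            "sr_20002": _events([("sr_20002", 1, "1223", "sr_20002",
                                  "2007-01-01", 2, None)]),
        }
        hd = HarmonizedData(episodes, pd.DataFrame({"identifier": [1]}),
                            np.array([1]))
        d = Definition("Dm", code_sets={"icd10": {"E11"}})
        from cohortpheno.definitions import parse_field_spec
        d.field_specs = [parse_field_spec("20002(1223)")]
        table = source_overlap_matrix(d, hd, REF)
        assert table.loc[1].sum() == 2

    def test_timeline_excludes_event0(self, defset, harmonized, settings):
        # RxDm matches the medication self-report source, which never has a
        # true event date (event flag 0 throughout)
        counts = timeline_counts(defset["RxDm"], harmonized, settings)
        matched = match_episodes(defset["RxDm"], harmonized, settings)
        dated = matched[matched["event"].isin((1, 2))]
        assert counts["count"].sum() == len(dated)
        undated = matched[matched["event"] == 0]
        assert len(undated), "fixture should produce undated episodes"

    def test_timeline_empty(self, harmonized, settings):
        empty = Definition("None", code_sets={"icd10": {"ZZZZ"}})
        assert len(timeline_counts(empty, harmonized, settings)) == 0


class TestIndividualTimeline:
    def test_sorted(self, harmonized):
        pid = int(harmonized.all_episodes()["identifier"].iloc[0])
        tl = individual_timeline(harmonized, pid)
        assert len(tl) >= 1
        assert tl["eventdate"].is_monotonic_increasing
        assert (tl["identifier"] == pid).all()

    def test_unknown_identifier_empty(self, harmonized):
        assert len(individual_timeline(harmonized, -1)) == 0

    def test_tie_break_by_source_then_code(self):
        episodes = {
            "b_src": _events([("b_src", 1, "X", "icd10", REF, 1, None)]),
            "a_src": _events([("a_src", 1, "Z", "icd10", REF, 1, None),
                              ("a_src", 1, "A", "icd10", REF, 1, None)]),
        }
        hd = HarmonizedData(episodes, pd.DataFrame({"identifier": [1]}),
                            np.array([1]))
        tl = individual_timeline(hd, 1)
        assert list(zip(tl[".id"], tl["code"])) == [
            ("a_src", "A"), ("a_src", "Z"), ("b_src", "X")]
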