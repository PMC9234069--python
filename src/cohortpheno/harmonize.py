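"""Convert every data source into the unified episode schema.

An episode is one clinical event with seven columns: ``.id`` (source),
``identifier``, ``code``, ``classification``, ``eventdate``, ``event`` and
``epidur``.  The ``event`` flag records date provenance: 1 for a true event
date from linked data or a self-reported operation, 2 for other self-reported
event dates, 0 when the date is imputed from the assessment-centre visit.
``epidur`` (days hospitalized) is present only for hospital episodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .definitions import Condition, DefinitionSet, ParseError
from .settings import DataSettings, SourceSettings, default_settings
from .ukb_io import (FieldCatalog, read_field_catalog, read_main_dataset,
                     read_record_table, read_withdrawals)

logger = logging.getLogger(__name__)

__all__ = ["Episode", "HarmonizedData", "harmonize_hesin", "harmonize_gp",
           "harmonize_death", "harmonize_self_report", "evaluate_touchscreen",
           "harmonize_all", "save_harmonized", "load_harmonized"]

EPISODE_COLUMNS = [".id", "identifier", "code", "classification",
                   "eventdate", "event", "epidur"]

#: convenience alias for readers; episodes travel as DataFrame rows
Episode = pd.Series


def _empty_episodes() -> pd.DataFrame:
    return pd.DataFrame({
        ".id": pd.Series(dtype=str),
        "identifier": pd.Series(dtype=np.int64),
        "code": pd.Series(dtype=str),
        "classification": pd.Series(dtype=str),
        "eventdate": pd.Series(dtype="datetime64[ns]"),
        "event": pd.Series(dtype=np.int64),
        "epidur": pd.Series(dtype="Int64"),
    })


def _episode_frame(source: str, identifiers, codes, classification: str,
                   eventdates, event, epidur=None) -> pd.DataFrame:
    n = len(identifiers)
    df = pd.DataFrame({
        ".id": np.repeat(source, n),
        "identifier": np.asarray(identifiers, dtype=np.int64),
        "code": np.asarray(codes, dtype=object),
        "classification": np.repeat(classification, n),
        "eventdate": pd.to_datetime(pd.Series(list(eventdates))),
        "event": np.asarray(event, dtype=np.int64) if not np.isscalar(event)
        else np.repeat(event, n),
        "epidur": pd.array(epidur, dtype="Int64") if epidur is not None
        else pd.array([pd.NA] * n, dtype="Int64"),
    })
    kept = df[df["eventdate"].notna()].reset_index(drop=True)
    dropped = n - len(kept)
    if dropped:
        logger.warning("%s: dropped %d episode(s) with no derivable event date",
                       source, dropped)
    return kept


@dataclass
class HarmonizedData:
    """The three-part harmonized container: episode tables grouped by source,
    the participant subset of the main dataset, and the full identifier
    vector."""

    episodes: dict[str, pd.DataFrame]
    participants: pd.DataFrame
    identifiers: np.ndarray

    def __post_init__(self) -> None:
        self.identifiers = np.asarray(self.identifiers, dtype=np.int64)

    def components(self) -> tuple:
        return (self.episodes, self.participants, self.identifiers)

    def all_episodes(self) -> pd.DataFrame:
        frames = [df for df in self.episodes.values() if len(df)]
        if not frames:
            return _empty_episodes()
        return pd.concat(frames, ignore_index=True)


def _iso_dates(series: pd.Series) -> pd.Series:
    """Strict ISO-8601 parse; empty cells become NaT, other dialects raise."""
    return pd.to_datetime(series.replace({"": None, "NA": None}),
                          format="%Y-%m-%d", errors="raise")


def _first_valid(*series: pd.Series) -> pd.Series:
    out = series[0].copy()
    for s in series[1:]:
        out = out.fillna(s)
    return out


def harmonize_hesin(hesin: pd.DataFrame, hesin_diag: pd.DataFrame | None,
                    hesin_oper: pd.DataFrame | None,
                    settings: DataSettings) -> dict[str, pd.DataFrame]:
    """Hospital inpatient episodes: one per diagnosis/operation code.

    The event date is the episode start, falling back to the admission date;
    ``epidur`` is episode end minus start in days.  Diagnosis/operation rows
    without a matching master row are dropped (count logged).
    """
    master = hesin.copy()
    for col in ("epistart", "epiend", "admidate", "disdate"):
        if col not in master.columns:
            master[col] = ""
        master[col] = _iso_dates(master[col])
    master["eventdate"] = _first_valid(master["epistart"], master["admidate"])
    end = _first_valid(master["epiend"], master["disdate"])
    dur = (end - master["eventdate"]).dt.days
    master["epidur"] = pd.array(
        np.where(dur.notna(), dur.clip(lower=0), np.nan), dtype="Int64")
    keys = ["identifier", "ins_index"]
    master_keyed = master[keys + ["eventdate", "epidur"]]

    out: dict[str, pd.DataFrame] = {}

    def emit(records: pd.DataFrame | None, columns: dict[str, tuple[str, str]]):
        if records is None or not len(records):
            return
        merged = records.merge(master_keyed, on=keys, how="left", indicator=True)
        orphans = int((merged["_merge"] == "left_only").sum())
        if orphans:
            logger.warning("hesin: dropped %d orphan record(s) with no master row",
                           orphans)
        merged = merged[merged["_merge"] == "both"]
        for col, (source, classification) in columns.items():
            if col not in merged.columns:
                continue
            rows = merged[merged[col].str.strip() != ""]
            if not len(rows):
                continue
            out[source] = _episode_frame(
                source, rows["identifier"], rows[col].str.strip(), classification,
                rows["eventdate"], 1, rows["epidur"])

    emit(hesin_diag, {"diag_icd10": ("hesin_icd10", "icd10"),
                      "diag_icd9": ("hesin_icd9", "icd9")})
    emit(hesin_oper, {"oper4": ("hesin_oper4", "opcs4")})
    return out


def harmonize_gp(gp_clinical: pd.DataFrame | None, gp_scripts: pd.DataFrame | None,
                 settings: DataSettings) -> dict[str, pd.DataFrame]:
    """Primary-care events and prescriptions.

    Each non-empty code cell yields one episode (a row with both read_2 and
    read_3 filled yields two).  Rows with no code in any code column drop.
    """
    out: dict[str, pd.DataFrame] = {}
    if gp_clinical is not None and len(gp_clinical):
        dates = _iso_dates(gp_clinical["event_dt"])
        for col, source, classification in (
                ("read_2", "gpclinical.read2", "read2"),
                ("read_3", "gpclinical.read3", "read3")):
            if col not in gp_clinical.columns:
                continue
            mask = gp_clinical[col].str.strip() != ""
            if mask.any():
                out[source] = _episode_frame(
                    source, gp_clinical.loc[mask, "identifier"],
                    gp_clinical.loc[mask, col].str.strip(), classification,
                    dates[mask], 1)
    if gp_scripts is not None and len(gp_scripts):
        code_col = next((c for c in ("drug_code", "dmd_code", "bnf_code", "read_2")
                         if c in gp_scripts.columns), None)
        if code_col is None:
            logger.warning("gp_scripts: no recognizable drug-code column; skipped")
        else:
            dates = _iso_dates(gp_scripts["issue_date"])
            mask = gp_scripts[code_col].str.strip() != ""
            if mask.any():
                out["gpscripts"] = _episode_frame(
                    "gpscripts", gp_scripts.loc[mask, "identifier"],
                    gp_scripts.loc[mask, code_col].str.strip(), "dmd",
                    dates[mask], 1)
    return out


def harmonize_death(death: pd.DataFrame, death_cause: pd.DataFrame | None,
                    settings: DataSettings) -> dict[str, pd.DataFrame]:
    """Death-register episodes: primary causes go to
    ``tte.death.icd10.primary``, contributory to ``…secondary``."""
    if death_cause is None or not len(death_cause):
        return {}
    dates = death.copy()
    dates["date_of_death"] = _iso_dates(dates["date_of_death"])
    keys = ["identifier"]
    if "ins_index" in dates.columns and "ins_index" in death_cause.columns:
        keys.append("ins_index")
    merged = death_cause.merge(
        dates[keys + ["date_of_death"]].drop_duplicates(subset=keys),
        on=keys, how="left")
    undated = int(merged["date_of_death"].isna().sum())
    if undated:
        logger.warning("death: dropped %d cause row(s) lacking a death date", undated)
    merged = merged[merged["date_of_death"].notna()
                    & (merged["cause_icd10"].str.strip() != "")]
    level = merged.get("level", pd.Series("1", index=merged.index)).str.strip()
    out: dict[str, pd.DataFrame] = {}
    for source, mask in (("tte.death.icd10.primary", level == "1"),
                         ("tte.death.icd10.secondary", level != "1")):
        rows = merged[mask]
        if len(rows):
            out[source] = _episode_frame(
                source, rows["identifier"], rows["cause_icd10"].str.strip(),
                "icd10", rows["date_of_death"], 1)
    return out


def _norm_code(value) -> str | None:
    """Stringify a self-report code cell; integral floats lose the '.0'."""
    if value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value):
        return None
    s = str(value).strip()
    if not s:
        return None
    try:
        f = float(s)
        if f.is_integer():
            return str(int(f))
    except ValueError:
        pass
    return s


def _birth_dates(participants: pd.DataFrame, settings: DataSettings) -> pd.Series:
    """Mid-month (day 15) birth date when month is known, else July 1."""
    idx = participants.index
    ycol = f"f.{settings.birth_year_field}.0.0"
    mcol = f"f.{settings.birth_month_field}.0.0"
    if ycol not in participants.columns:
        return pd.Series(pd.NaT, index=idx)
    years = pd.to_numeric(participants[ycol], errors="coerce")
    months = (pd.to_numeric(participants[mcol], errors="coerce")
              if mcol in participants.columns else pd.Series(np.nan, index=idx))

    def build(y, m):
        if pd.isna(y) or y < 1900:
            return pd.NaT
        if pd.isna(m) or not 1 <= m <= 12:
            return pd.Timestamp(int(y), 7, 1)
        return pd.Timestamp(int(y), int(m), 15)

    return pd.Series([build(y, m) for y, m in zip(years, months)], index=idx)


def _visit_dates(participants: pd.DataFrame, settings: DataSettings,
                 instance: int) -> pd.Series:
    col = f"f.{settings.visit_date_field}.{instance}.0"
    fallback = f"f.{settings.visit_date_field}.0.0"
    if col in participants.columns:
        return pd.to_datetime(participants[col])
    if fallback in participants.columns:
        return pd.to_datetime(participants[fallback])
    return pd.Series(pd.NaT, index=participants.index)


def _timing_to_date(kind: str, value: float, birth: pd.Timestamp,
                    visit: pd.Timestamp) -> pd.Timestamp:
    """Convert a reported year or age-at-event to a calendar date.

    Whole years land on July 1 (unbiased within-year placement); fractional
    (interpolated) years are offset from January 1.  Ages add ``age × 365.25``
    days to the birth date.  Implausible values return NaT.
    """
    if value is None or pd.isna(value) or value <= 0:
        return pd.NaT
    if kind == "year":
        if not 1900 <= value <= 2100:
            return pd.NaT
        whole = int(value)
        frac = value - whole
        if frac == 0:
            return pd.Timestamp(whole, 7, 1)
        return pd.Timestamp(whole, 1, 1) + timedelta(days=frac * 365.25)
    if kind == "age":
        if pd.isna(birth) or value > 130:
            return pd.NaT
        date = birth + timedelta(days=float(value) * 365.25)
        if pd.notna(visit) and date > pd.Timestamp.now():
            return pd.NaT
        return date
    return pd.NaT


def _instance_arrays(columns, field_id: int) -> list[tuple[int, int, str]]:
    prefix = f"f.{field_id}."
    out = []
    for col in columns:
        if col.startswith(prefix):
            _, _, inst, arr = col.split(".")
            out.append((int(inst), int(arr), col))
    return sorted(out)


def harmonize_self_report(participants: pd.DataFrame, catalog: FieldCatalog,
                          settings: DataSettings) -> dict[str, pd.DataFrame]:
    """Nurse-interview self-report fields → episodes.

    One episode per non-missing code cell per instance/array.  The event date
    comes from the companion timing field when valid (event flag = the
    source's ``default_event_flag``: 1 for operations, 2 otherwise);
    otherwise the visit date of that instance with event = 0.  Negative
    special timing codes (−1 "do not know", −3 "prefer not to answer") are
    treated as missing timing.
    """
    birth = _birth_dates(participants, settings)
    out: dict[str, pd.DataFrame] = {}
    for src in settings.self_report_sources():
        cells = _instance_arrays(participants.columns, src.field_id)
        if not cells:
            continue
        ids, codes, dates, events = [], [], [], []
        for inst, arr, col in cells:
            visits = _visit_dates(participants, settings, inst)
            timing_col = None
            if src.timing_field is not None:
                for cand in (f"f.{src.timing_field}.{inst}.{arr}",
                             f"f.{src.timing_field}.{inst}.0"):
                    if cand in participants.columns:
                        timing_col = cand
                        break
            for i in participants.index:
                code = _norm_code(participants.at[i, col])
                if code is None:
                    continue
                date = pd.NaT
                if timing_col is not None:
                    timing = pd.to_numeric(
                        pd.Series([participants.at[i, timing_col]]),
                        errors="coerce").iloc[0]
                    date = _timing_to_date(src.timing_kind, timing,
                                           birth.at[i], visits.at[i])
                if pd.notna(date):
                    event = src.default_event_flag
                else:
                    date, event = visits.at[i], 0
                ids.append(participants.at[i, "identifier"])
                codes.append(code)
                dates.append(date)
                events.append(event)
        if ids:
            out[src.source_id] = _episode_frame(
                src.source_id, ids, codes, src.classification, dates, events)
    return out


def _compare(values: pd.Series, comparator: str, target: str,
             value_type: str | None) -> pd.Series:
    numeric = value_type in ("integer", "real", "categorical", None)
    if numeric:
        try:
            target_num = float(target)
        except ValueError:
            if value_type in ("integer", "real"):
                raise ParseError(
                    f"condition value {target!r} is not coercible to "
                    f"{value_type}") from None
            numeric = False
    if numeric:
        vals = pd.to_numeric(values, errors="coerce")
        ok = vals.notna() & (vals >= 0)  # negative special codes never satisfy
        ops = {"=": vals == target_num, "!=": vals != target_num,
               "<": vals < target_num, "<=": vals <= target_num,
               ">": vals > target_num, ">=": vals >= target_num}
        return ok & ops[comparator]
    svals = values.astype("string").str.strip()
    ok = svals.notna() & (svals != "")
    if comparator == "=":
        return ok & (svals == target)
    if comparator == "!=":
        return ok & (svals != target)
    raise ParseError(f"ordering comparator {comparator!r} requires a numeric field")


def evaluate_touchscreen(participants: pd.DataFrame, condition: Condition,
                         catalog: FieldCatalog,
                         settings: DataSettings | None = None) -> pd.DataFrame:
    """Evaluate one touchscreen condition over every instance/array.

    Each satisfied participant/instance yields an episode whose code is the
    canonical condition text, dated from the condition's age field when given
    and valid (event = 2) or from the visit date (event = 0).
    """
    settings = settings or default_settings()
    ts = settings["ts"] if "ts" in settings else SourceSettings(
        "ts", "TS", "ts", date_rule="condition", default_event_flag=2)
    cells = _instance_arrays(participants.columns, condition.field_id)
    birth = _birth_dates(participants, settings)
    vtype = catalog.value_type(condition.field_id)
    ids, codes, dates, events = [], [], [], []
    for inst, arr, col in cells:
        hit = _compare(participants[col], condition.comparator, condition.value, vtype)
        if not hit.any():
            continue
        visits = _visit_dates(participants, settings, inst)
        age_col = None
        if condition.age_field is not None:
            for cand in (f"f.{condition.age_field}.{inst}.{arr}",
                         f"f.{condition.age_field}.{inst}.0"):
                if cand in participants.columns:
                    age_col = cand
                    break
        for i in participants.index[hit]:
            date = pd.NaT
            if age_col is not None:
                age = pd.to_numeric(pd.Series([participants.at[i, age_col]]),
                                    errors="coerce").iloc[0]
                date = _timing_to_date("age", age, birth.at[i], visits.at[i])
            if pd.notna(date):
                event = ts.default_event_flag
            else:
                date, event = visits.at[i], 0
            ids.append(participants.at[i, "identifier"])
            codes.append(condition.canonical)
            dates.append(date)
            events.append(event)
    if not ids:
        return _empty_episodes()
    return _episode_frame("ts", ids, codes, "ts", dates, events)


def _required_fields(defset: DefinitionSet | None, settings: DataSettings,
                     catalog: FieldCatalog) -> tuple[list[int], list[int]]:
    """(structural fields present in the catalog, defset-required fields)."""
    structural = [settings.visit_date_field, settings.birth_year_field,
                  settings.birth_month_field, settings.centre_field]
    structural = [f for f in structural if f in catalog.field_ids()]
    required: list[int] = []
    if defset is not None:
        sr_fields = {s.field_id: s for s in settings.self_report_sources()}
        for d in defset:
            for spec in d.field_specs:
                required.append(spec.field_id)
                src = sr_fields.get(spec.field_id)
                if src is not None and src.timing_field is not None:
                    required.append(src.timing_field)
            for cond in d.conditions:
                required.append(cond.field_id)
                if cond.age_field is not None:
                    required.append(cond.age_field)
    seen = set(structural)
    ordered = []
    for f in required:
        if f not in seen:
            seen.add(f)
            ordered.append(f)
    return structural, ordered


def harmonize_all(
    main_path: str | Path,
    metadata_path: str | Path,
    defset: DefinitionSet | None = None,
    settings: DataSettings | None = None,
    *,
    hesin: str | Path | None = None,
    hesin_diag: str | Path | None = None,
    hesin_oper: str | Path | None = None,
    gp_clinical: str | Path | None = None,
    gp_scripts: str | Path | None = None,
    death: str | Path | None = None,
    death_cause: str | Path | None = None,
    withdrawals: str | Path | set | None = None,
    allow_missing: bool = True,
) -> HarmonizedData:
    """Load every provided source and assemble the three-part container.

    Only the main dataset and metadata are mandatory; each record-level path
    is optional and skipped with a log line when absent.  Withdrawn
    participants are removed from every table.
    """
    settings = settings or default_settings()
    catalog = read_field_catalog(metadata_path)
    structural, required = _required_fields(defset, settings, catalog)
    participants = read_main_dataset(main_path, catalog, structural + required,
                                     allow_missing=allow_missing)
    withdrawn = (withdrawals if isinstance(withdrawals, set)
                 else read_withdrawals(withdrawals))
    if withdrawn:
        participants = participants[~participants["identifier"].isin(withdrawn)]
        participants = participants.reset_index(drop=True)
    identifiers = participants["identifier"].to_numpy(dtype=np.int64)
    id_set = set(identifiers.tolist())

    episodes: dict[str, pd.DataFrame] = {}

    def load(path):
        if path is None:
            return None
        path = Path(path)
        if not path.exists():
            logger.info("optional record-level file %s not found; skipped", path)
            return None
        return read_record_table(path)

    hesin_df = load(hesin)
    if hesin_df is not None:
        episodes.update(harmonize_hesin(hesin_df, load(hesin_diag),
                                        load(hesin_oper), settings))
    gp_df, scripts_df = load(gp_clinical), load(gp_scripts)
    if gp_df is not None or scripts_df is not None:
        episodes.update(harmonize_gp(gp_df, scripts_df, settings))
    death_df = load(death)
    if death_df is not None:
        episodes.update(harmonize_death(death_df, load(death_cause), settings))

    episodes.update(harmonize_self_report(participants, catalog, settings))

    if defset is not None:
        seen_conditions: set[tuple] = set()
        ts_frames = []
        for d in defset:
            for cond in d.conditions:
                key = (cond.canonical, cond.age_field)
                if key in seen_conditions:
                    continue
                seen_conditions.add(key)
                if cond.field_id not in catalog.field_ids():
                    if not allow_missing:
                        raise KeyError(f"touchscreen field {cond.field_id} missing "
                                       "from the main dataset")
                    logger.warning("touchscreen field %s missing; condition %s "
                                   "skipped", cond.field_id, cond.canonical)
                    continue
                frame = evaluate_touchscreen(participants, cond, catalog, settings)
                if len(frame):
                    ts_frames.append(frame)
        if ts_frames:
            episodes["ts"] = pd.concat(ts_frames, ignore_index=True)

    for source in list(episodes):
        df = episodes[source]
        df = df[df["identifier"].isin(id_set)].reset_index(drop=True)
        if len(df):
            episodes[source] = df
        else:
            del episodes[source]

    return HarmonizedData(episodes, participants, identifiers)


def save_harmonized(data: HarmonizedData, out_dir: str | Path) -> Path:
    """Write the container as TSV tables (lossless episode round-trip)."""
    out_dir = Path(out_dir)
    (out_dir / "episodes").mkdir(parents=True, exist_ok=True)
    for source, df in data.episodes.items():
        out = df.copy()
        out["eventdate"] = out["eventdate"].dt.strftime("%Y-%m-%d")
        out.to_csv(out_dir / "episodes" / f"{source}.tsv", sep="\t", index=False)
    participants = data.participants.copy()
    for col in participants.columns:
        if pd.api.types.is_datetime64_any_dtype(participants[col]):
            participants[col] = participants[col].dt.strftime("%Y-%m-%d")
    participants.to_csv(out_dir / "participants.tsv", sep="\t", index=False)
    np.savetxt(out_dir / "identifiers.txt", data.identifiers, fmt="%d")
    return out_dir


def load_harmonized(in_dir: str | Path) -> HarmonizedData:
    in_dir = Path(in_dir)
    episodes = {}
    for path in sorted((in_dir / "episodes").glob("*.tsv")):
        df = pd.read_csv(path, sep="\t", dtype={"code": str},
                         keep_default_na=False)
        df["identifier"] = df["identifier"].astype(np.int64)
        df["eventdate"] = pd.to_datetime(df["eventdate"], format="%Y-%m-%d")
        df["event"] = df["event"].astype(np.int64)
        df["epidur"] = pd.array(
            [int(v) if str(v).strip() not in ("", "nan", "<NA>") else pd.NA
             for v in df["epidur"]], dtype="Int64")
        episodes[path.stem] = df[EPISODE_COLUMNS]
    participants = pd.read_csv(in_dir / "participants.tsv", sep="\t")
    identifiers = np.loadtxt(in_dir / "identifiers.txt", dtype=np.int64, ndmin=1)
    return HarmonizedData(episodes, participants, identifiers)
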