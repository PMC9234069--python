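"""Case/control ascertainment relative to a reference date.

For one trait, participants matching the trait's codes (or any
``Include_definitions`` trait) become candidate cases; candidates also
matching an ``Exclude_from_cases`` trait are excluded cases; everyone else is
a control, minus controls matching an ``Exclude_from_controls`` trait.  In
the returned 16-column per-participant summary the ``Hx``/``Fu``/``Ref``/
``Any`` indicators carry 2 (yes) or 1 (no) and are negated for excluded
participants, so included case/control read 2/1 and excluded case/control
read −2/−1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as _date

import numpy as np
import pandas as pd

from .codemaps import normalize_code
from .definitions import Definition, DefinitionSet, plan_composite
from .harmonize import EPISODE_COLUMNS, HarmonizedData, _empty_episodes
from .settings import DataSettings, default_settings

logger = logging.getLogger(__name__)

__all__ = ["CASECONTROL_COLUMNS", "AscertainmentResult", "match_episodes",
           "summarize_participant", "get_cases_controls",
           "get_cases_controls_batch", "event_stats", "source_overlap_matrix",
           "timeline_counts", "individual_timeline"]

#: the 16 per-participant summary columns, in order
CASECONTROL_COLUMNS = [
    "identifier", "reference_date", "count", "sum.epidur", "median.epidur",
    "max.epidur", "survival_days", "Death_primary", "Death_any", "Hx_days",
    "Fu_days", "Hx", "Fu", "Ref", "first_diagnosis_days", "Any",
]

_DEATH_PREFIX = "tte.death"


@dataclass
class AscertainmentResult:
    """Three-part result: the all-participant status table, the event table
    of included cases, and the case-only summary."""

    status: pd.DataFrame        # 16 columns, one row per participant
    case_events: pd.DataFrame   # episode columns, included cases only
    case_summary: pd.DataFrame  # 16 columns, cases only (included + excluded)

    def components(self) -> tuple:
        return (self.status, self.case_events, self.case_summary)

    @property
    def statuses(self) -> pd.Series:
        """identifier → status in {2, 1, −1, −2} (the signed Any column)."""
        return self.status.set_index("identifier")["Any"]


def _norm_set(codes: set[str], ignore_case: bool) -> set[str]:
    out = {normalize_code(c) for c in codes}
    return {c.lower() for c in out} if ignore_case else out


def _code_is_nonnegative(code: str) -> bool:
    try:
        return float(code) >= 0
    except (TypeError, ValueError):
        return True  # non-numeric codes are ordinary codes


def match_episodes(definition: Definition, harmonized: HarmonizedData,
                   settings: DataSettings | None = None) -> pd.DataFrame:
    """All episodes matching one (already expanded) definition.

    Code sources match on classification + exact expanded code, self-report
    sources on field specs, touchscreen on canonical condition text.  A
    participant's episodes from source *s* are kept only if there are at
    least ``min_instances(s)`` of them.
    """
    settings = settings or default_settings()
    condition_codes = {c.canonical for c in definition.conditions}
    frames = []
    for source, df in harmonized.episodes.items():
        if source not in settings:
            logger.warning("no settings row for source %r; skipped", source)
            continue
        src = settings[source]
        if source.startswith("sr_"):
            specs = [s for s in definition.field_specs
                     if s.field_id == src.field_id]
            if not specs:
                continue
            mask = pd.Series(False, index=df.index)
            for spec in specs:
                if spec.any_code:
                    mask |= df["code"].map(_code_is_nonnegative)
                else:
                    mask |= df["code"].isin(spec.codes)
        elif src.classification == "ts":
            if not condition_codes:
                continue
            mask = df["code"].isin(condition_codes)
        else:
            codeset = definition.code_sets.get(src.classification)
            if not codeset:
                continue
            wanted = _norm_set(codeset, src.ignore_case)
            norm = df["code"].map(normalize_code)
            if src.ignore_case:
                norm = norm.str.lower()
            mask = norm.isin(wanted)
        hits = df[mask]
        if not len(hits):
            continue
        if src.min_instances > 1:
            counts = hits.groupby("identifier")["code"].transform("size")
            hits = hits[counts >= src.min_instances]
        if len(hits):
            frames.append(hits)
    if not frames:
        return _empty_episodes()
    return pd.concat(frames, ignore_index=True)


def _summarize_events(events: pd.DataFrame, refdates: pd.Series,
                      window_days: int) -> pd.DataFrame:
    """Vectorized per-participant summary of matched events (cases only)."""
    ev = events.merge(refdates.rename("reference_date"), left_on="identifier",
                      right_index=True, how="inner")
    ev["delta"] = (ev["eventdate"] - ev["reference_date"]).dt.days
    g = ev.groupby("identifier", sort=True)

    out = pd.DataFrame(index=g.size().index)
    out["reference_date"] = g["reference_date"].first()
    out["count"] = g.size()
    hosp = ev[ev["epidur"].notna()]
    if len(hosp):
        hg = hosp.groupby("identifier")["epidur"]
        out["sum.epidur"] = hg.sum()
        out["median.epidur"] = hg.median()
        out["max.epidur"] = hg.max()
    else:
        out["sum.epidur"] = np.nan
        out["median.epidur"] = np.nan
        out["max.epidur"] = np.nan

    first = g["delta"].min()
    out["first_diagnosis_days"] = first
    pre = ev[ev["delta"] <= 0].groupby("identifier")["delta"].min()
    out["Hx_days"] = -pre.reindex(out.index)
    out["Hx"] = np.where(out["Hx_days"].notna(), 2, 1)
    post = ev[ev["delta"] > 0].groupby("identifier")["delta"].min()
    out["Fu"] = np.where(first > 0, 2, 1)
    out["Fu_days"] = np.where(out["Fu"] == 2, post.reindex(out.index), np.nan)
    near = ev[ev["delta"].abs() <= window_days].groupby("identifier").size()
    out["Ref"] = np.where(near.reindex(out.index).notna(), 2, 1)

    deaths = ev[ev[".id"].str.startswith(_DEATH_PREFIX)]
    if len(deaths):
        out["survival_days"] = deaths.groupby("identifier")["delta"].min() \
            .reindex(out.index)
        primary = deaths[deaths[".id"].str.endswith("primary")] \
            .groupby("identifier").size().reindex(out.index)
        out["Death_primary"] = np.where(primary.notna(), 2, 1)
        out["Death_any"] = 2
        out["Death_any"] = np.where(
            deaths.groupby("identifier").size().reindex(out.index).notna(), 2, 1)
    else:
        out["survival_days"] = np.nan
        out["Death_primary"] = 1
        out["Death_any"] = 1
    out["Any"] = 2
    out = out.reset_index()
    return out[CASECONTROL_COLUMNS]


def summarize_participant(events: pd.DataFrame, reference_date,
                          window_days: int = 0) -> pd.Series:
    """Summarize the matched events of a single participant.

    Raises on an empty event set — participants without events are controls
    and are produced by :func:`get_cases_controls`, not here.
    """
    if events is None or not len(events):
        raise ValueError("summarize_participant requires at least one event")
    ids = events["identifier"].unique()
    if len(ids) != 1:
        raise ValueError("events must belong to a single participant")
    ref = pd.Series([pd.Timestamp(reference_date)],
                    index=pd.Index(ids, name="identifier"))
    return _summarize_events(events, ref, window_days).iloc[0]


def _as_reference_series(reference_dates, identifiers: np.ndarray) -> pd.Series:
    """Normalize the reference-date argument to identifier-indexed dates."""
    if isinstance(reference_dates, pd.DataFrame):
        s = pd.Series(pd.to_datetime(reference_dates.iloc[:, 1]).values,
                      index=reference_dates.iloc[:, 0].astype(np.int64))
    elif isinstance(reference_dates, pd.Series):
        s = pd.to_datetime(reference_dates)
        s.index = s.index.astype(np.int64)
    elif isinstance(reference_dates, dict):
        s = pd.Series({int(k): pd.Timestamp(v) for k, v in reference_dates.items()})
    elif isinstance(reference_dates, (str, pd.Timestamp, _date)):
        s = pd.Series(pd.Timestamp(reference_dates), index=identifiers)
    else:
        raise TypeError(f"unsupported reference_dates type: {type(reference_dates)}")
    missing = s.isna()
    if missing.any():
        logger.warning("dropping %d participant(s) with missing reference date",
                       int(missing.sum()))
    s = s[~missing]
    s.index.name = "identifier"
    return s


def get_cases_controls(
    defset: DefinitionSet,
    trait: str,
    harmonized: HarmonizedData,
    settings: DataSettings | None = None,
    reference_dates=None,
    window_days: int = 0,
) -> AscertainmentResult:
    """Ascertain case/control status for ``trait`` against reference dates.

    ``reference_dates`` is a single date, a mapping identifier → date, or a
    two-column DataFrame (identifier, date); participants without a
    reference date are dropped with a warning.
    """
    settings = settings or default_settings()
    if trait not in defset:
        raise KeyError(f"trait not defined: {trait!r}")
    refdates = _as_reference_series(reference_dates, harmonized.identifiers)
    pop = refdates.index.intersection(pd.Index(harmonized.identifiers))
    refdates = refdates.loc[pop]

    plan = plan_composite(defset, trait)
    matched: dict[str, pd.DataFrame] = {}
    members: dict[str, set[int]] = {}  # eval(T): own matches ∪ includes'
    for t in plan:
        events_t = match_episodes(defset[t], harmonized, settings)
        matched[t] = events_t
        own = set(events_t["identifier"].unique().tolist())
        for inc in defset[t].include_definitions:
            own |= members[inc]
        members[t] = own

    target = defset[trait]
    pop_set = set(pop.tolist())
    if target.study_population:
        pop_set &= members[target.study_population]
    cases = pop_set & members[trait]
    excluded_cases: set[int] = set()
    for ex in target.exclude_from_cases:
        excluded_cases |= cases & members[ex]
    controls = pop_set - cases
    excluded_controls: set[int] = set()
    for ex in target.exclude_from_controls:
        excluded_controls |= controls & members[ex]

    # events supporting the diagnosis: the trait itself plus its includes
    contributing = [trait]
    stack = list(target.include_definitions)
    while stack:
        t = stack.pop()
        if t not in contributing:
            contributing.append(t)
            stack.extend(defset[t].include_definitions)
    frames = [matched[t] for t in contributing if len(matched[t])]
    all_events = (pd.concat(frames, ignore_index=True).drop_duplicates()
                  if frames else _empty_episodes())
    case_event_pool = all_events[all_events["identifier"].isin(cases)]

    summary = _summarize_events(case_event_pool, refdates, window_days) \
        if len(case_event_pool) else pd.DataFrame(columns=CASECONTROL_COLUMNS)

    status = pd.DataFrame({"identifier": sorted(pop_set)})
    status = status.merge(summary, on="identifier", how="left")
    is_control = ~status["identifier"].isin(cases)
    status.loc[is_control, "reference_date"] = \
        refdates.reindex(status.loc[is_control, "identifier"]).values
    status.loc[is_control, "count"] = 0
    for col in ("Death_primary", "Death_any", "Hx", "Fu", "Ref", "Any"):
        status.loc[is_control, col] = 1
        status[col] = status[col].astype(np.int64)
    status["count"] = status["count"].astype(np.int64)

    flip = status["identifier"].isin(excluded_cases | excluded_controls)
    for col in ("Hx", "Fu", "Ref", "Any"):
        status.loc[flip, col] *= -1
    status = status[CASECONTROL_COLUMNS]

    included = status.loc[status["Any"] == 2, "identifier"]
    case_events = case_event_pool[
        case_event_pool["identifier"].isin(set(included))] \
        .sort_values([".id", "identifier", "eventdate", "code"]) \
        .reset_index(drop=True)[EPISODE_COLUMNS]
    case_summary = status[status["Any"].abs() == 2].reset_index(drop=True)
    return AscertainmentResult(status, case_events, case_summary)


def get_cases_controls_batch(
    defset: DefinitionSet,
    traits: list[str],
    harmonized: HarmonizedData,
    settings: DataSettings | None = None,
    reference_dates=None,
    window_days: int = 0,
) -> pd.DataFrame:
    """Loop over traits and merge their summaries into one wide table with
    ``<trait>_0_<column>`` names."""
    wide: pd.DataFrame | None = None
    for trait in traits:
        res = get_cases_controls(defset, trait, harmonized, settings,
                                 reference_dates, window_days)
        part = res.status.rename(columns={
            c: f"{trait}_0_{c}" for c in CASECONTROL_COLUMNS if c != "identifier"})
        wide = part if wide is None else wide.merge(part, on="identifier",
                                                    how="outer")
    return wide if wide is not None else pd.DataFrame(columns=["identifier"])


def event_stats(case_events: pd.DataFrame) -> pd.DataFrame:
    """Per-code frequencies over the case event table, sorted descending."""
    if not len(case_events):
        return pd.DataFrame(columns=["classification", "code", "event_count",
                                     "participant_count", "participant_fraction"])
    total = case_events["identifier"].nunique()
    g = case_events.groupby(["classification", "code"])
    out = pd.DataFrame({
        "event_count": g.size(),
        "participant_count": g["identifier"].nunique(),
    }).reset_index()
    out["participant_fraction"] = out["participant_count"] / total
    return out.sort_values(["event_count", "classification", "code"],
                           ascending=[False, True, True]).reset_index(drop=True)


def source_overlap_matrix(definition: Definition, harmonized: HarmonizedData,
                          reference_dates=None,
                          settings: DataSettings | None = None) -> pd.DataFrame:
    """Participant × source boolean membership for pre-reference evidence
    (rows only for participants with at least one pre-reference match)."""
    settings = settings or default_settings()
    matched = match_episodes(definition, harmonized, settings)
    if not len(matched):
        return pd.DataFrame()
    refdates = _as_reference_series(reference_dates, harmonized.identifiers)
    ev = matched.merge(refdates.rename("reference_date"), left_on="identifier",
                       right_index=True, how="inner")
    ev = ev[ev["eventdate"] <= ev["reference_date"]]
    if not len(ev):
        return pd.DataFrame()
    table = ev.assign(flag=True).pivot_table(
        index="identifier", columns=".id", values="flag", aggfunc="any",
        fill_value=False)
    table.columns.name = None
    return table.astype(bool)


def timeline_counts(definition: Definition, harmonized: HarmonizedData,
                    settings: DataSettings | None = None) -> pd.DataFrame:
    """(year, source) → matched event count; only dated events (flag 1/2)."""
    settings = settings or default_settings()
    matched = match_episodes(definition, harmonized, settings)
    matched = matched[matched["event"].isin((1, 2))]
    if not len(matched):
        return pd.DataFrame(columns=["year", ".id", "count"])
    out = (matched.assign(year=matched["eventdate"].dt.year)
           .groupby(["year", ".id"]).size().rename("count").reset_index())
    return out.sort_values(["year", ".id"]).reset_index(drop=True)


def individual_timeline(harmonized: HarmonizedData,
                        identifier: int) -> pd.DataFrame:
    """All episodes for one participant, date-ordered (ties: source, code)."""
    all_ep = harmonized.all_episodes()
    mine = all_ep[all_ep["identifier"] == identifier]
    return mine.sort_values(["eventdate", ".id", "code"]) \
        .reset_index(drop=True)[EPISODE_COLUMNS]
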