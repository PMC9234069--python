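"""Censoring-aware observed time for survival analyses.

Secondary-care censoring dates differ by region; the region is inferred from
the assessment-centre code.  Observed time runs from the baseline visit up to
the event date for incident cases, else up to the earliest of the death date
and the regional censoring date.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CensorConfig", "censor_date_for_centre", "derive_followup",
           "derive_followup_table", "read_censor_config", "write_censor_config"]

# assessment-centre code -> region
_DEFAULT_CENTRE_REGION = {
    **{c: "england" for c in (
        "10003", "11001", "11002", "11007", "11008", "11009", "11010", "11011",
        "11012", "11013", "11014", "11016", "11017", "11018", "11019", "11020",
        "11021")},
    **{c: "scotland" for c in ("11004", "11005")},
    **{c: "wales" for c in ("11003", "11022", "11006", "11023")},
}

# secondary-care (hospital inpatient) censoring dates per region; these move
# between releases and are overridable per run
_DEFAULT_REGION_CENSOR = {
    "england": "2021-03-31",
    "scotland": "2021-03-31",
    "wales": "2018-02-28",
}


@dataclass
class CensorConfig:
    region_censor: dict[str, pd.Timestamp] = field(default_factory=dict)
    centre_region: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.region_censor:
            self.region_censor = {r: pd.Timestamp(d)
                                  for r, d in _DEFAULT_REGION_CENSOR.items()}
        else:
            self.region_censor = {r: pd.Timestamp(d)
                                  for r, d in self.region_censor.items()}
        if not self.centre_region:
            self.centre_region = dict(_DEFAULT_CENTRE_REGION)
        missing = set(self.centre_region.values()) - set(self.region_censor)
        if missing:
            raise ValueError(f"regions without a censor date: {sorted(missing)}")


def censor_date_for_centre(centre_code, config: CensorConfig | None = None):
    """Secondary-care censor date for an assessment-centre code.

    Unknown centres yield NaT with a warning rather than an error.
    """
    config = config or CensorConfig()
    code = str(centre_code).strip()
    if code.endswith(".0"):
        code = code[:-2]
    region = config.centre_region.get(code)
    if region is None:
        logger.warning("unknown assessment centre code %r; censor date missing",
                       centre_code)
        return pd.NaT
    return config.region_censor[region]


def derive_followup(fu_indicator: int, fu_days, death_date, visit_date,
                    censor_date) -> tuple[float, str]:
    """Observed time and outcome for one participant.

    Incident cases (``fu_indicator == 2``) keep their event time; non-events
    are censored at death if it precedes the censoring date, otherwise at the
    censoring date.
    """
    visit = pd.Timestamp(visit_date)
    censor = pd.Timestamp(censor_date)
    if visit > censor:
        raise ValueError(f"visit date {visit.date()} is after censor date "
                         f"{censor.date()}")
    if fu_indicator == 2:
        if fu_days is None or pd.isna(fu_days):
            raise ValueError("incident case with missing fu_days")
        return float(fu_days), "event"
    if death_date is not None and pd.notna(death_date):
        death = pd.Timestamp(death_date)
        if death <= censor:
            return float((death - visit).days), "censored"
    return float((censor - visit).days), "censored"


def derive_followup_table(status: pd.DataFrame, visit_dates: pd.Series,
                          centre_codes: pd.Series,
                          death_dates: pd.Series | None = None,
                          config: CensorConfig | None = None) -> pd.DataFrame:
    """Vectorized :func:`derive_followup` over an ascertainment status table.

    ``visit_dates``, ``centre_codes`` and ``death_dates`` are indexed by
    identifier.  Returns identifier, observed_days and outcome.
    """
    config = config or CensorConfig()
    rows = []
    for _, r in status.iterrows():
        ident = r["identifier"]
        censor = censor_date_for_centre(centre_codes.get(ident), config)
        visit = visit_dates.get(ident)
        if pd.isna(censor) or pd.isna(visit):
            continue
        death = death_dates.get(ident) if death_dates is not None else None
        observed, outcome = derive_followup(
            abs(int(r["Fu"])), r.get("Fu_days"), death, visit, censor)
        rows.append({"identifier": ident, "observed_days": observed,
                     "outcome": outcome})
    return pd.DataFrame(rows, columns=["identifier", "observed_days", "outcome"])


def read_censor_config(path: str | Path) -> CensorConfig:
    """Read a censor config TSV with rows ``region <tab> date`` and
    ``centre <tab> region`` (a ``kind`` column distinguishes them)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    region_censor, centre_region = {}, {}
    for _, row in df.iterrows():
        if row["kind"] == "region":
            region_censor[row["key"]] = pd.Timestamp(row["value"])
        elif row["kind"] == "centre":
            centre_region[row["key"]] = row["value"]
        else:
            raise ValueError(f"unknown censor-config kind {row['kind']!r}")
    return CensorConfig(region_censor, centre_region)


def write_censor_config(config: CensorConfig, path: str | Path) -> Path:
    path = Path(path)
    rows = [{"kind": "region", "key": r, "value": d.strftime("%Y-%m-%d")}
            for r, d in sorted(config.region_censor.items())]
    rows += [{"kind": "centre", "key": c, "value": r}
             for c, r in sorted(config.centre_region.items())]
    pd.DataFrame(rows, columns=["kind", "key", "value"]).to_csv(
        path, sep="\t", index=False)
    return path
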