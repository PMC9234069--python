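"""Per-source harmonization rules (the data-settings table).

Each harmonizable source has one row declaring which definition-table column
supplies its codes, its classification system, whether that system is
hierarchical, how event dates are derived and the event flag assigned when a
usable date exists, plus the minimum number of episodes a participant needs
from the source before they count (``min_instances``).

``date_rule`` values:

``record``
    the event date is carried on the record itself (hospital, GP, death);
``year:<field>``
    companion main-dataset field holds the (possibly interpolated) calendar
    year of the event;
``age:<field>``
    companion field holds age at event; converted via the birth date;
``condition``
    touchscreen source — the age field, if any, is attached per condition;
``none``
    no timing information exists; dates are imputed from the visit date.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

__all__ = ["SourceSettings", "DataSettings", "default_settings", "read_data_settings",
           "write_data_settings"]

SETTINGS_COLUMNS = [
    "source_id", "definition_column", "classification", "hierarchical",
    "ignore_case", "date_rule", "default_event_flag", "min_instances",
]


@dataclass(frozen=True)
class SourceSettings:
    source_id: str
    definition_column: str
    classification: str
    hierarchical: bool = True
    ignore_case: bool = False
    date_rule: str = "record"
    default_event_flag: int = 1
    min_instances: int = 1

    @property
    def field_id(self) -> int | None:
        """Main-dataset field id for self-report sources (``sr_<field>``)."""
        if self.source_id.startswith("sr_"):
            return int(self.source_id.split("_", 1)[1])
        return None

    @property
    def timing_field(self) -> int | None:
        """Companion timing field id, if the date rule names one."""
        if ":" in self.date_rule:
            return int(self.date_rule.split(":", 1)[1])
        return None

    @property
    def timing_kind(self) -> str:
        return self.date_rule.split(":", 1)[0]


@dataclass
class DataSettings:
    """The full settings table plus the handful of structural field numbers."""

    sources: dict[str, SourceSettings]
    visit_date_field: int = 53
    birth_year_field: int = 34
    birth_month_field: int = 52
    centre_field: int = 54

    def __getitem__(self, source_id: str) -> SourceSettings:
        return self.sources[source_id]

    def __iter__(self):
        return iter(self.sources.values())

    def __contains__(self, source_id: str) -> bool:
        return source_id in self.sources

    def definition_columns(self) -> list[str]:
        """Distinct code-bearing definition-table columns, settings order."""
        seen: list[str] = []
        for s in self.sources.values():
            if s.definition_column not in seen:
                seen.append(s.definition_column)
        return seen

    def classification_columns(self) -> dict[str, str]:
        """classification label -> definition column (for code-set sources)."""
        out: dict[str, str] = {}
        for s in self.sources.values():
            if s.source_id.startswith(("sr_", "ts")):
                continue
            out.setdefault(s.classification, s.definition_column)
        return out

    def self_report_sources(self) -> list[SourceSettings]:
        return [s for s in self.sources.values() if s.source_id.startswith("sr_")]

    def with_min_instances(self, source_id: str, n: int) -> "DataSettings":
        sources = dict(self.sources)
        sources[source_id] = replace(sources[source_id], min_instances=n)
        return DataSettings(sources, self.visit_date_field, self.birth_year_field,
                            self.birth_month_field, self.centre_field)


def default_settings() -> DataSettings:
    """Settings wiring for the canonical source identifiers."""
    rows = [
        SourceSettings("hesin_icd10", "ICD10", "icd10"),
        SourceSettings("hesin_icd9", "ICD9", "icd9"),
        SourceSettings("hesin_oper4", "OPCS4", "opcs4"),
        SourceSettings("gpclinical.read2", "READ2", "read2"),
        SourceSettings("gpclinical.read3", "CTV3", "read3"),
        SourceSettings("gpscripts", "Rx", "dmd", hierarchical=False),
        SourceSettings("tte.death.icd10.primary", "ICD10", "icd10"),
        SourceSettings("tte.death.icd10.secondary", "ICD10", "icd10"),
        SourceSettings("sr_20001", "SR", "sr_20001", hierarchical=False,
                       date_rule="year:20006", default_event_flag=2),
        SourceSettings("sr_20002", "SR", "sr_20002", hierarchical=False,
                       date_rule="year:20008", default_event_flag=2),
        SourceSettings("sr_20003", "SR", "sr_20003", hierarchical=False,
                       date_rule="none", default_event_flag=0),
        SourceSettings("sr_20004", "SR", "sr_20004", hierarchical=False,
                       date_rule="year:20010", default_event_flag=1),
        SourceSettings("ts", "TS", "ts", hierarchical=False,
                       date_rule="condition", default_event_flag=2),
    ]
    return DataSettings({s.source_id: s for s in rows})


def _as_bool(v) -> bool:
    return str(v).strip().lower() in {"1", "true", "t", "yes"}


def read_data_settings(path: str | Path) -> DataSettings:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"data-settings file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(SETTINGS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"data-settings file missing columns: {sorted(missing)}")
    sources = {}
    for _, row in df.iterrows():
        s = SourceSettings(
            source_id=row["source_id"].strip(),
            definition_column=row["definition_column"].strip(),
            classification=row["classification"].strip(),
            hierarchical=_as_bool(row["hierarchical"]),
            ignore_case=_as_bool(row["ignore_case"]),
            date_rule=row["date_rule"].strip() or "record",
            default_event_flag=int(row["default_event_flag"]),
            min_instances=int(row["min_instances"]),
        )
        sources[s.source_id] = s
    return DataSettings(sources)


def write_data_settings(settings: DataSettings, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "source_id": s.source_id,
            "definition_column": s.definition_column,
            "classification": s.classification,
            "hierarchical": int(s.hierarchical),
            "ignore_case": int(s.ignore_case),
            "date_rule": s.date_rule,
            "default_event_flag": s.default_event_flag,
            "min_instances": s.min_instances,
        }
        for s in settings
    ]
    pd.DataFrame(rows, columns=SETTINGS_COLUMNS).to_csv(path, sep="\t", index=False)
    return path
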