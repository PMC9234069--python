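"""Readers for the main dataset, its field metadata, record-level tables and
withdrawal lists.

The main dataset is a wide TSV whose columns are labelled
``f.<field>.<instance>.<array>`` with the participant identifier in
``f.eid``.  Field metadata comes either from the html document produced
alongside the dataset or from a three-column TSV fallback
(``column_label``, ``field_id``, ``type``) which is the stable contract.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from html.parser import HTMLParser
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CatalogEntry", "FieldCatalog", "read_field_catalog",
           "read_main_dataset", "read_withdrawals", "read_record_table"]

VALUE_TYPES = {"integer", "real", "text", "date", "categorical"}

_TYPE_SYNONYMS = {
    "integer": "integer", "sequence": "integer",
    "continuous": "real", "real": "real",
    "text": "text", "compound": "text",
    "date": "date", "time": "date",
    "categorical (single)": "categorical", "categorical (multiple)": "categorical",
    "categorical single": "categorical", "categorical multiple": "categorical",
    "categorical": "categorical",
}


@dataclass(frozen=True)
class CatalogEntry:
    field_id: int
    instance: int
    array: int
    value_type: str  # one of VALUE_TYPES


@dataclass
class FieldCatalog:
    """Mapping of main-dataset column labels to typed field coordinates."""

    entries: dict[str, CatalogEntry]

    def columns_for_field(self, field_id: int) -> list[str]:
        return [label for label, e in self.entries.items() if e.field_id == field_id]

    def value_type(self, field_id: int) -> str | None:
        for e in self.entries.values():
            if e.field_id == field_id:
                return e.value_type
        return None

    def field_ids(self) -> set[int]:
        return {e.field_id for e in self.entries.values()}


def _normalize_type(raw: str) -> str:
    t = _TYPE_SYNONYMS.get(raw.strip().lower())
    if t is None:
        logger.warning("unknown field type %r; treating as text", raw)
        t = "text"
    return t


_LABEL_RE = re.compile(r"^f\.(\d+)\.(\d+)\.(\d+)$")
_UDI_RE = re.compile(r"^(\d+)-(\d+)\.(\d+)$")


def _entry_from_label(label: str, vtype: str) -> tuple[str, CatalogEntry] | None:
    if label in ("f.eid", "eid", "identifier"):
        return "identifier", CatalogEntry(0, 0, 0, "integer")
    m = _LABEL_RE.match(label) or _UDI_RE.match(label)
    if not m:
        return None
    f, i, a = (int(g) for g in m.groups())
    return f"f.{f}.{i}.{a}", CatalogEntry(f, i, a, vtype)


class _MetadataHTMLParser(HTMLParser):
    """Pulls (UDI/column, type) pairs out of the first metadata table."""

    def __init__(self) -> None:
        super().__init__()
        self.rows: list[list[str]] = []
        self._row: list[str] | None = None
        self._cell: list[str] | None = None

    def handle_starttag(self, tag, attrs):
        if tag == "tr":
            self._row = []
        elif tag in ("td", "th"):
            self._cell = []

    def handle_endtag(self, tag):
        if tag in ("td", "th") and self._cell is not None and self._row is not None:
            self._row.append(" ".join("".join(self._cell).split()))
            self._cell = None
        elif tag == "tr" and self._row is not None:
            if self._row:
                self.rows.append(self._row)
            self._row = None

    def handle_data(self, data):
        if self._cell is not None:
            self._cell.append(data)


def _catalog_from_html(path: Path) -> FieldCatalog:
    parser = _MetadataHTMLParser()
    parser.feed(path.read_text(encoding="utf-8", errors="replace"))
    header = None
    entries: dict[str, CatalogEntry] = {}
    for row in parser.rows:
        lowered = [c.lower() for c in row]
        if header is None:
            if any(c in ("udi", "column", "column_label") for c in lowered) \
                    and "type" in lowered:
                header = {name: idx for idx, name in enumerate(lowered)}
            continue
        label_idx = next(header[k] for k in ("udi", "column", "column_label")
                         if k in header)
        type_idx = header["type"]
        if len(row) <= max(label_idx, type_idx):
            continue
        parsed = _entry_from_label(row[label_idx], _normalize_type(row[type_idx]))
        if parsed:
            entries[parsed[0]] = parsed[1]
    if header is None or not entries:
        raise ValueError(f"could not locate a metadata table in {path}")
    return FieldCatalog(entries)


def _catalog_from_tsv(path: Path) -> FieldCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"column_label", "field_id", "type"}
    if not required <= set(df.columns):
        raise ValueError(f"metadata TSV {path} must have columns {sorted(required)}")
    entries: dict[str, CatalogEntry] = {}
    for _, row in df.iterrows():
        parsed = _entry_from_label(row["column_label"], _normalize_type(row["type"]))
        if parsed is None:
            logger.warning("skipping unparseable column label %r", row["column_label"])
            continue
        entries[parsed[0]] = parsed[1]
    if not entries:
        raise ValueError(f"metadata TSV {path} yielded no entries")
    return FieldCatalog(entries)


def read_field_catalog(metadata_path: str | Path) -> FieldCatalog:
    """Read field metadata from the html document or the TSV fallback.

    The participant-identifier column (``f.eid``) is mapped to
    ``identifier`` in the catalog.
    """
    path = Path(metadata_path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    head = path.read_text(encoding="utf-8", errors="replace")[:2048].lower()
    if path.suffix in (".html", ".htm") or "<html" in head or "<table" in head:
        return _catalog_from_html(path)
    return _catalog_from_tsv(path)


def _convert_column(series: pd.Series, vtype: str) -> pd.Series:
    s = series.replace({"": None, "NA": None})
    if vtype == "integer":
        return pd.to_numeric(s, errors="raise").astype("Int64")
    if vtype == "real":
        return pd.to_numeric(s, errors="raise").astype(float)
    if vtype == "date":
        # ISO-8601 only; anything else is a correctness hazard and fails loudly
        return pd.to_datetime(s, format="%Y-%m-%d", errors="raise")
    return s.astype("string")


def read_main_dataset(
    tab_path: str | Path,
    catalog: FieldCatalog,
    fields_to_keep: list[int],
    allow_missing: bool = True,
) -> pd.DataFrame:
    """Read the identifier plus all instances/arrays of the requested fields,
    typed per the catalog (dates parsed as ISO-8601 calendar dates)."""
    tab_path = Path(tab_path)
    if not tab_path.exists():
        raise FileNotFoundError(f"main dataset not found: {tab_path}")
    header = pd.read_csv(tab_path, sep="\t", nrows=0).columns.tolist()
    id_col = next((c for c in ("f.eid", "identifier", "eid") if c in header), None)
    if id_col is None:
        raise ValueError(f"main dataset {tab_path} lacks an identifier column (f.eid)")
    usecols = [id_col]
    for fid in fields_to_keep:
        labels = [c for c in catalog.columns_for_field(fid) if c in header]
        if not labels:
            if allow_missing:
                logger.warning("field %s missing from main dataset; skipped", fid)
                continue
            raise KeyError(f"field {fid} required by the definition table is "
                           f"missing from the main dataset {tab_path}")
        usecols.extend(labels)
    df = pd.read_csv(tab_path, sep="\t", dtype=str, keep_default_na=False,
                     usecols=usecols)[usecols]
    df = df.rename(columns={id_col: "identifier"})
    df["identifier"] = pd.to_numeric(df["identifier"], errors="raise").astype(np.int64)
    if df["identifier"].duplicated().any():
        raise ValueError("duplicate participant identifiers in main dataset")
    for col in df.columns[1:]:
        df[col] = _convert_column(df[col], catalog.entries[col].value_type)
    return df


def read_withdrawals(path: str | Path | None) -> set[int]:
    """Read a withdrawal list: one identifier per line, optional header."""
    if path is None:
        return set()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"withdrawal list not found: {path}")
    out: set[int] = set()
    for i, line in enumerate(path.read_text(encoding="utf-8").splitlines()):
        token = line.split(",")[0].strip()
        if not token:
            continue
        try:
            out.add(int(token))
        except ValueError:
            if i == 0:  # header line like "V1"
                continue
            raise ValueError(f"non-numeric identifier {token!r} in {path}")
    return out


def read_record_table(path: str | Path, id_column: str = "eid") -> pd.DataFrame:
    """Read a record-level TSV; the identifier column is normalized to
    ``identifier`` and parsed as integer, all other columns stay text."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"record-level file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if id_column not in df.columns:
        alt = next((c for c in ("eid", "identifier") if c in df.columns), None)
        if alt is None:
            raise ValueError(f"{path} lacks identifier column {id_column!r}")
        id_column = alt
    df = df.rename(columns={id_column: "identifier"})
    df["identifier"] = pd.to_numeric(df["identifier"], errors="raise").astype(np.int64)
    return df
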