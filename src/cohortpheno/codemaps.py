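"""Classification-system code maps: loading, prefix expansion and extraction.

A code map lists every code known to one classification system (e.g. ICD-10,
READ2).  Hierarchical systems allow a definition table to carry only parent
codes; :func:`expand_codes` closes a pattern list over the map by prefix.

READ2/CTV3 codes are padded to five characters with trailing dots
(``"G573."``).  The padding is stripped before prefix comparison but the
original strings are preserved in every output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CodeMap", "load_code_map", "expand_codes", "extract_existing_codes"]


def normalize_code(code: str) -> str:
    """Trim whitespace and strip READ-style trailing-dot padding."""
    return code.strip().rstrip(".")


@dataclass
class CodeMap:
    """All known codes of one classification system.

    Parameters
    ----------
    system_id
        Short label such as ``"icd10"`` or ``"read2"``.
    codes
        Unique code strings, whitespace-trimmed.
    description
        Optional mapping from code to free text; keys must be codes.
    hierarchical
        Whether prefix hierarchy applies (parent codes expand to children).
    """

    system_id: str
    codes: set[str]
    description: dict[str, str] = field(default_factory=dict)
    hierarchical: bool = True

    def __post_init__(self) -> None:
        if not self.system_id:
            raise ValueError("system_id must be non-empty")
        self.codes = {c.strip() for c in self.codes}
        unknown = set(self.description) - self.codes
        if unknown:
            raise ValueError(f"description keys not in codes: {sorted(unknown)[:5]}")

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def __len__(self) -> int:
        return len(self.codes)


def load_code_map(path: str | Path, system_id: str, hierarchical: bool = True) -> CodeMap:
    """Read a plain-text code map (one or two tab-separated columns, no header).

    Column 1 is the code, optional column 2 a free-text description.
    Duplicate codes collapse to one entry (first description wins).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"code map file not found: {path}")
    codes: set[str] = set()
    descriptions: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            code = parts[0].strip()
            if not code:
                continue
            codes.add(code)
            if len(parts) > 1 and parts[1].strip() and code not in descriptions:
                descriptions[code] = parts[1].strip()
    if not codes:
        raise ValueError(f"code map file has no parseable rows: {path}")
    return CodeMap(system_id=system_id, codes=codes, description=descriptions,
                   hierarchical=hierarchical)


def expand_codes(
    patterns: list[str] | set[str],
    code_map: CodeMap,
    ignore_case: bool = False,
) -> set[str]:
    """Expand patterns over a code map.

    For hierarchical maps, returns every map code of which a pattern is a
    prefix after normalization (trailing-dot stripping), plus exact matches.
    For flat maps, exact (normalized) matches only.  The result is always a
    subset of ``code_map.codes``.
    """

    def norm(c: str) -> str:
        c = normalize_code(c)
        return c.lower() if ignore_case else c

    pats = [norm(p) for p in patterns if norm(p)]
    if not pats:
        return set()
    out: set[str] = set()
    for code in code_map.codes:
        ncode = norm(code)
        for p in pats:
            if ncode == p or (code_map.hierarchical and ncode.startswith(p)):
                out.add(code)
                break
    return out


def extract_existing_codes(
    record_path: str | Path,
    code_columns: list[str],
    out_prefix: str | Path,
) -> list[Path]:
    """Extract per-column flat code maps from a record-level table.

    Writes one file ``<out_prefix><column>.tsv`` per requested column holding
    the sorted unique non-empty codes of that column.  Returns written paths.
    """
    record_path = Path(record_path)
    if not record_path.exists():
        raise FileNotFoundError(f"record file not found: {record_path}")
    df = pd.read_csv(record_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in code_columns if c not in df.columns]
    if missing:
        raise KeyError(f"column(s) not found in {record_path.name}: {missing}")
    out_prefix = Path(out_prefix)
    if out_prefix.is_dir() or str(out_prefix).endswith("/"):
        out_prefix.mkdir(parents=True, exist_ok=True)
        make = lambda col: out_prefix / f"{col}.tsv"  # noqa: E731
    else:
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        make = lambda col: out_prefix.parent / f"{out_prefix.name}{col}.tsv"  # noqa: E731
    written: list[Path] = []
    for col in code_columns:
        values = sorted({v.strip() for v in df[col] if v.strip()})
        if not values:
            logger.warning("column %s of %s has no codes; writing empty map",
                           col, record_path.name)
        out = make(col)
        out.write_text("\n".join(values) + ("\n" if values else ""), encoding="utf-8")
        written.append(out)
    return written
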