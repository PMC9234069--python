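"""Phenotype definition tables.

One trait per row.  Code columns carry comma-separated code lists (with
optional parenthesised annotations and parent codes to be expanded over the
code maps), the self-report column carries field specs like
``20002(1471, 1483)``, the touchscreen column carries comparator conditions
like ``6177=3(insulin)``, and four composite columns reference other traits.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .codemaps import CodeMap, expand_codes, load_code_map
from .settings import DataSettings

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError", "CodePattern", "Condition", "FieldSpec", "Definition",
    "DefinitionSet", "ValidationReport", "parse_code_entry", "parse_field_spec",
    "parse_condition", "read_definition_table", "write_definition_table",
    "plan_composite",
]

COMPOSITE_COLUMNS = ("Study_population", "Include_definitions",
                     "Exclude_from_cases", "Exclude_from_controls")

COMPARATORS = ("!=", ">=", "<=", "=", "<", ">")
_COMPARATOR_ALIASES = {"≥": ">=", "≤": "<="}

ANY = "ANY"  # sentinel: bare field number, any non-negative value counts


class ParseError(ValueError):
    """Raised on malformed definition-table cells."""


@dataclass(frozen=True)
class CodePattern:
    raw: str
    code: str
    annotation: str | None = None


@dataclass(frozen=True)
class Condition:
    """A touchscreen condition such as ``4041=1[2976](Gestational diabetes)``."""

    field_id: int
    comparator: str
    value: str
    age_field: int | None = None
    annotation: str | None = None

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise ParseError(
                f"unknown comparator {self.comparator!r}; accepted: "
                f"{', '.join(COMPARATORS)} (≥ and ≤ are aliases)")
        if self.field_id <= 0:
            raise ParseError(f"field id must be positive, got {self.field_id}")

    @property
    def canonical(self) -> str:
        """Comparator text without annotation/age — used as the episode code."""
        return f"{self.field_id}{self.comparator}{self.value}"

    def serialize(self) -> str:
        text = self.canonical
        if self.age_field is not None:
            text += f"[{self.age_field}]"
        if self.annotation:
            text += f"({self.annotation})"
        return text


@dataclass(frozen=True)
class FieldSpec:
    """A self-report field with specific codes, or any code (bare number)."""

    field_id: int
    codes: frozenset[str] | None = None  # None means ANY

    @property
    def any_code(self) -> bool:
        return self.codes is None

    def serialize(self) -> str:
        if self.any_code:
            return str(self.field_id)
        return f"{self.field_id}({', '.join(sorted(self.codes))})"


@dataclass
class Definition:
    trait: str
    code_sets: dict[str, set[str]] = field(default_factory=dict)
    raw_patterns: dict[str, list[CodePattern]] = field(default_factory=dict)
    field_specs: list[FieldSpec] = field(default_factory=list)
    conditions: list[Condition] = field(default_factory=list)
    study_population: str | None = None
    include_definitions: list[str] = field(default_factory=list)
    exclude_from_cases: list[str] = field(default_factory=list)
    exclude_from_controls: list[str] = field(default_factory=list)
    description: str = ""

    def references(self) -> list[str]:
        refs = list(self.include_definitions) + list(self.exclude_from_cases) \
            + list(self.exclude_from_controls)
        if self.study_population:
            refs.append(self.study_population)
        return refs


@dataclass
class ValidationReport:
    dropped_codes: list[tuple[str, str, str]] = field(default_factory=list)  # trait, column, code
    warnings: list[str] = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        logger.warning(message)


@dataclass
class DefinitionSet:
    definitions: list[Definition]
    report: ValidationReport = field(default_factory=ValidationReport)

    def __post_init__(self) -> None:
        traits = [d.trait for d in self.definitions]
        dupes = {t for t in traits if traits.count(t) > 1}
        if dupes:
            raise ParseError(f"duplicate TRAIT identifier(s): {sorted(dupes)}")

    def __getitem__(self, trait: str) -> Definition:
        for d in self.definitions:
            if d.trait == trait:
                return d
        raise KeyError(f"trait not defined: {trait!r}")

    def __contains__(self, trait: str) -> bool:
        return any(d.trait == trait for d in self.definitions)

    def __iter__(self):
        return iter(self.definitions)

    def traits(self) -> list[str]:
        return [d.trait for d in self.definitions]

    def __eq__(self, other) -> bool:  # report is diagnostics, not identity
        if not isinstance(other, DefinitionSet):
            return NotImplemented
        return self.definitions == other.definitions


def _split_outside_parens(text: str, sep: str = ",") -> list[str]:
    """Split on ``sep`` at paren depth zero; raises on unbalanced parens."""
    parts: list[str] = []
    depth = 0
    current: list[str] = []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ParseError(f"unbalanced parentheses in {text!r}")
        if ch == sep and depth == 0:
            parts.append("".join(current))
            current = []
        else:
            current.append(ch)
    if depth != 0:
        raise ParseError(f"unbalanced parentheses in {text!r}")
    parts.append("".join(current))
    return [p.strip() for p in parts if p.strip()]


_CODE_RE = re.compile(r"^(?P<code>[^()]+?)\s*(?:\((?P<ann>[^()]*)\))?$")


def parse_code_entry(text: str) -> list[CodePattern]:
    """Parse a comma-separated code list; ``(…)`` annotates the preceding code."""
    if text is None or not str(text).strip():
        return []
    patterns: list[CodePattern] = []
    for frag in _split_outside_parens(str(text)):
        m = _CODE_RE.match(frag)
        if not m or not m.group("code").strip():
            raise ParseError(f"cannot parse code entry fragment {frag!r}")
        ann = m.group("ann")
        patterns.append(CodePattern(raw=frag, code=m.group("code").strip(),
                                    annotation=ann.strip() if ann else None))
    return patterns


_FIELD_SPEC_RE = re.compile(r"^(?P<field>\d+)\s*(?:\((?P<codes>[^()]*)\))?$")


def parse_field_spec(text: str) -> FieldSpec:
    m = _FIELD_SPEC_RE.match(str(text).strip())
    if not m:
        raise ParseError(f"cannot parse field spec {text!r} (expected "
                         "'field' or 'field(code, …)')")
    codes_text = m.group("codes")
    if codes_text is None:
        return FieldSpec(field_id=int(m.group("field")))
    codes = frozenset(c.strip() for c in codes_text.split(",") if c.strip())
    if not codes:
        return FieldSpec(field_id=int(m.group("field")))
    return FieldSpec(field_id=int(m.group("field")), codes=codes)


_CONDITION_RE = re.compile(
    r"^(?P<field>\d+)\s*(?P<cmp>!=|>=|<=|≥|≤|=|<|>)\s*"
    r"(?P<value>[^\[\]()]+?)\s*(?:\[(?P<age>\d+)\])?\s*(?:\((?P<ann>[^()]*)\))?$")


def parse_condition(text: str) -> Condition:
    text = str(text).strip()
    m = _CONDITION_RE.match(text)
    if not m:
        raise ParseError(
            f"cannot parse condition {text!r}; accepted comparators: "
            f"{', '.join(COMPARATORS)} plus aliases ≥, ≤")
    cmp_ = _COMPARATOR_ALIASES.get(m.group("cmp"), m.group("cmp"))
    ann = m.group("ann")
    return Condition(
        field_id=int(m.group("field")),
        comparator=cmp_,
        value=m.group("value").strip(),
        age_field=int(m.group("age")) if m.group("age") else None,
        annotation=ann.strip() if ann else None,
    )


def _parse_trait_list(text: str) -> list[str]:
    if text is None or not str(text).strip():
        return []
    return [t.strip() for t in str(text).split(",") if t.strip()]


def _load_maps(codemap_dir: str | Path | None, settings: DataSettings,
               report: ValidationReport) -> dict[str, CodeMap]:
    maps: dict[str, CodeMap] = {}
    if codemap_dir is None:
        return maps
    codemap_dir = Path(codemap_dir)
    for classification in settings.classification_columns():
        path = codemap_dir / f"{classification}.tsv"
        if path.exists():
            hierarchical = any(s.hierarchical for s in settings
                               if s.classification == classification)
            maps[classification] = load_code_map(path, classification, hierarchical)
        else:
            report.warn(f"no code map for {classification} at {path}; "
                        "codes taken as-is without expansion")
    return maps


def read_definition_table(
    path: str | Path,
    settings: DataSettings,
    codemap_dir: str | Path | None = None,
) -> DefinitionSet:
    """Read, validate and expand a phenotype definition table.

    Parent codes are expanded over the code maps found in ``codemap_dir``
    (one ``<classification>.tsv`` per system).  Codes that match nothing in
    their map are dropped and listed in the validation report.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"definition table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "TRAIT" not in df.columns:
        raise ParseError(f"definition table {path} lacks a TRAIT column")
    report = ValidationReport()
    maps = _load_maps(codemap_dir, settings, report)

    code_columns = settings.classification_columns()  # classification -> column
    column_to_classification = {col: cls for cls, col in code_columns.items()}
    sr_column = next((s.definition_column for s in settings.self_report_sources()), None)
    ts_column = next((s.definition_column for s in settings
                      if s.classification == "ts"), None)
    known = ({"TRAIT", "DESCRIPTION"} | set(COMPOSITE_COLUMNS)
             | set(column_to_classification) | {sr_column, ts_column}) - {None}
    for col in df.columns:
        if col not in known:
            report.warn(f"ignoring unknown definition-table column {col!r}")

    ignore_case = {s.classification: s.ignore_case for s in settings}
    definitions: list[Definition] = []
    for _, row in df.iterrows():
        trait = row["TRAIT"].strip()
        if not trait:
            raise ParseError("empty TRAIT identifier")
        d = Definition(trait=trait, description=row.get("DESCRIPTION", "").strip())
        for col, classification in column_to_classification.items():
            if col not in df.columns:
                continue
            patterns = parse_code_entry(row[col])
            if not patterns:
                continue
            d.raw_patterns[col] = patterns
            cmap = maps.get(classification)
            if cmap is None:
                d.code_sets[classification] = {p.code for p in patterns}
                continue
            expanded: set[str] = set()
            for p in patterns:
                hits = expand_codes([p.code], cmap,
                                    ignore_case=ignore_case.get(classification, False))
                if not hits:
                    report.dropped_codes.append((trait, col, p.code))
                    report.warn(f"{trait}: code {p.code!r} in column {col} matches "
                                f"nothing in the {classification} map; dropped")
                expanded |= hits
            if expanded:
                d.code_sets[classification] = expanded
        if sr_column and sr_column in df.columns and row[sr_column].strip():
            d.field_specs = [parse_field_spec(t)
                             for t in _split_outside_parens(row[sr_column])]
        if ts_column and ts_column in df.columns and row[ts_column].strip():
            d.conditions = [parse_condition(t)
                            for t in _split_outside_parens(row[ts_column])]
        if "Study_population" in df.columns:
            refs = _parse_trait_list(row["Study_population"])
            if len(refs) > 1:
                raise ParseError(f"{trait}: Study_population must name a single trait")
            d.study_population = refs[0] if refs else None
        if "Include_definitions" in df.columns:
            d.include_definitions = _parse_trait_list(row["Include_definitions"])
        if "Exclude_from_cases" in df.columns:
            d.exclude_from_cases = _parse_trait_list(row["Exclude_from_cases"])
        if "Exclude_from_controls" in df.columns:
            d.exclude_from_controls = _parse_trait_list(row["Exclude_from_controls"])
        definitions.append(d)

    defset = DefinitionSet(definitions, report)
    for d in defset:
        for ref in d.references():
            if ref not in defset:
                raise ParseError(f"{d.trait}: composite reference to unknown "
                                 f"trait {ref!r}")
    return defset


def write_definition_table(defset: DefinitionSet, path: str | Path,
                           settings: DataSettings) -> Path:
    """Serialize to the normalized table format (round-trips through
    :func:`read_definition_table`)."""
    path = Path(path)
    code_columns = settings.classification_columns()
    column_order = list(code_columns.values())
    sr_column = next((s.definition_column for s in settings.self_report_sources()), None)
    ts_column = next((s.definition_column for s in settings
                      if s.classification == "ts"), None)
    columns = (["TRAIT", "DESCRIPTION"] + column_order
               + [c for c in (sr_column, ts_column) if c]
               + list(COMPOSITE_COLUMNS))
    rows = []
    for d in defset:
        row = dict.fromkeys(columns, "")
        row["TRAIT"] = d.trait
        row["DESCRIPTION"] = d.description
        for col, patterns in d.raw_patterns.items():
            row[col] = ", ".join(p.raw for p in patterns)
        if sr_column:
            row[sr_column] = ", ".join(f.serialize() for f in d.field_specs)
        if ts_column:
            row[ts_column] = ", ".join(c.serialize() for c in d.conditions)
        row["Study_population"] = d.study_population or ""
        row["Include_definitions"] = ", ".join(d.include_definitions)
        row["Exclude_from_cases"] = ", ".join(d.exclude_from_cases)
        row["Exclude_from_controls"] = ", ".join(d.exclude_from_controls)
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
    return path


def plan_composite(defset: DefinitionSet, trait: str) -> list[str]:
    """Dependency-ordered evaluation plan: every referenced trait precedes
    the target.  Raises on cycles, naming the cycle."""
    if trait not in defset:
        raise KeyError(f"trait not defined: {trait!r}")
    order: list[str] = []
    state: dict[str, int] = {}  # 1 = on stack, 2 = done

    def visit(t: str, stack: list[str]) -> None:
        if state.get(t) == 2:
            return
        if state.get(t) == 1:
            cycle = stack[stack.index(t):] + [t]
            raise ParseError(f"cyclic composite reference: {' -> '.join(cycle)}")
        state[t] = 1
        for ref in defset[t].references():
            visit(ref, stack + [t])
        state[t] = 2
        order.append(t)

    visit(trait, [])
    return order
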