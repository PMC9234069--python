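"""Synthetic cohort generation in every supported input format.

Generates a main dataset + metadata, hospital episode trio, primary-care
events and prescriptions, death register, withdrawal list and a ground-truth
table, all as plain TSV/text, so the full pipeline is testable without
restricted data.  Codes are drawn from small bundled toy code maps with a
parent + children structure per system, so parent-code expansion is
exercised end to end.  Same seed ⇒ byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .settings import default_settings, write_data_settings

logger = logging.getLogger(__name__)

__all__ = ["TraitGen", "SynthConfig", "generate_cohort", "write_toy_code_maps",
           "write_default_definitions", "default_trait_gens", "TOY_CODE_MAPS"]

TOY_CODE_MAPS: dict[str, dict[str, str]] = {
    "icd10": {
        "E11": "Type 2 diabetes mellitus", "E110": "T2DM with coma",
        "E119": "T2DM without complications",
        "E10": "Type 1 diabetes mellitus", "E101": "T1DM with ketoacidosis",
        "E109": "T1DM without complications",
        "I48": "Atrial fibrillation and flutter", "I480": "Paroxysmal AF",
        "I481": "Persistent AF",
        "I50": "Heart failure", "I500": "Congestive heart failure",
        "I10": "Essential hypertension",
        "J45": "Asthma", "K21": "Gastro-oesophageal reflux",
    },
    "icd9": {
        "25000": "Diabetes mellitus type II", "25010": "Diabetes with ketoacidosis",
        "4273": "Atrial fibrillation", "428": "Heart failure",
        "4010": "Malignant hypertension",
    },
    "opcs4": {
        "K40": "Saphenous vein graft replacement", "K401": "CABG single",
        "K402": "CABG double", "K45": "Connection of mammary artery",
    },
    "read2": {
        "C10F.": "Type 2 diabetes mellitus", "C10F1": "T2DM with renal comp.",
        "C10FJ": "Insulin treated T2DM",
        "C10E.": "Type 1 diabetes mellitus", "C10E1": "T1DM with renal comp.",
        "G573.": "Atrial fibrillation and flutter", "G5730": "Atrial fibrillation",
        "G573z": "AF and flutter NOS",
        "G58..": "Heart failure", "G5800": "Acute congestive heart failure",
        "H33..": "Asthma", "H330.": "Extrinsic asthma",
    },
    "read3": {
        "X40J5": "Type 2 diabetes mellitus", "XaELQ": "T2DM on diet only",
        "X202R": "Paroxysmal atrial fibrillation", "XE2uV": "Heart failure",
        "H33..": "Asthma",
    },
    "dmd": {
        "met00001": "metformin 500mg tablets", "ins00002": "insulin glargine",
        "oad00003": "gliclazide 80mg tablets", "sta00004": "simvastatin 40mg",
    },
}

_NOISE_GP = ["H330.", "H33.."]
_NOISE_ICD10 = ["J45", "K21"]

_CENTRES = ["11001", "11008", "11012", "11004", "11005", "11003", "11022"]


@dataclass(frozen=True)
class TraitGen:
    """Generative spec for one trait: definition cells + leaf codes emitted."""

    trait: str
    prevalence: float
    incidence: float = 0.0  # annual post-baseline hazard (approximate)
    definition: dict[str, str] = field(default_factory=dict)
    gen_codes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    sr_field: int | None = None
    sr_codes: tuple[str, ...] = ()
    ts_field: int | None = None
    ts_value: str | None = None

    def available_sources(self, prevalent: bool) -> list[str]:
        kinds = list(self.gen_codes)
        if self.sr_field is not None:
            kinds.append("sr")
        if self.ts_field is not None:
            kinds.append("ts")
        if prevalent:
            kinds = [k for k in kinds if k != "death"]
        else:  # incident: baseline self-report cannot carry future disease
            kinds = [k for k in kinds if k not in ("sr", "ts")]
        return kinds


def default_trait_gens() -> list[TraitGen]:
    return [
        TraitGen("DmT2", prevalence=0.05, incidence=0.005,
                 definition={"ICD10": "E11", "ICD9": "25000", "READ2": "C10F.",
                             "CTV3": "X40J5, XaELQ", "SR": "20002(1223)"},
                 gen_codes={"hesin_icd10": ("E110", "E119"),
                            "hesin_icd9": ("25000",),
                            "gp_read2": ("C10F1", "C10FJ"),
                            "gp_read3": ("X40J5", "XaELQ")},
                 sr_field=20002, sr_codes=("1223",)),
        TraitGen("DmT1", prevalence=0.01,
                 definition={"ICD10": "E10", "READ2": "C10E.",
                             "SR": "20002(1222)"},
                 gen_codes={"hesin_icd10": ("E101", "E109"),
                            "gp_read2": ("C10E1",)},
                 sr_field=20002, sr_codes=("1222",)),
        TraitGen("RxDm", prevalence=0.06,
                 definition={"Rx": "met00001, ins00002, oad00003", "SR": "20003"},
                 gen_codes={"gp_scripts": ("met00001", "ins00002", "oad00003")},
                 sr_field=20003, sr_codes=("1140884600", "1140874718")),
        TraitGen("Af", prevalence=0.03, incidence=0.004,
                 definition={"ICD10": "I48", "ICD9": "4273", "READ2": "G573.",
                             "CTV3": "X202R", "SR": "20002(1471, 1483)"},
                 gen_codes={"hesin_icd10": ("I480", "I481"),
                            "hesin_icd9": ("4273",),
                            "gp_read2": ("G5730", "G573z"),
                            "gp_read3": ("X202R",)},
                 sr_field=20002, sr_codes=("1471",)),
        TraitGen("Hf", prevalence=0.02, incidence=0.008,
                 definition={"ICD10": "I50", "CTV3": "XE2uV",
                             "SR": "20002(1076)"},
                 gen_codes={"hesin_icd10": ("I500",),
                            "gp_read3": ("XE2uV",),
                            "death": ("I500",)},
                 sr_field=20002, sr_codes=("1076",)),
        TraitGen("Ht", prevalence=0.10,
                 definition={"ICD10": "I10", "ICD9": "4010",
                             "TS": "6177=2(bp medication)"},
                 gen_codes={"hesin_icd10": ("I10",), "hesin_icd9": ("4010",)},
                 ts_field=6177, ts_value="2"),
        TraitGen("Cabg", prevalence=0.02,
                 definition={"OPCS4": "K40", "SR": "20004(1095)"},
                 gen_codes={"hesin_oper4": ("K401", "K402")},
                 sr_field=20004, sr_codes=("1095",)),
        TraitGen("DmRxT2", prevalence=0.0,
                 definition={"Include_definitions": "DmT2",
                             "Exclude_from_cases": "DmT1",
                             "Exclude_from_controls": "RxDm"}),
    ]


@dataclass
class SynthConfig:
    n: int = 200
    seed: int = 0
    visit_start: str = "2006-01-01"
    visit_end: str = "2010-12-31"
    birth_year_range: tuple[int, int] = (1940, 1970)
    cohort_start: str = "1995-01-01"
    censor_end: str = "2018-01-01"
    traits: list[TraitGen] = field(default_factory=default_trait_gens)
    source_prob: float = 0.6
    date_missing_prob: float = 0.1
    noise_rate: float = 0.3
    withdrawal_fraction: float = 0.02
    centres: tuple[str, ...] = tuple(_CENTRES)
    #: (case_trait, exclusion_trait, k): give k existing cases of case_trait
    #: evidence of exclusion_trait, dated before baseline
    inject_exclusion: tuple[str, str, int] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for p in (self.source_prob, self.date_missing_prob, self.noise_rate,
                  self.withdrawal_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        if "inject_exclusion" in known and known["inject_exclusion"] is not None:
            known["inject_exclusion"] = tuple(known["inject_exclusion"])
        return cls(**known)

    def set_prevalence(self, trait: str, prevalence: float,
                       incidence: float | None = None) -> "SynthConfig":
        traits = [replace(t, prevalence=prevalence,
                          incidence=t.incidence if incidence is None else incidence)
                  if t.trait == trait else t for t in self.traits]
        return replace(self, traits=traits)


def write_toy_code_maps(out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for system, codes in TOY_CODE_MAPS.items():
        path = out_dir / f"{system}.tsv"
        lines = [f"{code}\t{desc}" for code, desc in sorted(codes.items())]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written[system] = path
    return written


def write_default_definitions(path: str | Path,
                              traits: list[TraitGen] | None = None) -> Path:
    """Write the definition table matching :func:`default_trait_gens`."""
    traits = traits or default_trait_gens()
    columns = ["TRAIT", "DESCRIPTION", "ICD10", "ICD9", "OPCS4", "READ2",
               "CTV3", "Rx", "SR", "TS", "Study_population",
               "Include_definitions", "Exclude_from_cases",
               "Exclude_from_controls"]
    rows = []
    for tg in traits:
        row = dict.fromkeys(columns, "")
        row["TRAIT"] = tg.trait
        row.update(tg.definition)
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
    return path


_FIELD_TYPES = {31: "Integer", 34: "Integer", 52: "Integer", 53: "Date",
                54: "Categorical (single)", 6177: "Categorical (single)",
                20001: "Categorical (multiple)", 20002: "Categorical (multiple)",
                20003: "Categorical (multiple)", 20004: "Categorical (multiple)",
                20006: "Continuous", 20008: "Continuous", 20010: "Continuous"}


def _write_metadata(columns: list[str], out_dir: Path) -> tuple[Path, Path]:
    rows = [("f.eid", 0, "Sequence")]
    for col in columns:
        if col == "f.eid":
            continue
        fid = int(col.split(".")[1])
        rows.append((col, fid, _FIELD_TYPES.get(fid, "Text")))
    tsv = out_dir / "metadata.tsv"
    pd.DataFrame(rows, columns=["column_label", "field_id", "type"]).to_csv(
        tsv, sep="\t", index=False)
    html_rows = "\n".join(
        f"<tr><td>{label}</td><td>{vtype}</td><td>field {fid}</td></tr>"
        for label, fid, vtype in rows)
    html = out_dir / "metadata.html"
    html.write_text(
        "<html><body>\n<table>\n"
        "<tr><th>Column</th><th>Type</th><th>Description</th></tr>\n"
        f"{html_rows}\n</table>\n</body></html>\n", encoding="utf-8")
    return tsv, html


def _uniform_date(rng: np.random.Generator, start: pd.Timestamp,
                  end: pd.Timestamp) -> pd.Timestamp:
    span = (end - start).days
    return start + timedelta(days=int(rng.integers(0, max(span, 0) + 1)))


class _Records:
    """Accumulators for every record-level output table."""

    def __init__(self) -> None:
        self.hesin: list[dict] = []
        self.hesin_diag: list[dict] = []
        self.hesin_oper: list[dict] = []
        self.gp_clinical: list[dict] = []
        self.gp_scripts: list[dict] = []
        self.death_date: dict[int, pd.Timestamp] = {}
        self.death_causes: list[dict] = []
        self.ins_index: dict[int, int] = {}

    def next_ins(self, pid: int) -> int:
        idx = self.ins_index.get(pid, 0)
        self.ins_index[pid] = idx + 1
        return idx

    def add_hesin(self, rng, pid: int, code: str, system: str,
                  date: pd.Timestamp, missing_start: bool = False) -> None:
        idx = self.next_ins(pid)
        dur = int(rng.integers(0, 15))
        end = date + timedelta(days=dur)
        self.hesin.append({
            "eid": pid, "ins_index": idx,
            "epistart": "" if missing_start else date.strftime("%Y-%m-%d"),
            "epiend": "" if missing_start else end.strftime("%Y-%m-%d"),
            "admidate": date.strftime("%Y-%m-%d"),
            "disdate": end.strftime("%Y-%m-%d"),
        })
        if system == "hesin_oper4":
            self.hesin_oper.append({"eid": pid, "ins_index": idx, "level": "1",
                                    "oper4": code})
        else:
            self.hesin_diag.append({
                "eid": pid, "ins_index": idx, "level": "1",
                "diag_icd10": code if system == "hesin_icd10" else "",
                "diag_icd9": code if system == "hesin_icd9" else ""})

    def add_gp(self, rng, pid: int, code: str, column: str,
               date: pd.Timestamp) -> None:
        self.gp_clinical.append({
            "eid": pid, "data_provider": str(int(rng.integers(1, 5))),
            "event_dt": date.strftime("%Y-%m-%d"),
            "read_2": code if column == "read_2" else "",
            "read_3": code if column == "read_3" else ""})

    def add_script(self, rng, pid: int, code: str, date: pd.Timestamp) -> None:
        self.gp_scripts.append({
            "eid": pid, "data_provider": str(int(rng.integers(1, 5))),
            "issue_date": date.strftime("%Y-%m-%d"), "drug_code": code})

    def add_death(self, pid: int, code: str, date: pd.Timestamp) -> None:
        if pid in self.death_date:
            level = "2"
            date = self.death_date[pid]
        else:
            level = "1"
            self.death_date[pid] = date
        self.death_causes.append({
            "eid": pid, "ins_index": 0,
            "arr_index": sum(1 for c in self.death_causes if c["eid"] == pid),
            "level": level, "cause_icd10": code})


def generate_cohort(config: SynthConfig,
                    out_dir: str | Path) -> tuple[dict[str, Path], pd.DataFrame]:
    """Generate the full synthetic input set plus a ground-truth table.

    Returns a manifest (logical name → path) and the truth table, which is
    also written to ``truth.tsv``.  The withdrawal-list length is
    ``round(n × withdrawal_fraction)``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    rng = np.random.default_rng(config.seed)

    visit_start = pd.Timestamp(config.visit_start)
    visit_end = pd.Timestamp(config.visit_end)
    cohort_start = pd.Timestamp(config.cohort_start)
    censor_end = pd.Timestamp(config.censor_end)

    ids = (1000001 + np.arange(config.n)).tolist()
    sex = rng.integers(0, 2, size=config.n)
    birth_year = rng.integers(config.birth_year_range[0],
                              config.birth_year_range[1] + 1, size=config.n)
    birth_month = rng.integers(1, 13, size=config.n)
    visits = [_uniform_date(rng, visit_start, visit_end) for _ in range(config.n)]
    centres = rng.choice(np.asarray(config.centres), size=config.n)

    sr_fields = sorted({tg.sr_field for tg in config.traits
                        if tg.sr_field is not None})
    ts_fields = sorted({tg.ts_field for tg in config.traits
                        if tg.ts_field is not None})
    settings = default_settings()
    sr_timing = {s.field_id: s.timing_field
                 for s in settings.self_report_sources()}
    n_arrays = 3
    sr_cells: dict[int, dict[int, list[tuple[str, str]]]] = \
        {f: {} for f in sr_fields}  # field -> pid -> [(code, year)]
    ts_values: dict[int, dict[int, str]] = {f: {} for f in ts_fields}

    records = _Records()
    truth_rows: dict[tuple[int, str], dict] = {}

    def add_sr(pid: int, fld: int, code: str, year: str) -> None:
        cells = sr_cells[fld].setdefault(pid, [])
        if len(cells) < n_arrays:
            cells.append((code, year))

    def emit(tg: TraitGen, pid: int, visit: pd.Timestamp, kind: str,
             onset: pd.Timestamp, prevalent: bool) -> None:
        if kind == "sr":
            missing = rng.random() < config.date_missing_prob
            add_sr(pid, tg.sr_field,
                   str(rng.choice(np.asarray(tg.sr_codes))),
                   "" if missing else str(onset.year))
        elif kind == "ts":
            ts_values[tg.ts_field][pid] = tg.ts_value
        elif kind in ("hesin_icd10", "hesin_icd9", "hesin_oper4"):
            code = str(rng.choice(np.asarray(tg.gen_codes[kind])))
            missing_start = rng.random() < config.date_missing_prob
            records.add_hesin(rng, pid, code, kind, onset, missing_start)
        elif kind == "gp_read2":
            records.add_gp(rng, pid, str(rng.choice(np.asarray(tg.gen_codes[kind]))),
                           "read_2", onset)
        elif kind == "gp_read3":
            records.add_gp(rng, pid, str(rng.choice(np.asarray(tg.gen_codes[kind]))),
                           "read_3", onset)
        elif kind == "gp_scripts":
            records.add_script(rng, pid,
                               str(rng.choice(np.asarray(tg.gen_codes[kind]))), onset)
        elif kind == "death":
            records.add_death(pid, str(rng.choice(np.asarray(tg.gen_codes[kind]))),
                              max(onset, visit + timedelta(days=30)))

    for i, pid in enumerate(ids):
        visit = visits[i]
        for tg in config.traits:
            prevalent = rng.random() < tg.prevalence
            incident = False
            if not prevalent and tg.incidence > 0:
                years = (censor_end - visit).days / 365.25
                incident = rng.random() < min(1.0, tg.incidence * years)
            if not (prevalent or incident):
                continue
            if prevalent:
                onset = _uniform_date(rng, cohort_start, visit)
            else:
                onset = _uniform_date(rng, visit + timedelta(days=1), censor_end)
            avail = tg.available_sources(prevalent)
            if not avail:
                continue
            chosen = [k for k in avail if rng.random() < config.source_prob]
            if not chosen:
                chosen = [avail[int(rng.integers(len(avail)))]]
            for kind in chosen:
                emit(tg, pid, visit, kind, onset, prevalent)
            truth_rows[(pid, tg.trait)] = {
                "identifier": pid, "trait": tg.trait,
                "status": "prevalent" if prevalent else "incident",
                "onset_date": onset.strftime("%Y-%m-%d"),
                "sources": ";".join(sorted(chosen))}
        if rng.random() < config.noise_rate:
            if rng.random() < 0.5:
                records.add_gp(rng, pid, str(rng.choice(np.asarray(_NOISE_GP))),
                               "read_2", _uniform_date(rng, cohort_start, censor_end))
            else:
                records.add_hesin(rng, pid,
                                  str(rng.choice(np.asarray(_NOISE_ICD10))),
                                  "hesin_icd10",
                                  _uniform_date(rng, cohort_start, censor_end))

    if config.inject_exclusion is not None:
        case_trait, excl_trait, k = config.inject_exclusion
        excl_gen = next(t for t in config.traits if t.trait == excl_trait)
        case_ids = sorted(pid for (pid, t) in truth_rows if t == case_trait)
        if len(case_ids) < k:
            raise ValueError(
                f"cannot inject exclusion evidence for {k} participants: only "
                f"{len(case_ids)} {case_trait} cases generated")
        injected = case_ids[:k]
        code = excl_gen.gen_codes.get("hesin_icd10", excl_gen.sr_codes)[0]
        for pid in injected:
            visit = visits[ids.index(pid)]
            records.add_hesin(rng, pid, code, "hesin_icd10",
                              visit - timedelta(days=30))
            truth_rows[(pid, excl_trait)] = {
                "identifier": pid, "trait": excl_trait, "status": "prevalent",
                "onset_date": (visit - timedelta(days=30)).strftime("%Y-%m-%d"),
                "sources": "injected"}

    n_withdraw = int(round(config.n * config.withdrawal_fraction))
    withdrawn = sorted(rng.choice(np.asarray(ids), size=n_withdraw,
                                  replace=False).tolist()) if n_withdraw else []

    # ---- main dataset ----------------------------------------------------
    main = {"f.eid": ids,
            "f.31.0.0": sex.tolist(),
            "f.34.0.0": birth_year.tolist(),
            "f.52.0.0": birth_month.tolist(),
            "f.53.0.0": [v.strftime("%Y-%m-%d") for v in visits],
            "f.54.0.0": [str(c) for c in centres]}
    for fld in ts_fields:
        fills = ts_values[fld]
        base = [str(v) for v in rng.choice(np.asarray(["1", "3", "-3"]),
                                           size=config.n)]
        main[f"f.{fld}.0.0"] = [fills.get(pid, base[j])
                                for j, pid in enumerate(ids)]
    for fld in sr_fields:
        timing = sr_timing.get(fld)
        for arr in range(n_arrays):
            codes, years = [], []
            for pid in ids:
                cells = sr_cells[fld].get(pid, [])
                code, year = cells[arr] if arr < len(cells) else ("", "")
                codes.append(code)
                years.append(year)
            main[f"f.{fld}.0.{arr}"] = codes
            if timing is not None:
                main[f"f.{timing}.0.{arr}"] = years

    main_df = pd.DataFrame(main)
    main_path = out_dir / "main.tab"
    main_df.to_csv(main_path, sep="\t", index=False)
    meta_tsv, meta_html = _write_metadata(list(main_df.columns), out_dir)

    # ---- record-level tables ---------------------------------------------
    def write_records(name: str, rows: list[dict], columns: list[str]) -> Path:
        path = out_dir / f"{name}.txt"
        pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
        return path

    manifest = {
        "main": main_path, "metadata": meta_tsv, "metadata_html": meta_html,
        "hesin": write_records("hesin", records.hesin,
                               ["eid", "ins_index", "epistart", "epiend",
                                "admidate", "disdate"]),
        "hesin_diag": write_records("hesin_diag", records.hesin_diag,
                                    ["eid", "ins_index", "level", "diag_icd10",
                                     "diag_icd9"]),
        "hesin_oper": write_records("hesin_oper", records.hesin_oper,
                                    ["eid", "ins_index", "level", "oper4"]),
        "gp_clinical": write_records("gp_clinical", records.gp_clinical,
                                     ["eid", "data_provider", "event_dt",
                                      "read_2", "read_3"]),
        "gp_scripts": write_records("gp_scripts", records.gp_scripts,
                                    ["eid", "data_provider", "issue_date",
                                     "drug_code"]),
        "death": write_records(
            "death",
            [{"eid": pid, "ins_index": 0, "date_of_death": d.strftime("%Y-%m-%d")}
             for pid, d in sorted(records.death_date.items())],
            ["eid", "ins_index", "date_of_death"]),
        "death_cause": write_records("death_cause", records.death_causes,
                                     ["eid", "ins_index", "arr_index", "level",
                                      "cause_icd10"]),
    }

    withdrawal_path = out_dir / "withdrawals.txt"
    withdrawal_path.write_text(
        "".join(f"{pid}\n" for pid in withdrawn), encoding="utf-8")
    manifest["withdrawals"] = withdrawal_path

    manifest.update({f"codemap_{k}": v
                     for k, v in write_toy_code_maps(out_dir / "codemaps").items()})
    manifest["codemap_dir"] = out_dir / "codemaps"
    manifest["definitions"] = write_default_definitions(
        out_dir / "definitions.tsv", config.traits)
    manifest["data_settings"] = write_data_settings(
        settings, out_dir / "data_settings.tsv")

    withdrawn_set = set(withdrawn)
    truth = pd.DataFrame(
        [dict(row, withdrawn=int(row["identifier"] in withdrawn_set))
         for row in truth_rows.values()],
        columns=["identifier", "trait", "status", "onset_date", "sources",
                 "withdrawn"])
    truth = truth.sort_values(["trait", "identifier"]).reset_index(drop=True)
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    manifest["truth"] = truth_path
    return manifest, truth
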