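"""Thin rendering layer: figures and reports from ascertainment tables.

All acceptance-relevant numbers live in the tables produced by the
ascertainment operations; figures here are best-effort conveniences and
rendering never mutates its inputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

logger = logging.getLogger(__name__)

__all__ = ["render_reports"]

KNOWN_FORMATS = {"png", "tsv"}


def _plot_frequency(table: pd.DataFrame, path: Path) -> None:
    top = table.head(30)
    fig, ax = plt.subplots(figsize=(8, max(2, 0.3 * len(top))))
    labels = top["classification"] + ":" + top["code"]
    ax.barh(labels[::-1], top["event_count"][::-1])
    ax.set_xlabel("event count")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _plot_timeline(table: pd.DataFrame, path: Path) -> None:
    wide = table.pivot_table(index="year", columns=".id", values="count",
                             fill_value=0)
    fig, ax = plt.subplots(figsize=(8, 4))
    bottom = None
    for col in wide.columns:
        ax.bar(wide.index, wide[col], bottom=bottom, label=col)
        bottom = wide[col] if bottom is None else bottom + wide[col]
    ax.set_xlabel("year")
    ax.set_ylabel("events")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _plot_overlap(table: pd.DataFrame, path: Path) -> None:
    # upset-style bar chart of source-combination counts
    combos = table.apply(lambda r: "+".join(c for c in table.columns if r[c]),
                         axis=1).value_counts()
    fig, ax = plt.subplots(figsize=(8, max(2, 0.3 * len(combos))))
    ax.barh(combos.index[::-1], combos.values[::-1])
    ax.set_xlabel("participants")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _plot_individual(table: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(8, max(2, 0.3 * table[".id"].nunique())))
    sources = sorted(table[".id"].unique())
    for y, src in enumerate(sources):
        rows = table[table[".id"] == src]
        ax.plot(rows["eventdate"], [y] * len(rows), "o", label=src)
        for _, r in rows.iterrows():
            ax.annotate(r["code"], (r["eventdate"], y), fontsize=6,
                        textcoords="offset points", xytext=(0, 5))
    ax.set_yticks(range(len(sources)), sources)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


_PLOTTERS = {"frequency": _plot_frequency, "timeline": _plot_timeline,
             "overlap": _plot_overlap, "individual": _plot_individual}


def render_reports(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                   formats: tuple[str, ...] = ("tsv",),
                   dropped_codes: list | None = None) -> dict[str, Path]:
    """Render each named table in each requested format.

    Known table names: ``frequency``, ``timeline``, ``overlap``,
    ``individual``; unknown names are written as TSV only.  Empty tables are
    skipped silently, with a note in the run report.  Unknown formats are a
    fatal error.
    """
    unknown = set(formats) - KNOWN_FORMATS
    if unknown:
        raise ValueError(f"unknown output format(s): {sorted(unknown)}; "
                         f"supported: {sorted(KNOWN_FORMATS)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    notes: list[str] = []
    for name, table in tables.items():
        if table is None or not len(table):
            notes.append(f"table {name!r} is empty; skipped")
            continue
        if "tsv" in formats:
            path = out_dir / f"{name}.tsv"
            keep_index = name == "overlap"  # identifier lives in the index
            table.to_csv(path, sep="\t", index=keep_index)
            manifest[f"{name}.tsv"] = path
        if "png" in formats and name in _PLOTTERS:
            path = out_dir / f"{name}.png"
            _PLOTTERS[name](table, path)
            manifest[f"{name}.png"] = path
    report_lines = list(notes)
    for item in dropped_codes or []:
        trait, column, code = item
        report_lines.append(f"dropped code: trait={trait} column={column} "
                            f"code={code}")
    report_path = out_dir / "report.txt"
    report_path.write_text("\n".join(report_lines) + ("\n" if report_lines else ""),
                           encoding="utf-8")
    manifest["report.txt"] = report_path
    return manifest
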