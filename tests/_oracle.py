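"""Independent brute-force oracles used to cross-check the library.

These deliberately avoid the library's vectorized matching/ascertainment
code paths: matching is a per-row Python loop, composite semantics are plain
set algebra.
"""

from __future__ import annotations


def _strip_dots(code: str) -> str:
    return code.strip().rstrip(".")


def oracle_expand(patterns, codes, hierarchical, ignore_case=False):
    """Per-code × per-pattern prefix scan."""
    out = set()
    for code in codes:
        ncode = _strip_dots(code)
        if ignore_case:
            ncode = ncode.lower()
        for pat in patterns:
            npat = _strip_dots(pat)
            if ignore_case:
                npat = npat.lower()
            if not npat:
                continue
            if ncode == npat or (hierarchical and ncode.startswith(npat)):
                out.add(code)
                break
    return out


def _row_matches(source, src_settings, code, definition):
    if source.startswith("sr_"):
        field = int(source.split("_")[1])
        for spec in definition.field_specs:
            if spec.field_id != field:
                continue
            if spec.codes is None:
                try:
                    if float(code) < 0:
                        continue
                except (TypeError, ValueError):
                    pass
                return True
            if code in spec.codes:
                return True
        return False
    if src_settings.classification == "ts":
        return code in {c.canonical for c in definition.conditions}
    codeset = definition.code_sets.get(src_settings.classification)
    if not codeset:
        return False
    norm = _strip_dots(code)
    wanted = {_strip_dots(c) for c in codeset}
    if src_settings.ignore_case:
        norm = norm.lower()
        wanted = {c.lower() for c in wanted}
    return norm in wanted


def oracle_match_set(definition, harmonized, settings):
    """Participants with >= min_instances matching episodes in any source."""
    members = set()
    for source, df in harmonized.episodes.items():
        if source not in settings:
            continue
        src = settings[source]
        counts: dict[int, int] = {}
        for _, row in df.iterrows():
            if _row_matches(source, src, row["code"], definition):
                counts[row["identifier"]] = counts.get(row["identifier"], 0) + 1
        members |= {pid for pid, n in counts.items() if n >= src.min_instances}
    return members


def oracle_statuses(defset, trait, harmonized, settings, population):
    """identifier -> status via pure set unions/differences."""
    match_cache: dict[str, set] = {}

    def members(t: str) -> set:
        if t not in match_cache:
            own = oracle_match_set(defset[t], harmonized, settings)
            for inc in defset[t].include_definitions:
                own = own | members(inc)
            match_cache[t] = own
        return match_cache[t]

    target = defset[trait]
    pop = set(population)
    if target.study_population:
        pop = pop & members(target.study_population)
    cases = pop & members(trait)
    excluded_cases = set()
    for ex in target.exclude_from_cases:
        excluded_cases |= cases & members(ex)
    controls = pop - cases
    excluded_controls = set()
    for ex in target.exclude_from_controls:
        excluded_controls |= controls & members(ex)
    statuses = {}
    for pid in pop:
        if pid in cases:
            statuses[pid] = -2 if pid in excluded_cases else 2
        else:
            statuses[pid] = -1 if pid in excluded_controls else 1
    return statuses
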