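"""Shared fixtures: a small synthetic cohort generated once per session."""

from __future__ import annotations

import pytest

from cohortpheno.definitions import read_definition_table
from cohortpheno.harmonize import harmonize_all
from cohortpheno.settings import default_settings
from cohortpheno.synth import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def settings():
    return default_settings()


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """(manifest, truth, config) for a 200-participant cohort, seed 42."""
    out = tmp_path_factory.mktemp("cohort")
    config = SynthConfig(n=200, seed=42)
    manifest, truth = generate_cohort(config, out)
    return manifest, truth, config


@pytest.fixture(scope="session")
def defset(cohort, settings):
    manifest, _, _ = cohort
    return read_definition_table(manifest["definitions"], settings,
                                 manifest["codemap_dir"])


@pytest.fixture(scope="session")
def harmonized(cohort, defset, settings):
    manifest, _, _ = cohort
    return harmonize_all(
        manifest["main"], manifest["metadata"], defset, settings,
        hesin=manifest["hesin"], hesin_diag=manifest["hesin_diag"],
        hesin_oper=manifest["hesin_oper"], gp_clinical=manifest["gp_clinical"],
        gp_scripts=manifest["gp_scripts"], death=manifest["death"],
        death_cause=manifest["death_cause"],
        withdrawals=manifest["withdrawals"])


@pytest.fixture(scope="session")
def reference_dates(harmonized):
    return harmonized.participants[["identifier", "f.53.0.0"]]
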