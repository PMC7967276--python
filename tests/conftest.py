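"""Shared fixtures: one noise-free simulated study and one full pipeline run.

Both are session-scoped: the simulated study is the deterministic desk-scale
design (all orientation classes, planted TSS shifts, four REP loci) and is
reused by every module that needs realistic tracks or alignments.
"""

from __future__ import annotations

import pytest

from divtss.pipeline import PipelineConfig, run_pipeline
from divtss.simulate import default_config, simulate, write_fixture

FIXTURE_SEED = 101


@pytest.fixture(scope="session")
def noise_free_config():
    return default_config(mismatch_read_fraction=0.0)


@pytest.fixture(scope="session")
def noise_free_fixture(noise_free_config):
    """In-memory simulated study without read errors (clean recovery tests)."""
    return simulate(noise_free_config, FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_on_disk(noise_free_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    return write_fixture(noise_free_config, FIXTURE_SEED, outdir)


@pytest.fixture(scope="session")
def pipeline_result(fixture_on_disk, tmp_path_factory):
    fx = fixture_on_disk
    config = PipelineConfig(
        genome=fx.paths["genome"],
        annotation=fx.paths["annotation"],
        conditions=fx.paths["sam"],
        outdir=tmp_path_factory.mktemp("run"),
        predicted_tss=fx.paths["predicted_tss"],
    )
    return run_pipeline(config)
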