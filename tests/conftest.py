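"""Shared fixtures: synthetic datasets and full pipeline runs.

The heavy end-to-end objects are session-scoped so the recovery-style
tests share one simulation + one pipeline execution.
"""

from __future__ import annotations

import pytest

from srdk.config import PipelineConfig
from srdk.pipeline import run_pipeline
from srdk.simulate import simulate_dataset

SEED = 1


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def dataset():
    """Default-condition synthetic dataset (fixed seed)."""
    return simulate_dataset(seed=SEED)


@pytest.fixture(scope="session")
def result(dataset):
    """Full pipeline run on the default synthetic dataset."""
    return run_pipeline(
        dataset.srna_libs,
        dataset.degradome_libs,
        dataset.genome,
        dataset.transcripts,
        dataset.mirna_ref,
        dataset.ncrna,
        coding_status=dataset.truth.coding_status,
    )


@pytest.fixture(scope="session")
def background_dataset():
    """Background-only dataset: no planted hairpins, targets or cascade."""
    return simulate_dataset(seed=SEED, n_hairpins=0, n_ssr_hairpins=0, srna_depth=20_000)


@pytest.fixture(scope="session")
def background_result(background_dataset):
    ds = background_dataset
    return run_pipeline(
        ds.srna_libs, ds.degradome_libs, ds.genome, ds.transcripts,
        ds.mirna_ref, ds.ncrna, coding_status=ds.truth.coding_status,
    )
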