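import pytest

from famdyn import pipeline as pl
from famdyn import synthetic as syn


@pytest.fixture(scope="session")
def default_params():
    """Noise-free study conditions at the default scale (~500 families,
    7 lineages, 24 datasets)."""
    return syn.SimulationParams(seed=11)


@pytest.fixture(scope="session")
def study_bundle(default_params):
    return syn.simulate_study(default_params)


@pytest.fixture(scope="session")
def study_result(study_bundle):
    """Full pipeline run on the default synthetic study (shared across tests
    to keep the suite fast)."""
    return pl.run_pipeline(study_bundle, pl.PipelineConfig(run_qc=False))


@pytest.fixture(scope="session")
def tiny_params():
    """A small, fast study for tests that re-run the pipeline."""
    return syn.SimulationParams(
        seed=5, n_root_families=60, gain_rate=5.0, n_contaminants=5
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_params):
    return syn.simulate_study(tiny_params)
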