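import pytest

from pxmir.pipeline import PipelineConfig, run_pipeline
from pxmir.simulate import SimulationConfig, generate_all

SESSION_SEED = 11


@pytest.fixture(scope="session")
def study():
    """One synthetic study shared by generator-level tests."""
    return generate_all(SimulationConfig(seed=SESSION_SEED))


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default-scale pipeline run shared across the suite."""
    return run_pipeline(PipelineConfig(seed=SESSION_SEED))
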