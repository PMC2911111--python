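import numpy as np
import pytest

from mirrormeth import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig(seed=1)


@pytest.fixture(scope="session")
def pipeline_result(default_config):
    """One full end-to-end run shared by all tests that only read it."""
    return run_pipeline(default_config)


@pytest.fixture(scope="session")
def genome(pipeline_result):
    return pipeline_result["genome"]


@pytest.fixture(scope="session")
def methylome(pipeline_result):
    return pipeline_result["methylome"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
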