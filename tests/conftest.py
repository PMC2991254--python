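import pytest

from imss.classify import PipelineConfig, SelectionParams, fit_pipeline
from imss.motifs import DiscoveryParams
from imss.simulate import SyntheticConfig, generate_family


@pytest.fixture(scope="session")
def family():
    """Default synthetic family: 20 proteins, 3 planted lock/key pairs, no noise."""
    return generate_family(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def pipeline_config():
    """Desk-scale pipeline settings: smaller candidate list and forest."""
    return PipelineConfig(
        discovery=DiscoveryParams(top_k=50, seed=1),
        selection=SelectionParams(n_estimators=100),
        seed=1,
    )


@pytest.fixture(scope="session")
def trained(family, pipeline_config):
    records, data, truth = family
    return fit_pipeline(data, records, pipeline_config)
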