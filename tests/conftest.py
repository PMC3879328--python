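import pytest

from snvgraph.simulate import SimConfig, illumina_ga_lane2_model, simulate_dataset


@pytest.fixture(scope="session")
def ga_model():
    """The Illumina GA outer-lane generating profile."""
    return illumina_ga_lane2_model()


@pytest.fixture(scope="session")
def small_dataset(ga_model):
    """A quick simulated dataset shared by unit tests (seconds, not minutes)."""
    cfg = SimConfig(n_parents=150, abundance_range=(50, 20_000), seed=7)
    return simulate_dataset(cfg)
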