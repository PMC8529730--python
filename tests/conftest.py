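import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def benchmark_features():
    """One featurized synthetic benchmark, shared across tests (seed 7)."""
    from picme.pipeline import simulated_feature_table
    from picme.simulate import SimParams

    return simulated_feature_table(SimParams(n_pairs=600, seed=7))
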