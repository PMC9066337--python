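import pytest
from hypothesis import HealthCheck, settings

import pmslt

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic parameter bundle (seed 1)."""
    return pmslt.generate_bundle(1)


@pytest.fixture(scope="session")
def model(bundle):
    """Compiled model with the BAU arm precomputed."""
    return pmslt.Model(bundle)


@pytest.fixture(scope="session")
def base_result(model):
    """Expected-value base-case run."""
    return model.run(pmslt.InterventionSpec())
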