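import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fvesca():
    from srnase.datasets import load_fvesca_features

    return load_fvesca_features()


@pytest.fixture(scope="session")
def fviridis():
    from srnase.datasets import load_fviridis_features

    return load_fviridis_features()


@pytest.fixture(scope="session")
def candidate_identities():
    from srnase.datasets import load_candidate_identities

    return load_candidate_identities()


@pytest.fixture(scope="session")
def crosstribe():
    from srnase.datasets import load_crosstribe_identities

    return load_crosstribe_identities()


@pytest.fixture(scope="session")
def fig4_blocks():
    from srnase.datasets import load_fig4_blocks

    return load_fig4_blocks()
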