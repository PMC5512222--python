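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
def catalog():
    from polyvalent.catalog import load_catalog

    return load_catalog()


@pytest.fixture(scope="session")
def small_corpus():
    """A modest default-configuration corpus shared across tests."""
    from polyvalent.simulate import GeneratorConfig, generate_corpus

    return generate_corpus(GeneratorConfig(n_proteins=2000, seed=11))
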