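import pytest

from netpharm.synthgen import SynthConfig, generate_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic study, shared across tests."""
    return generate_bundle(SynthConfig(rng_seed=0))


@pytest.fixture(scope="session")
def network(bundle):
    return bundle.network


@pytest.fixture(scope="session")
def disease_field(bundle):
    from netpharm.propagate import disease_effect

    return disease_effect(bundle.network, bundle.disease_genes)
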