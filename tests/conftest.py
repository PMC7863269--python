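import pytest

from plastidscan.simulate import SimParams, simulate, toy_params, write_fixture


@pytest.fixture(scope="session")
def toy_truth():
    """Small six-taxon simulation shared across tests (study-like rates)."""
    return simulate(toy_params(seed=11))


@pytest.fixture(scope="session")
def full_truth():
    """One study-scale (~153 kb) six-taxon simulation."""
    return simulate(SimParams(seed=5))


@pytest.fixture(scope="session")
def toy_fixture_dir(tmp_path_factory, toy_truth):
    out = tmp_path_factory.mktemp("fixture")
    write_fixture(toy_truth, out)
    return out
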