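import pytest

from phytonet.fixtures import FixtureSpec, build_fixture, generate_all


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec()


@pytest.fixture(scope="session")
def default_data(default_spec):
    return build_fixture(default_spec)


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory, default_spec):
    out = tmp_path_factory.mktemp("fixture")
    return generate_all(default_spec, out)
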