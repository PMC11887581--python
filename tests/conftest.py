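import pytest
from hypothesis import HealthCheck, settings

from pcevalid import fixtures

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("snapshot")
    fixtures.build_fixture_snapshot(out)
    return out


@pytest.fixture(scope="session")
def graph_model(fixture_dir):
    return fixtures.load_fixture(fixture_dir)


@pytest.fixture(scope="session")
def graph(graph_model):
    return graph_model[0]


@pytest.fixture(scope="session")
def model(graph_model):
    return graph_model[1]
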