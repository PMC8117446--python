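import pytest

from omicspaper.fixtures import demo_spec, generate, write_fixture_dir
from omicspaper.transport import FixtureBackend


@pytest.fixture(scope="session")
def demo_bundle():
    """The demo study conditions: 2 experiments, 3 samples, all links present."""
    return generate(demo_spec())


@pytest.fixture()
def fixture_dir(demo_bundle, tmp_path):
    directory = tmp_path / "fixtures"
    write_fixture_dir(demo_bundle, directory)
    return directory


@pytest.fixture()
def backend(fixture_dir):
    return FixtureBackend(fixture_dir)
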