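import pytest

from effluxkit.fixtures import make_fixtures
from effluxkit.simulate import SimConfig


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The full study-shaped synthetic fixture, generated once per session."""
    out = tmp_path_factory.mktemp("fixture")
    make_fixtures(out, seed=0)
    return out


@pytest.fixture
def noiseless_config():
    return SimConfig(
        seed=1,
        n_experiments=4,
        constructs=(("varA", 100.0), ("varB", 0.0), ("varC", 37.5)),
        noise_cv=0.0,
        load_cv=0.0,
        renilla_cv=0.0,
    )
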