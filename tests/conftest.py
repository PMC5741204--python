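import pytest

from pathsense.chemstruct import parse_and_normalize
from pathsense.config import RunConfig
from pathsense.fixtures import build_fixture_kb, COCAINE_INCHI
from pathsense.knowledgebase import load_kb


@pytest.fixture(scope="session")
def cocaine_kb_dir(tmp_path_factory):
    return build_fixture_kb("cocaine", out_dir=tmp_path_factory.mktemp("kb") / "cocaine")


@pytest.fixture(scope="session")
def parathion_kb_dir(tmp_path_factory):
    return build_fixture_kb("parathion", out_dir=tmp_path_factory.mktemp("kb") / "parathion")


@pytest.fixture(scope="session")
def random30_kb_dir(tmp_path_factory):
    return build_fixture_kb("random", seed=1, n_compounds=30, n_reactions=8,
                            out_dir=tmp_path_factory.mktemp("kb") / "random30")


@pytest.fixture(scope="session")
def cocaine_kb(cocaine_kb_dir):
    return load_kb(cocaine_kb_dir)


@pytest.fixture(scope="session")
def parathion_kb(parathion_kb_dir):
    return load_kb(parathion_kb_dir)


@pytest.fixture(scope="session")
def random30_kb(random30_kb_dir):
    return load_kb(random30_kb_dir)


@pytest.fixture(scope="session")
def cocaine_mol():
    return parse_and_normalize(COCAINE_INCHI)


@pytest.fixture
def default_config():
    return RunConfig()
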