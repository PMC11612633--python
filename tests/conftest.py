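import pytest

from neurovar import fixtures as fx


@pytest.fixture(scope="session")
def mini_catalog():
    """The in-memory mini-catalog of curated facts."""
    return fx.build_catalog_fixture()


@pytest.fixture(scope="session")
def case_study(tmp_path_factory):
    """A full case-study-shape fixture tree (seed 7), built once per session."""
    out = tmp_path_factory.mktemp("case_study")
    return fx.make_case_study_fixture(out, seed=7)
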