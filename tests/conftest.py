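import pytest

from tdnmr import FixtureConfig, export_fixture_set


@pytest.fixture(scope="session")
def candy_fixture_dir(tmp_path_factory):
    """Noiseless ten-candy roster (2 replicates) with its manifest."""
    out = tmp_path_factory.mktemp("candy_roster")
    manifest = export_fixture_set(FixtureConfig(out_dir=out, seed=1, n_replicates=2))
    return out, manifest
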