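import pytest

from clusterkin import FixtureSpec, generate_bundle, toy3_fixture


@pytest.fixture(scope="session")
def toy3():
    """The embedded three-proteome, six-cluster worked example."""
    return toy3_fixture()


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A mid-sized generated bundle with partial-absence synapomorphies."""
    outdir = tmp_path_factory.mktemp("bundle")
    spec = FixtureSpec(n_proteomes=6, seed=7, partial_absence_per_node=1)
    return generate_bundle(spec, outdir)
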