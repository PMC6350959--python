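import pytest

from vdmap import CrossConfig, build_packaged_fixture


@pytest.fixture(scope="session")
def packaged_bundle():
    """The deterministic packaged chr14 fixture (built once per session)."""
    return build_packaged_fixture(seed=1)


@pytest.fixture(scope="session")
def bundle_paths(tmp_path_factory, packaged_bundle):
    """The fixture emitted to disk as FASTA/GFF3/VCF/TSV files."""
    outdir = tmp_path_factory.mktemp("fixture")
    return packaged_bundle.write(outdir)


@pytest.fixture()
def default_config():
    return CrossConfig(seed=1)
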