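import pytest

from virodiv.synthetic import CommunityConfig, generate_community


@pytest.fixture(scope="session")
def small_community(tmp_path_factory):
    """One seeded synthetic community emitted to disk, shared read-only."""
    outdir = tmp_path_factory.mktemp("community")
    cfg = CommunityConfig(seed=7, n_viral=6, n_viral_round2=3, n_nonviral=6)
    bundle = generate_community(cfg, outdir)
    return cfg, bundle, outdir
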