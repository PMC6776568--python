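import pytest

from regulink import RunConfig, SimConfig, run_pipeline, simulate_study


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """The default synthetic study (seed 1), shared across the session."""
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate_study(SimConfig(seed=1), outdir)


@pytest.fixture(scope="session")
def report(bundle, tmp_path_factory):
    """Full-pipeline report over the default synthetic study."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = RunConfig.from_bundle(bundle, outdir, seed=1)
    return run_pipeline(cfg)
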