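import pytest

from epitrans.pipeline import make_demo, run_pipeline
from epitrans.synthetic import generate_dataset

DEMO_SEED = 11


@pytest.fixture(scope="session")
def demo_dataset():
    """One synthetic study shared by all tests that need full data."""
    return generate_dataset(seed=DEMO_SEED)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """A complete demo pipeline run (config, manifest)."""
    outdir = tmp_path_factory.mktemp("demo")
    config = make_demo(outdir, seed=DEMO_SEED)
    manifest = run_pipeline(config)
    return config, manifest
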