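import pandas as pd
import pytest

from unexploited import SimulationConfig, make_fixture
from unexploited import io as uio
from unexploited.pipeline import config_from_manifest


@pytest.fixture(scope="session")
def default_config():
    """The standard synthetic cohort (2000 genes x 50 pairs, seed 7)."""
    return SimulationConfig()


@pytest.fixture(scope="session")
def noise_free_config():
    """Deterministic variant: every planted gene responds in every pair."""
    return SimulationConfig(noise_sd=0.0, response_prob=1.0)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, default_config):
    """A fully generated input set for the standard cohort."""
    outdir = tmp_path_factory.mktemp("fixture_default")
    manifest = make_fixture(default_config, outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, fixture_dir):
    """One full pipeline run on the standard fixture: (report, outdir, truth)."""
    from unexploited.pipeline import run_pipeline

    _, manifest = fixture_dir
    outdir = tmp_path_factory.mktemp("run_default")
    report = run_pipeline(config_from_manifest(manifest, str(outdir)))
    truth = uio.read_truth(manifest["truth"])
    return report, outdir, truth


def tiny_matrix(values, pairs):
    """Helper: build an ExpressionMatrix from a dict of columns."""
    from unexploited import ExpressionMatrix

    return ExpressionMatrix(pd.DataFrame(values), pairs)
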