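import numpy as np
import pytest

from gvpipe.cli import default_config_for_cohort, run_stage
from gvpipe.synthetic_cohort import CohortSimConfig, emit_cohort


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Default-condition synthetic cohort (5 normal / 7 tumor / 7 rnaseq)."""
    root = tmp_path_factory.mktemp("cohort")
    config = CohortSimConfig(n_patients=7, n_variants=60, seed=11)
    paths = emit_cohort(config, str(root))
    return config, paths


@pytest.fixture(scope="session")
def pipeline_run(cohort, tmp_path_factory):
    """A completed end-to-end pipeline run on the session cohort."""
    config, paths = cohort
    out = tmp_path_factory.mktemp("analysis")
    pcfg = default_config_for_cohort(paths["out_dir"], str(out), seed=config.seed)
    run_stage("all", pcfg)
    return pcfg


@pytest.fixture()
def rng():
    return np.random.default_rng(202)
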