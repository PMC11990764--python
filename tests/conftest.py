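import numpy as np
import pytest

from dnmosaic.config import MosaicSpec, PipelineConfig, SimulationConfig
from dnmosaic.simulate import Cohort, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """Full-size synthetic study: 5 trios, ~85.6 DNMs each, study depths."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """Compact cohort for fast end-to-end checks, with clear-margin mosaics
    (VAFs >= 2% everywhere, generous long-read depth) so detection and
    classification are unambiguous."""
    cfg = SimulationConfig(
        n_trios=3, mean_dnms_per_trio=25.0, seed=5, longread_depth=60.0,
        mosaic_spec=(
            MosaicSpec("pre_pgc_blood", (1, 2), (0.02, 0.12)),
            MosaicSpec("post_pgc_sperm_only", (1, 1), (0.02, 0.05)),
            MosaicSpec("child_postzygotic", (1, 1), (0.30, 0.38)),
        ))
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_result(small_cohort, tmp_path_factory):
    from dnmosaic.pipeline import run_pipeline
    cfg = PipelineConfig(simulation=small_cohort.config,
                         seed=small_cohort.config.seed)
    out = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(cfg, out, cohort=small_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
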