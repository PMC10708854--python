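import numpy as np
import pytest

from msitvc import (GrowthParams, PipelineConfig, SpectralResponseParams,
                    generate_dataset, run_pipeline)
from msitvc.reference import mean_ranking_table, sd_ranking_table


@pytest.fixture
def table_mean():
    """Published mean-block per-method waveband ranks."""
    return mean_ranking_table()


@pytest.fixture
def table_sd():
    """Published sd-block per-method waveband ranks."""
    return sd_ranking_table()


@pytest.fixture(scope="session")
def spoilage_dataset():
    """Default seeded spoilage simulation: 5 temperatures x 17 samples."""
    return generate_dataset(n_per_temp=17, gp=GrowthParams(),
                            sp=SpectralResponseParams(), seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """Cheap dataset for ranker tests (5 temperatures x 8 samples)."""
    return generate_dataset(n_per_temp=8, gp=GrowthParams(),
                            sp=SpectralResponseParams(), seed=3)


@pytest.fixture(scope="session")
def tsk_system():
    """A fixed 4-rule, 3-input ground-truth TSK system."""
    rng = np.random.default_rng(0)
    return [(rng.normal(size=3), rng.uniform(0.5, 1.5, 3), rng.normal(size=4))
            for _ in range(4)]


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One default end-to-end pipeline run, shared across tests."""
    out = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = PipelineConfig(out_dir=str(out), seed=1)
    return run_pipeline(cfg)
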