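import numpy as np
import pytest

from brainnetdx import CohortConfig, PipelineConfig, RVFLConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny null cohort: 6 vs 6 subjects, 10 regions."""
    cfg = CohortConfig(n_asd=6, n_td=6, n_regions=10, vertices_per_region=30,
                       voxels_per_region=40, base_seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_pipeline_config():
    return PipelineConfig(
        cohort=CohortConfig(n_asd=6, n_td=6, n_regions=10, vertices_per_region=30,
                            voxels_per_region=40, base_seed=42),
        q=10,
        n_repeats=2,
        k_folds=3,
        mrmr_k=5,
        rvfl=RVFLConfig(n_hidden=20),
        base_seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
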