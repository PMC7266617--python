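import numpy as np
import pytest

import replearn as rl
from replearn.datasets import TRAINED, UNTRAINED


@pytest.fixture(scope="session")
def small_cfg():
    return rl.SimConfig(n_subjects=2, n_sessions=2, n_runs=8, n_voxels=40,
                        seed=7)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    true = rl.make_true_patterns(small_cfg)
    datasets = rl.make_run_estimates(true, small_cfg)
    return {"config": small_cfg, "true": true, "datasets": datasets}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_pattern_dataset(rng, n_cond=4, n_runs=3, n_voxels=10,
                           with_residuals=False):
    data = rng.standard_normal((n_cond * n_runs, n_voxels))
    ds = rl.PatternDataset(
        data=data,
        condition_ids=np.tile(np.arange(n_cond), n_runs),
        partition_ids=np.repeat(np.arange(n_runs), n_cond),
        residuals=rng.standard_normal((50, n_voxels)) if with_residuals else None,
        dof=50 if with_residuals else None,
    )
    return ds
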