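import numpy as np
import pytest

from carotidfr.synthdata import PhantomSpec
from carotidfr.trajectory import TrajectorySpec, make_trajectory


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_trajectory():
    """50 spokes x 33 samples on a 16-voxel grid (odd count: a k=0 sample)."""
    return make_trajectory(TrajectorySpec(5, 10, 33, 0.5))


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def tiny_experiment():
    """Desk-scale experiment small enough for full reconstruction in tests."""
    from carotidfr.pipeline import ExperimentConfig
    from carotidfr.recon import ReconConfig

    return ExperimentConfig(
        grid_size=24,
        d_d_mm=3.0,
        d_s_mm=3.4,
        scan_duration_s=10.0,
        samples_per_readout=24,
        n_coils=2,
        kspace_noise_rel=0.0,
        recon=ReconConfig(log_objective=False, cg_max_iters=6, n_admm_iters=6),
    )
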