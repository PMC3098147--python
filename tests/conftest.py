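import numpy as np
import pytest

from txmquant import PhantomConfig, build_phantom


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    return PhantomConfig(
        shape=(64, 64, 64), voxel_pitch_nm=15.0,
        cell_axes_nm=(400.0, 400.0, 360.0),
        nucleus_axes_nm=(150.0, 150.0, 140.0),
        n_clusters=10, size_median_nm=120.0, size_log_sigma=0.25,
        min_size_nm=60.0, seed=42,
    )


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return build_phantom(small_config)


@pytest.fixture(scope="session")
def shell_phantom():
    cfg = PhantomConfig(
        shape=(96, 96, 96), voxel_pitch_nm=15.0,
        cell_axes_nm=(650.0, 650.0, 600.0),
        nucleus_axes_nm=(180.0, 180.0, 170.0),
        n_clusters=25, size_median_nm=110.0, size_log_sigma=0.2,
        min_size_nm=60.0, placement="perinuclear_shell",
        shell_inner_nm=200.0, shell_outer_nm=420.0, seed=7,
    )
    return build_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
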