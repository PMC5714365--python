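"""Shared fixtures: scaled phantoms and the full motion study."""

import numpy as np
import pytest

from protonmotion.phantom import PhantomConfig, generate_phase_series
from protonmotion.study import run_motion_study


def small_config(**overrides) -> PhantomConfig:
    """Default anatomy on a coarse 48^3 grid (same physical extent)."""
    kwargs = dict(grid_shape=(48, 48, 48), voxel_spacing=4.0, seed=5)
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def small_series():
    return generate_phase_series(small_config())


@pytest.fixture(scope="session")
def small_study():
    """Four-strategy study on the coarse moving phantom."""
    return run_motion_study(config=small_config(), keep_composite_doses=True)


@pytest.fixture(scope="session")
def zero_motion_study():
    """Four-strategy study with breathing switched off."""
    return run_motion_study(config=small_config(peak_to_peak_amplitude_cm=0.0))


@pytest.fixture(scope="session")
def default_study():
    """The headline experiment: default phantom, 96^3 grid, 1.3 cm motion."""
    return run_motion_study(
        config=PhantomConfig(seed=7), keep_composite_doses=True
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
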