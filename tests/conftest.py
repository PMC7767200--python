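import numpy as np
import pytest

from linefrap import (
    BeamParameters,
    CameraModel,
    SimulationConfig,
    Species,
    generate_dataset,
)


@pytest.fixture(scope="session")
def beam() -> BeamParameters:
    """Calibration constants used across desk-scale experiments."""
    return BeamParameters(K0=1.0, r0e=1.0, r0c=0.25)


@pytest.fixture(scope="session")
def small_noiseless_dataset():
    """A small noise-free rendered dataset shared by pipeline tests:
    40k membrane particles, 23 frames, bleach after frame 2."""
    cfg = SimulationConfig(
        box=12.0,
        species=(Species(D=1.0, count=40_000),),
        beam=BeamParameters(K0=1.0, r0e=1.0, r0c=0.25),
        n_frames=23,
        frame_interval=0.15,
        bleach_after_frame=2,
        camera=CameraModel(photons_per_particle=None),
        seed=21,
    )
    stack, gt, gt_curve, _ = generate_dataset(cfg)
    return cfg, stack, gt, gt_curve


@pytest.fixture(scope="session")
def small_noisy_dataset():
    """Same scenario with a 16-bit camera (Poisson + read noise)."""
    cfg = SimulationConfig(
        box=12.0,
        species=(Species(D=1.0, count=40_000),),
        beam=BeamParameters(K0=1.0, r0e=1.0, r0c=0.25),
        n_frames=23,
        frame_interval=0.15,
        bleach_after_frame=2,
        camera=CameraModel(pixel_size=0.1, photons_per_particle=60.0,
                           read_noise=2.0),
        seed=22,
    )
    stack, gt, gt_curve, _ = generate_dataset(cfg)
    return cfg, stack, gt, gt_curve


def pytest_configure(config):
    np.seterr(all="ignore")
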