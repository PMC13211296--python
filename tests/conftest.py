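import numpy as np
import pytest

from isletscope.synth import (
    DriftModel,
    NoiseModel,
    SceneConfig,
    StepEvent,
    StepSchedule,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def textured_frame(rng):
    """Smooth random texture with broad spectral content, good for registration."""
    import scipy.ndimage as ndi

    frame = ndi.gaussian_filter(rng.standard_normal((96, 96)), 2.0)
    return frame - frame.min() + 0.1


@pytest.fixture
def small_scene():
    """Tiny islet scene for fast generator tests."""
    return SceneConfig(
        frame_shape=(96, 96),
        n_frames=12,
        islet_center=(48.0, 48.0),
        islet_radius=26.0,
        granule_patches=(
            ((42.0, 44.0), 6.0, 3.0),
            ((56.0, 52.0), 5.0, 2.5),
        ),
        texture_grain=2.0,
        seed=7,
    )


@pytest.fixture
def quiet():
    """Noiseless, gain-free detector model."""
    return NoiseModel(photon_scale=0.0, read_sd=0.0, gain_sd=0.0)


@pytest.fixture
def no_drift():
    return DriftModel(kind="fixed_path", path=tuple([(0.0, 0.0)] * 12))


def single_step_schedule(onset=6, drop=0.5, transition=1):
    return StepSchedule(events=(StepEvent(onset, drop, transition),))


@pytest.fixture
def one_step():
    return single_step_schedule()
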