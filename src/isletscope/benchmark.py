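"""Standard synthetic benchmarks: fixed study conditions with ground truth.

Two benchmarks are used throughout the test-suite and the reproduction
script:

* the *drift benchmark* — a 64-frame, 256 x 256 stack with random-walk drift
  of 1 px/frame and the generator's default detector noise, scoring shift
  recovery of the stabilizer;
* the *GSIS benchmark* — the standard stimulation protocol at one frame per
  minute (low glucose 15 min, high glucose 30 min, low glucose 15 min, KCl
  15 min; 75 frames), with granule-depletion steps of 10% and 15% at the
  high-glucose and KCl onsets (frames 15 and 60), either as a full image
  stack or as a directly synthesized noisy normalized trace.

Scene geometry is fixed here, not tunable: only the seed varies between
replicates.
"""

from __future__ import annotations

import numpy as np

from .protocol import StimulusProtocol, standard_gsis_protocol
from .synth import (
    DriftModel,
    NoiseModel,
    SceneConfig,
    StepEvent,
    StepSchedule,
    SyntheticManifest,
    render_scene,
)
from .stack import TimeLapseStack

__all__ = [
    "HIGH_GLUCOSE_ONSET_FRAME",
    "KCL_ONSET_FRAME",
    "BENCHMARK_DROPS",
    "drift_benchmark",
    "gsis_benchmark_scene",
    "gsis_benchmark",
    "noisy_step_trace",
]

HIGH_GLUCOSE_ONSET_FRAME = 15
KCL_ONSET_FRAME = 60
BENCHMARK_DROPS = (0.10, 0.15)


def _benchmark_patches(rng: np.random.Generator, center, islet_radius):
    """Six granule-rich patches scattered inside the islet disk."""
    patches = []
    for _ in range(6):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.65 * islet_radius)
        pc = (center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang))
        pr = rng.uniform(0.08, 0.18) * islet_radius
        patches.append((pc, float(pr), float(rng.uniform(2.5, 4.0))))
    return tuple(patches)


def _scene(seed: int, n_frames: int) -> SceneConfig:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9]))
    center = (128.0, 128.0)
    radius = 80.0
    return SceneConfig(
        frame_shape=(256, 256),
        n_frames=n_frames,
        frame_interval_s=60.0,
        islet_center=center,
        islet_radius=radius,
        granule_patches=_benchmark_patches(rng, center, radius),
        texture_grain=3.0,
        seed=seed,
    )


def drift_benchmark(seed: int) -> tuple[TimeLapseStack, SyntheticManifest]:
    """64-frame drifting stack (random walk, 1 px/frame) with default noise."""
    return render_scene(
        _scene(seed, n_frames=64),
        drift=DriftModel(kind="random_walk", step_sd=1.0),
        noise=NoiseModel(),
        schedule=StepSchedule(),
    )


def gsis_benchmark_scene(
    seed: int,
    drift_sd: float = 0.5,
) -> tuple[SceneConfig, DriftModel, NoiseModel, StepSchedule]:
    """Configuration bundle for the two-step stimulation benchmark."""
    schedule = StepSchedule(
        events=(
            StepEvent(HIGH_GLUCOSE_ONSET_FRAME, BENCHMARK_DROPS[0], 1),
            StepEvent(KCL_ONSET_FRAME, BENCHMARK_DROPS[1], 1),
        ),
        baseline_hold=HIGH_GLUCOSE_ONSET_FRAME,
    )
    return (
        _scene(seed, n_frames=75),
        DriftModel(kind="random_walk", step_sd=drift_sd),
        NoiseModel(),
        schedule,
    )


def gsis_benchmark(seed: int) -> tuple[TimeLapseStack, SyntheticManifest, StimulusProtocol]:
    """Full image-stack GSIS benchmark plus its stimulation protocol."""
    config, drift, noise, schedule = gsis_benchmark_scene(seed)
    stack, manifest = render_scene(config, drift, noise, schedule)
    return stack, manifest, standard_gsis_protocol()


def noisy_step_trace(
    seed: int,
    n_frames: int = 75,
    onsets: tuple[int, ...] = (HIGH_GLUCOSE_ONSET_FRAME, KCL_ONSET_FRAME),
    drops: tuple[float, ...] = BENCHMARK_DROPS,
    noise_sd_frac: float = 0.01,
    baseline: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Directly synthesized normalized trace with multiplicative step drops.

    Gaussian noise with standard deviation ``noise_sd_frac * baseline`` is
    added.  Returns ``(trace, true_step_sizes)`` where the k-th step size is
    the absolute level change at ``onsets[k]``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    trace = np.full(n_frames, float(baseline))
    level = float(baseline)
    step_sizes = []
    for onset, drop in zip(onsets, drops):
        new_level = level * (1.0 - drop)
        trace[onset:] = new_level
        step_sizes.append(level - new_level)
        level = new_level
    trace = trace + rng.normal(0.0, noise_sd_frac * baseline, size=n_frames)
    return trace, np.array(step_sizes)
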