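"""Study conditions for the detection benchmarks.

The synthetic conditions the pipelines are validated against are defined
once, here, and shared by the test suite and the reproduction script:

* spike benchmark — 200 x 200 px movies, 100 frames at 50 ms, ten
  scheduled dF/F0 = 1.0 spikes (tau = 400 ms) per movie on a flat
  specimen baseline set so that the spike peak amplitude is five times
  the per-pixel camera noise standard deviation (SNR 5), plus matched
  noise-only movies as the false-positive control;
* vesicle benchmark — scripted approach-and-merge scenes of two vesicles
  (one diffusing gently, one walking a straight 18 px approach over 16
  frames) and matched control scenes of four well-separated independent
  vesicles. The proximity event is localised at the disappeared track's
  last resolvable position, so the vesicle footprint (sigma 0.7 px) and
  the detection smoothing (0.4 px, window 3) are chosen to keep two
  emitters resolvable down to ~2.5 px separation — well-sampled point
  emitters at the high SNR of this labeling, matching the 3 px event
  localisation tolerance of the scripted scenario.

Event positions keep clear of the border-exclusion zone so that every
scheduled event is detectable by contract.
"""

from __future__ import annotations

import numpy as np

from .pipelines import RapidSpikesParams, VesicleProximityParams
from .scenes import MergeScript, SceneSpec, SpikeEvent

__all__ = [
    "SPIKE_SNR",
    "spike_benchmark_spec",
    "spike_benchmark_params",
    "merge_scene_spec",
    "control_scene_spec",
    "vesicle_benchmark_params",
]

SPIKE_SNR = 5.0
_READ_NOISE = 2.0
# Background B such that a dF/F0 = 1 spike (signal = B counts) sits at
# SNR = B / sqrt(B + read_noise^2): solve B^2 = SNR^2 (B + r^2).
_SPIKE_BACKGROUND = float(
    (SPIKE_SNR**2 + np.sqrt(SPIKE_SNR**4 + 4 * SPIKE_SNR**2 * _READ_NOISE**2)) / 2
)


def spike_benchmark_spec(
    seed: int,
    n_spikes: int = 10,
    shape: tuple[int, int] = (200, 200),
    n_frames: int = 100,
) -> SceneSpec:
    """One seeded spike movie: scheduled transients on a flat baseline."""
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = 25.0
    min_sep = 15.0
    positions: list[tuple[float, float]] = []
    while len(positions) < n_spikes:
        x = float(rng.uniform(margin, w - 1 - margin))
        y = float(rng.uniform(margin, h - 1 - margin))
        if all(np.hypot(x - px, y - py) >= min_sep for px, py in positions):
            positions.append((x, y))
    onsets = rng.integers(2, n_frames - 10, size=n_spikes)
    spikes = tuple(
        SpikeEvent(onset_frame=int(t), x=x, y=y, amplitude=1.0, tau_ms=400.0, sigma_spot=2.0)
        for (x, y), t in zip(positions, onsets)
    )
    return SceneSpec(
        shape=shape,
        n_frames=n_frames,
        frame_period_ms=50.0,
        background=_SPIKE_BACKGROUND,
        poisson_noise=True,
        read_noise=_READ_NOISE,
        spikes=spikes,
    )


def spike_benchmark_params() -> RapidSpikesParams:
    return RapidSpikesParams(
        sigma=1.5,
        window=7,
        ratio_threshold=1.5,
        min_intensity=15.0,
        border_px=15,
        epsilon=1.0,
    )


def merge_scene_spec(seed: int) -> SceneSpec:
    """Two vesicles, one scripted to approach and merge onto the other."""
    rng = np.random.default_rng(seed)
    h = w = 150
    target = (
        float(rng.uniform(45, w - 45)),
        float(rng.uniform(45, h - 45)),
    )
    angle = float(rng.uniform(0, 2 * np.pi))
    dist = 18.0
    mover = (target[0] + dist * np.cos(angle), target[1] + dist * np.sin(angle))
    return SceneSpec(
        shape=(h, w),
        n_frames=40,
        frame_period_ms=50.0,
        background=20.0,
        read_noise=_READ_NOISE,
        n_vesicles=2,
        vesicle_amplitude=300.0,
        vesicle_sigma=0.7,
        diffusion_um2_s=0.002,
        vesicle_starts=(mover, target),
        merges=(MergeScript(mover=0, target=1, start_frame=8, merge_frame=24),),
    )


def control_scene_spec(seed: int) -> SceneSpec:
    """Independent, well-separated vesicles: no merge events expected."""
    h = w = 150
    starts = ((40.0, 40.0), (110.0, 40.0), (40.0, 110.0), (110.0, 110.0))
    return SceneSpec(
        shape=(h, w),
        n_frames=40,
        frame_period_ms=50.0,
        background=20.0,
        read_noise=_READ_NOISE,
        n_vesicles=4,
        vesicle_amplitude=300.0,
        vesicle_sigma=0.7,
        diffusion_um2_s=0.002,
        vesicle_starts=starts,
    )


def vesicle_benchmark_params() -> VesicleProximityParams:
    return VesicleProximityParams(
        proximity_radius=4.0,
        lookback=3,
        window_frames=10,
        presence_fraction=0.6,
        min_net_displacement=5.0,
        min_path_length=5.0,
        link_distance=6.0,
        memory=0,
        sigma=0.4,
        sigma_bg=8.0,
        window=3,
        low_threshold=20.0,
        high_threshold=1e6,
        border_px=8,
    )
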