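"""Behavioural tests for the three real-time detection pipelines."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from eventscope.imaging_core import Frame, WidefieldTimelapse
from eventscope.pipelines import (
    DynaminRiseParams,
    RapidSpikesParams,
    VesicleProximityParams,
    get_pipeline,
)
from eventscope.scenes import RampEvent, SceneSpec, _add_gaussian_spot, generate_dynamin_scene
from eventscope import benchmarks as bm
from eventscope.scenes import generate_calcium_scene, generate_vesicle_scene

from conftest import frames_from_arrays, run_pipeline_over


def replay(frames, pipeline_name, params, mask=None):
    pipeline = get_pipeline(pipeline_name)
    state = pipeline.fresh_state()
    if mask is None:
        mask = np.ones(frames[0].shape, dtype=bool)
    events = []
    for frame in frames:
        ev, state = pipeline.process(frame, state, mask, params)
        events.extend(ev)
    return events


class TestRapidSignalSpikes:
    params = RapidSpikesParams(sigma=1.0, window=5, ratio_threshold=1.5, min_intensity=10, border_px=5)

    def test_first_frame_only_primes_state(self):
        frames = frames_from_arrays([np.full((40, 40), 100.0)])
        assert replay(frames, "rapid_signal_spikes", self.params) == []

    def test_identical_frames_produce_no_events(self):
        arr = np.full((40, 40), 100.0)
        frames = frames_from_arrays([arr, arr.copy()])
        pipeline = get_pipeline("rapid_signal_spikes")
        state = pipeline.fresh_state()
        mask = np.ones((40, 40), bool)
        _, state = pipeline.process(frames[0], state, mask, self.params)
        events, state = pipeline.process(frames[1], state, mask, self.params)
        assert events == []
        ratio = state.last_preprocessed
        np.testing.assert_allclose(ratio[mask], 1.0)

    def test_single_block_detected_at_center_with_oracle_salience(self):
        prev = np.full((50, 50), 100.0)
        cur = prev.copy()
        cur[20:25, 30:35] = 200.0  # 5x5 block, center (x=32, y=22)
        events = replay(frames_from_arrays([prev, cur]), "rapid_signal_spikes", self.params)
        assert len(events) == 1
        ev = events[0]
        assert (ev.x, ev.y) == (32.0, 22.0)
        # oracle: run the stages directly
        ratio = gaussian_filter(cur, 1.0, mode="reflect") / np.maximum(
            gaussian_filter(prev, 1.0, mode="reflect"), 1.0
        )
        assert ev.salience == pytest.approx(ratio[22, 32])
        assert 1.5 < ev.salience <= 2.0

    def test_events_ordered_by_salience(self):
        prev = np.full((60, 60), 100.0)
        cur = prev.copy()
        cur[10:15, 10:15] = 180.0  # ratio ~1.8
        cur[40:45, 40:45] = 250.0  # ratio ~2.5
        events = replay(frames_from_arrays([prev, cur]), "rapid_signal_spikes", self.params)
        assert len(events) == 2
        assert (events[0].x, events[0].y) == (42.0, 42.0)
        assert events[0].salience > events[1].salience

    def test_border_exclusion_suppresses_edge_events(self):
        prev = np.full((40, 40), 100.0)
        cur = prev.copy()
        cur[0:4, 0:4] = 300.0
        events = replay(frames_from_arrays([prev, cur]), "rapid_signal_spikes", self.params)
        assert events == []

    def test_mask_gates_detection(self):
        prev = np.full((40, 40), 100.0)
        cur = prev.copy()
        cur[18:23, 18:23] = 250.0
        mask = np.zeros((40, 40), bool)
        assert replay(frames_from_arrays([prev, cur]), "rapid_signal_spikes", self.params, mask) == []

    def test_shape_mismatch_rejected(self):
        pipeline = get_pipeline("rapid_signal_spikes")
        with pytest.raises(ValueError, match="mask shape"):
            pipeline.process(
                Frame(np.zeros((10, 10))), pipeline.fresh_state(), np.ones((5, 5), bool), self.params
            )

    def test_noise_only_movie_emits_nothing_at_default_threshold(self):
        spec = replace(bm.spike_benchmark_spec(0), spikes=())
        timelapse, _ = generate_calcium_scene(spec, seed=7)
        events = run_pipeline_over(timelapse, "rapid_signal_spikes", bm.spike_benchmark_params())
        assert events == []

    def test_replay_is_deterministic(self):
        timelapse, _ = generate_calcium_scene(bm.spike_benchmark_spec(3, n_frames=40), seed=3)
        e1 = run_pipeline_over(timelapse, "rapid_signal_spikes", bm.spike_benchmark_params())
        e2 = run_pipeline_over(timelapse, "rapid_signal_spikes", bm.spike_benchmark_params())
        assert e1 == e2


def ramp_timelapse(ratio, n_frames=10, i0=100.0):
    """Noiseless scene with one spot ramping i0 -> ratio*i0 over 5 frames."""
    spec = SceneSpec(
        shape=(60, 60),
        n_frames=n_frames,
        background=50.0,
        poisson_noise=False,
        read_noise=0.0,
        ramps=(RampEvent(onset_frame=0, x=30.0, y=28.0, i0=i0, ratio=ratio, ramp_frames=5),),
    )
    return generate_dynamin_scene(spec, seed=0)


class TestDynaminRise:
    params = DynaminRiseParams(
        n_frames=5,
        rise_ratio=2.0,
        low_threshold=5.0,
        high_threshold=1e6,
        box_halfwidth=2,
        link_distance=4.0,
        memory=0,
        sigma=1.0,
        sigma_bg=8.0,
        window=5,
        border_px=5,
    )

    def test_constant_spot_never_triggers(self):
        timelapse, _ = ramp_timelapse(ratio=1.0000001, n_frames=10)
        events = run_pipeline_over(timelapse, "dynamin_rise", self.params)
        assert events == []

    def test_ramp_to_2p6_triggers_once_at_fifth_frame(self):
        timelapse, truth = ramp_timelapse(ratio=2.6, n_frames=10)
        events = run_pipeline_over(timelapse, "dynamin_rise", self.params)
        assert len(events) == 1
        ev = events[0]
        assert ev.frame_index == 4  # N = 5 frames: 0..4
        assert np.hypot(ev.x - 30.0, ev.y - 28.0) <= 1.0
        assert ev.salience >= 2.0

    def test_ramp_to_1p8_stays_below_threshold(self):
        timelapse, _ = ramp_timelapse(ratio=1.8, n_frames=10)
        assert run_pipeline_over(timelapse, "dynamin_rise", self.params) == []

    def test_box_intensity_ratio_matches_scene_arithmetic(self):
        """The detected rise ratio equals the scheduled amplitude ratio:
        preprocessing is linear and the flat background cancels."""
        timelapse, _ = ramp_timelapse(ratio=2.6, n_frames=10)
        events = run_pipeline_over(timelapse, "dynamin_rise", self.params)
        assert events[0].salience == pytest.approx(2.6, rel=0.05)

    def test_high_threshold_rejects_bright_clusters(self):
        timelapse, _ = ramp_timelapse(ratio=2.6, n_frames=10)
        params = replace(self.params, high_threshold=10.0, low_threshold=1.0)
        assert run_pipeline_over(timelapse, "dynamin_rise", params) == []


def render_vesicle_frames(positions_per_frame, shape=(80, 80), amplitude=300.0, sigma=0.8, background=20.0):
    frames = []
    for pts in positions_per_frame:
        img = np.full(shape, background)
        for x, y in pts:
            _add_gaussian_spot(img, x, y, amplitude, sigma)
        frames.append(img)
    return frames_from_arrays(frames)


class TestVesicleProximity:
    params = VesicleProximityParams(
        proximity_radius=3.0,
        lookback=3,
        window_frames=10,
        presence_fraction=0.6,
        min_net_displacement=5.0,
        min_path_length=5.0,
        link_distance=5.0,
        memory=0,
        sigma=0.4,
        sigma_bg=8.0,
        window=3,
        low_threshold=20.0,
        border_px=5,
    )

    def test_stationary_separated_vesicles_never_trigger(self):
        pts = [[(20.0, 20.0), (40.0, 40.0)]] * 30
        events = replay(render_vesicle_frames(pts), "vesicle_proximity", self.params)
        assert events == []

    def test_scripted_approach_and_merge_triggers_once(self):
        """B approaches stationary A from 15 px to contact over 10 frames,
        after which only one emitter is rendered: all five conditions hold
        once, at B's last resolvable position."""
        a = (40.0, 40.0)
        pts = []
        for t in range(10):
            bx = 40.0 + 15.0 - 1.5 * t
            pts.append([a, (bx, 40.0)])
        pts.extend([[a]] * 10)  # merged: single emitter
        events = replay(render_vesicle_frames(pts), "vesicle_proximity", self.params)
        assert len(events) == 1
        assert np.hypot(events[0].x - a[0], events[0].y - a[1]) <= 3.0

    def test_solitary_disappearance_does_not_trigger(self):
        """A lone moving vesicle that photobleaches: no surviving track is
        close by, so condition 2 fails."""
        pts = [[(20.0 + 1.5 * t, 30.0)] for t in range(10)] + [[]] * 10
        events = replay(render_vesicle_frames(pts), "vesicle_proximity", self.params)
        assert events == []

    def test_stationary_pair_merge_fails_movement_condition(self):
        """Two adjacent stationary vesicles where one vanishes: conditions
        1-4 hold but neither track travelled, so condition 5 fails."""
        pts = [[(30.0, 30.0), (34.0, 30.0)]] * 12 + [[(30.0, 30.0)]] * 8
        events = replay(render_vesicle_frames(pts), "vesicle_proximity", self.params)
        assert events == []

    def test_benchmark_merge_scenes_trigger_at_merge_site(self):
        hits = 0
        for seed in range(5):
            timelapse, truth = generate_vesicle_scene(bm.merge_scene_spec(seed), seed)
            events = run_pipeline_over(timelapse, "vesicle_proximity", bm.vesicle_benchmark_params())
            m = truth.events[0]
            if len(events) == 1 and np.hypot(events[0].x - m["x"], events[0].y - m["y"]) <= 3.0:
                hits += 1
        assert hits >= 4

    def test_control_scenes_are_silent(self):
        for seed in range(5):
            timelapse, _ = generate_vesicle_scene(bm.control_scene_spec(seed), seed)
            assert run_pipeline_over(timelapse, "vesicle_proximity", bm.vesicle_benchmark_params()) == []


class TestInterfaceContract:
    @pytest.mark.parametrize(
        "pipeline_name,params",
        [
            ("rapid_signal_spikes", RapidSpikesParams()),
            ("dynamin_rise", DynaminRiseParams()),
            ("vesicle_proximity", VesicleProximityParams()),
        ],
    )
    def test_state_carries_all_history(self, pipeline_name, params, rng):
        """Frame-by-frame replay through the (frame, state, mask) contract is
        self-contained: running the same stream twice gives identical events,
        and every event lies inside the mask and the border zone."""
        spec = SceneSpec(shape=(64, 64), n_frames=12, background=30.0, read_noise=1.0, n_spots=2)
        timelapse, _ = generate_calcium_scene(spec, seed=11)
        mask = np.ones((64, 64), bool)
        e1 = run_pipeline_over(timelapse, pipeline_name, params, mask)
        e2 = run_pipeline_over(timelapse, pipeline_name, params, mask)
        assert e1 == e2
        h, w = 64, 64
        border = params.border_px
        for ev in e1:
            assert border <= ev.x <= w - 1 - border
            assert border <= ev.y <= h - 1 - border
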