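"""Tests for post-acquisition quantification."""

import numpy as np
import pytest

from eventscope.analysis import (
    ClusterRegion,
    ClusterTrace,
    bleach_correct_histogram_match,
    compute_msd,
    dff0_trace,
    evaluate_detection,
    link_cluster_traces,
    msd_table,
    segment_clusters,
)
from eventscope.imaging_core import WidefieldTimelapse
from eventscope.scenes import SceneSpec, SpikeEvent, brownian_trajectories, generate_calcium_scene


def lapse(frames, period=50.0):
    return WidefieldTimelapse(np.asarray(frames, dtype=float), 100.0, period)


class TestDff0Trace:
    def test_constant_movie_is_flat_zero(self):
        tl = lapse([np.full((20, 20), 80.0)] * 6)
        trace = dff0_trace(tl, (10.0, 10.0), radius=3.0)
        np.testing.assert_allclose(trace.dff0, 0.0)

    def test_doubling_gives_unit_dff0(self):
        frames = [np.full((20, 20), 50.0)] * 5 + [np.full((20, 20), 100.0)] * 3
        trace = dff0_trace(lapse(frames), (10.0, 10.0), radius=2.0, baseline_frames=1)
        np.testing.assert_allclose(trace.dff0[:5], 0.0)
        np.testing.assert_allclose(trace.dff0[5:], 1.0)

    def test_recovers_spike_kinetics_from_noiseless_scene(self):
        spec = SceneSpec(
            shape=(64, 64), n_frames=30, background=200.0,
            poisson_noise=False, read_noise=0.0,
            spikes=(SpikeEvent(onset_frame=5, x=32.0, y=32.0, amplitude=0.8, tau_ms=400.0, sigma_spot=5.0),),
        )
        tl, _ = generate_calcium_scene(spec, seed=0)
        trace = dff0_trace(tl, (32.0, 32.0), radius=1.0, baseline_frames=3)
        t_rel = (np.arange(30) - 5) * 0.05
        expected = np.where(t_rel >= 0, 0.8 * np.exp(-t_rel / 0.4), 0.0)
        np.testing.assert_allclose(trace.dff0, expected, atol=0.8 * 0.02)

    def test_invariant_under_global_gain(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(10, 100, size=(6, 20, 20))
        t1 = dff0_trace(lapse(frames), (10.0, 10.0), 3.0)
        t2 = dff0_trace(lapse(frames * 7.5), (10.0, 10.0), 3.0)
        np.testing.assert_allclose(t1.dff0, t2.dff0, rtol=1e-12)

    def test_disc_outside_frame_rejected(self):
        tl = lapse([np.ones((10, 10))] * 2)
        with pytest.raises(ValueError, match="outside"):
            dff0_trace(tl, (1.0, 5.0), radius=3.0)

    def test_zero_baseline_rejected(self):
        tl = lapse([np.zeros((10, 10)), np.ones((10, 10))])
        with pytest.raises(ValueError, match="baseline"):
            dff0_trace(tl, (5.0, 5.0), radius=2.0)


class TestEvaluateDetection:
    def test_perfect_agreement(self):
        events = [(3, 10.0, 10.0), (7, 30.0, 30.0)]
        q = evaluate_detection(events, events, r_tol=2.0, t_tol=1)
        assert (q.true_ratio, q.det_ratio) == (1.0, 1.0)

    def test_counting_example_eight_of_nine_and_ten(self):
        annotations = [(t, 10.0 * t, 5.0) for t in range(10)]
        detections = [(t, 10.0 * t + 0.5, 5.0) for t in range(8)]  # 8 good
        detections.append((20, 500.0, 500.0))                      # 1 spurious
        q = evaluate_detection(detections, annotations, r_tol=2.0, t_tol=1)
        assert q.n_matched == 8
        assert q.true_ratio == pytest.approx(8 / 9)
        assert q.det_ratio == pytest.approx(0.8)

    def test_no_detections_flags_true_ratio_undefined(self):
        q = evaluate_detection([], [(0, 1.0, 1.0)], r_tol=1.0, t_tol=1)
        assert q.true_ratio is None
        assert q.det_ratio == 0.0

    def test_order_invariance(self, rng):
        anns = [(int(t), float(x), float(y)) for t, x, y in rng.uniform(0, 50, size=(12, 3))]
        dets = [(int(t), float(x), float(y)) for t, x, y in rng.uniform(0, 50, size=(15, 3))]
        q1 = evaluate_detection(dets, anns, 8.0, 3)
        perm = rng.permutation(len(dets))
        q2 = evaluate_detection([dets[i] for i in perm], anns, 8.0, 3)
        assert q1.n_matched == q2.n_matched


class TestBleachCorrection:
    def test_identical_frames_unchanged(self):
        frames = np.tile(np.random.default_rng(0).uniform(0, 100, (16, 16)), (5, 1, 1))
        out = bleach_correct_histogram_match(lapse(frames))
        np.testing.assert_allclose(out.frames, frames)

    def test_halved_frame_restored_to_reference_distribution(self):
        rng = np.random.default_rng(1)
        a = rng.permutation(np.linspace(10, 200, 400)).reshape(20, 20)  # all distinct
        b = 0.5 * a
        out = bleach_correct_histogram_match(lapse([a, b]))
        np.testing.assert_allclose(np.sort(out.frames[1].ravel()), np.sort(a.ravel()))

    def test_exponentially_bleached_movie_means_restored(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(20, 200, size=(32, 32))
        frames = [base * np.exp(-0.15 * t) for t in range(10)]
        out = bleach_correct_histogram_match(lapse(frames), reference_frame_index=0)
        ref_mean = out.frames[0].mean()
        for i in range(10):
            assert abs(out.frames[i].mean() - ref_mean) / ref_mean < 0.02

    def test_mapping_is_monotone_within_each_frame(self):
        rng = np.random.default_rng(3)
        frames = [rng.uniform(0, 255, (24, 24)) for _ in range(4)]
        out = bleach_correct_histogram_match(lapse(frames), 0)
        for orig, corr in zip(frames[1:], out.frames[1:]):
            order = np.argsort(orig.ravel(), kind="stable")
            corrected_sorted = corr.ravel()[order]
            assert np.all(np.diff(corrected_sorted) >= -1e-9)


def rasterized_ellipse(a_px=40, b_px=20, shape=(112, 112), value=100.0):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    inside = ((xx - w / 2) / a_px) ** 2 + ((yy - h / 2) / b_px) ** 2 <= 1.0
    return np.where(inside, value, 0.0), inside


def brute_force_erode(mask):
    h, w = mask.shape
    out = np.zeros_like(mask)
    for i in range(1, h - 1):
        for j in range(1, w - 1):
            out[i, j] = mask[i - 1 : i + 2, j - 1 : j + 2].all()
    return out


class TestSegmentClusters:
    def test_empty_frame_yields_nothing(self):
        assert segment_clusters(np.zeros((32, 32)), 10.0, 0.03) == []

    def test_ellipse_aspect_ratio_and_area_against_pixel_oracle(self):
        # semi-axes large enough that the single 1-px erosion does not bias
        # the axis ratio beyond the tolerance
        img, _ = rasterized_ellipse(40, 20)
        px = 0.03  # 30 nm pixels
        regions = segment_clusters(img, 50.0, px)
        assert len(regions) == 1
        region = regions[0]
        assert region.aspect_ratio == pytest.approx(2.0, abs=0.1)
        # oracle: smooth + threshold as specified, then brute-force erosion
        from scipy.ndimage import gaussian_filter

        mask = gaussian_filter(img, 1.0, mode="reflect") >= 50.0
        eroded_count = int(brute_force_erode(mask).sum())
        assert region.area_um2 == pytest.approx(eroded_count * px**2)

    def test_small_objects_excluded_by_area_filter(self):
        img = np.zeros((32, 32))
        img[10:14, 10:16] = 100.0  # erodes to a handful of px, well under 0.015 um^2
        assert segment_clusters(img, 50.0, 0.03) == []
        # a larger object at the same pixel size passes the filter
        big = np.zeros((40, 40))
        big[8:18, 8:24] = 100.0
        regions = segment_clusters(big, 50.0, 0.03)
        assert len(regions) == 1
        assert regions[0].area_um2 > 0.015

    def test_centroid_is_binary_centroid_in_um(self):
        img = np.zeros((40, 40))
        img[10:20, 14:30] = 100.0
        regions = segment_clusters(img, 50.0, 0.05)
        x, y = regions[0].centroid_um
        # symmetric block: centroid at the block center
        assert x == pytest.approx((14 + 29) / 2 * 0.05, abs=0.05)
        assert y == pytest.approx((10 + 19) / 2 * 0.05, abs=0.05)

    def test_invalid_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            segment_clusters(np.zeros((8, 8)), 1.0, 0.0)


def region(frame, x_um, y_um, area=0.1):
    return ClusterRegion(frame_index=frame, area_um2=area, aspect_ratio=1.0, centroid_um=(x_um, y_um))


class TestLinkClusterTraces:
    def test_stationary_cluster_one_trace(self):
        per_frame = [[region(f, 1.0, 1.0)] for f in range(10)]
        traces = link_cluster_traces(per_frame)
        assert len(traces) == 1 and len(traces[0]) == 10

    def test_jump_beyond_limit_splits_trace(self):
        per_frame = [[region(0, 1.0, 1.0)], [region(1, 1.5, 1.0)]]  # 0.5 um > 0.3 um
        traces = link_cluster_traces(per_frame)
        assert len(traces) == 2

    def test_two_drifting_clusters_no_swap(self):
        per_frame = [
            [region(f, 0.1 * f, 0.0), region(f, 0.1 * f, 2.0)] for f in range(10)
        ]
        traces = link_cluster_traces(per_frame)
        assert len(traces) == 2
        for tr in traces:
            ys = {c[1] for c in tr.centroids_um}
            assert len(ys) == 1

    def test_primary_flag_marks_largest_first_frame_cluster(self):
        per_frame = [
            [region(0, 1.0, 1.0, area=0.5), region(0, 3.0, 3.0, area=0.2)],
            [region(1, 1.05, 1.0, area=0.5), region(1, 3.0, 3.05, area=0.2)],
        ]
        traces = link_cluster_traces(per_frame)
        primary = [tr for tr in traces if tr.is_primary]
        assert len(primary) == 1
        assert primary[0].centroids_um[0] == (1.0, 1.0)


class TestComputeMsd:
    def test_stationary_trace_is_zero(self):
        tr = ClusterTrace(frames=list(range(5)), centroids_um=[(1.0, 1.0)] * 5, areas_um2=[0.1] * 5)
        assert compute_msd(tr, 2) == 0.0
        assert compute_msd(tr, 2, mode="literal_distance") == 0.0

    def test_uniform_motion_closed_form(self):
        pts = [(0.1 * t, 0.0) for t in range(10)]
        tr = ClusterTrace(frames=list(range(10)), centroids_um=pts, areas_um2=[0.1] * 10)
        assert compute_msd(tr, 3) == pytest.approx(0.09)
        assert compute_msd(tr, 3, mode="literal_distance") == pytest.approx(0.3)

    def test_lag_zero_and_overlong_lag(self):
        tr = ClusterTrace(frames=[0, 1], centroids_um=[(0, 0), (1, 1)], areas_um2=[0.1, 0.1])
        assert compute_msd(tr, 0) == 0.0
        with pytest.raises(ValueError):
            compute_msd(tr, 2)

    def test_brownian_ensemble_linear_in_lag(self):
        D, dt = 0.01, 0.4
        traj = brownian_trajectories(50, 100, D, dt, seed=9)
        for lag in (1, 3, 5):
            msds = [compute_msd(traj[:, k, :], lag) for k in range(traj.shape[1])]
            assert np.mean(msds) == pytest.approx(4 * D * dt * lag, rel=0.1)

    def test_msd_table_modes_and_nan_for_short_traces(self):
        tr = ClusterTrace(frames=[0, 1], centroids_um=[(0, 0), (0.1, 0)], areas_um2=[0.1] * 2)
        table = msd_table([tr], max_lag=3)
        assert table[table.lag_frames == 1].msd.iloc[0] == pytest.approx(0.01)
        assert np.isnan(table[table.lag_frames == 3].msd.iloc[0])
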