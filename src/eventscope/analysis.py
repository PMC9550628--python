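"""Post-acquisition quantification.

Three groups of tools:

* event validation — dF/F0 trace extraction at detected coordinates and
  detection-quality ratios against manual annotations (the true-positive
  ratio among detections and the detected fraction of annotated events);
* photobleaching compensation by histogram matching each frame onto a
  reference frame;
* cluster dynamics — segmentation of labeled vesicle clusters in scan
  timelapses (smooth, global threshold, single erosion, size filter),
  centroid-trace linking with a per-frame step limit, and mean squared
  displacement analysis of the traces.

MSD is reported in µm² as the mean of squared centroid displacements at a
given lag (the default); a ``literal_distance`` mode returning the mean
un-squared Euclidean distance in µm is available for comparison, since
both conventions appear in the field's informal descriptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.exposure import match_histograms

from .imaging_core import WidefieldTimelapse
from .pipelines import EventDetection

__all__ = [
    "IntensityTrace",
    "DetectionQuality",
    "ClusterRegion",
    "ClusterTrace",
    "dff0_trace",
    "evaluate_detection",
    "bleach_correct_histogram_match",
    "segment_clusters",
    "link_cluster_traces",
    "compute_msd",
]

MIN_CLUSTER_AREA_UM2 = 0.015   # objects at or below this are discarded
MAX_CLUSTER_STEP_UM = 0.3      # upper limit on centroid movement per frame


@dataclass
class IntensityTrace:
    """Mean disc intensity around a coordinate per frame, and its dF/F0."""

    f: np.ndarray        # F(t), counts
    t: np.ndarray        # frame times, s
    f0: float            # baseline
    dff0: np.ndarray     # (F(t) - F0) / F0

    def __len__(self) -> int:
        return len(self.f)


def dff0_trace(
    timelapse: WidefieldTimelapse,
    coordinate: tuple[float, float],
    radius: float = 3.0,
    baseline_frames: int = 1,
) -> IntensityTrace:
    """Extract F(t) as the mean in a disc and normalise to dF/F0.

    F0 is the mean of the first ``baseline_frames`` frames;
    ``baseline_frames = 1`` makes F0 = F(t0). The disc must lie inside
    the frame and F0 must be positive.
    """
    if baseline_frames < 1 or baseline_frames > len(timelapse):
        raise ValueError("baseline_frames must be in [1, n_frames]")
    x, y = coordinate
    h, w = timelapse.frame_shape
    if not (radius <= x <= w - 1 - radius and radius <= y <= h - 1 - radius):
        raise ValueError("disc extends outside the frame")
    yy, xx = np.mgrid[0:h, 0:w]
    disc = (xx - x) ** 2 + (yy - y) ** 2 <= radius**2
    f = timelapse.frames[:, disc].astype(float).mean(axis=1)
    t = np.arange(len(timelapse)) * timelapse.frame_period_ms / 1000.0
    f0 = float(f[:baseline_frames].mean())
    if f0 <= 0:
        raise ValueError("baseline F0 must be > 0")
    return IntensityTrace(f=f, t=t, f0=f0, dff0=(f - f0) / f0)


@dataclass
class DetectionQuality:
    """Detection-vs-annotation agreement counts and ratios.

    ``true_ratio`` is matched detections / all detections (None when
    there are no detections); ``det_ratio`` is matched annotations / all
    annotations.
    """

    n_detections: int
    n_annotations: int
    n_matched: int
    true_ratio: float | None
    det_ratio: float
    r_tol_px: float
    t_tol_frames: int


def _event_tuple(e) -> tuple[int, float, float]:
    if isinstance(e, EventDetection):
        return e.frame_index, e.x, e.y
    if isinstance(e, dict):
        return int(e["frame_index"]), float(e["x"]), float(e["y"])
    f, x, y = e
    return int(f), float(x), float(y)


def evaluate_detection(detections, annotations, r_tol: float, t_tol: int) -> DetectionQuality:
    """Greedy one-to-one matching of detections to annotations.

    Candidate pairs within both tolerances are sorted by time difference
    first, then spatial distance, and matched greedily. The result is
    order-independent in the inputs.
    """
    if r_tol <= 0 or t_tol <= 0:
        raise ValueError("tolerances must be > 0")
    dets = [_event_tuple(e) for e in detections]
    anns = [_event_tuple(e) for e in annotations]

    pairs = []
    for di, (df, dx, dy) in enumerate(dets):
        for ai, (af, ax, ay) in enumerate(anns):
            dt = abs(df - af)
            dr = float(np.hypot(dx - ax, dy - ay))
            if dt <= t_tol and dr <= r_tol:
                pairs.append((dt, dr, df, dx, dy, di, ai))
    pairs.sort()

    used_d: set[int] = set()
    used_a: set[int] = set()
    matched = 0
    for dt, dr, _f, _x, _y, di, ai in pairs:
        if di in used_d or ai in used_a:
            continue
        used_d.add(di)
        used_a.add(ai)
        matched += 1

    return DetectionQuality(
        n_detections=len(dets),
        n_annotations=len(anns),
        n_matched=matched,
        true_ratio=None if not dets else matched / len(dets),
        det_ratio=0.0 if not anns else matched / len(anns),
        r_tol_px=float(r_tol),
        t_tol_frames=int(t_tol),
    )


def bleach_correct_histogram_match(
    timelapse: WidefieldTimelapse, reference_frame_index: int = 0
) -> WidefieldTimelapse:
    """Remap each frame's intensity distribution onto a reference frame's.

    The quantile mapping is monotone non-decreasing within each frame, so
    intensity ordering is preserved; the reference frame is returned
    unchanged. Compensates photobleaching without modelling its kinetics.
    """
    frames = timelapse.frames
    if not 0 <= reference_frame_index < len(timelapse):
        raise ValueError("reference frame index out of range")
    ref = frames[reference_frame_index].astype(float)
    out = np.empty_like(frames, dtype=float)
    for i in range(len(timelapse)):
        if i == reference_frame_index:
            out[i] = ref
        else:
            out[i] = match_histograms(frames[i].astype(float), ref)
    return WidefieldTimelapse(out, timelapse.pixel_size_nm, timelapse.frame_period_ms)


@dataclass
class ClusterRegion:
    """One segmented cluster in one frame."""

    frame_index: int
    area_um2: float
    aspect_ratio: float
    centroid_um: tuple[float, float]  # (x, y)

    def to_dict(self) -> dict:
        return {
            "frame_index": self.frame_index,
            "area_um2": self.area_um2,
            "aspect_ratio": self.aspect_ratio,
            "x_um": self.centroid_um[0],
            "y_um": self.centroid_um[1],
        }


def segment_clusters(
    frame: np.ndarray,
    global_threshold: float,
    pixel_size_um: float,
    frame_index: int = 0,
    smoothing_sigma: float = 1.0,
    erosion_iterations: int = 1,
    min_area_um2: float = MIN_CLUSTER_AREA_UM2,
) -> list[ClusterRegion]:
    """Segment labeled clusters in one scan frame.

    Gaussian smoothing (1 px), binarisation at a timelapse-constant global
    threshold, one binary erosion with a 3x3 square element, 8-connected
    labelling, and a size filter discarding objects with area at or below
    ``min_area_um2``. The aspect ratio is major/minor axis of the
    region's second-moment equivalent ellipse; the centroid is the
    unweighted binary centroid in µm.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    img = ndimage.gaussian_filter(np.asarray(frame, dtype=float), smoothing_sigma, mode="reflect")
    binary = img >= global_threshold
    if erosion_iterations > 0:
        binary = ndimage.binary_erosion(
            binary, structure=np.ones((3, 3), dtype=bool), iterations=erosion_iterations
        )
    labels = measure.label(binary, connectivity=2)
    regions = []
    for rp in measure.regionprops(labels):
        area_um2 = rp.area * pixel_size_um**2
        if area_um2 <= min_area_um2:
            continue
        minor = rp.axis_minor_length
        major = rp.axis_major_length
        ar = float(major / minor) if minor > 0 else float("inf")
        cy, cx = rp.centroid
        regions.append(
            ClusterRegion(
                frame_index=frame_index,
                area_um2=float(area_um2),
                aspect_ratio=max(ar, 1.0),
                centroid_um=(float(cx * pixel_size_um), float(cy * pixel_size_um)),
            )
        )
    regions.sort(key=lambda r: -r.area_um2)
    return regions


@dataclass
class ClusterTrace:
    """Ordered centroids of one cluster across frames."""

    frames: list[int]
    centroids_um: list[tuple[float, float]]
    areas_um2: list[float]
    is_primary: bool = False  # seeded by the largest cluster in the first frame

    def __len__(self) -> int:
        return len(self.frames)


def link_cluster_traces(
    regions_per_frame: list[list[ClusterRegion]],
    max_step_um: float = MAX_CLUSTER_STEP_UM,
) -> list[ClusterTrace]:
    """Connect per-frame cluster centroids into traces.

    Frame-to-frame minimum-Euclidean-distance matching with an upper limit
    of ``max_step_um`` movement per frame; unmatched regions end or begin
    traces. The trace seeded by the largest cluster of the first non-empty
    frame is flagged ``is_primary`` for MSD analysis.
    """
    traces: list[ClusterTrace] = []
    open_traces: list[ClusterTrace] = []

    first_frame_with_regions = next(
        (i for i, regs in enumerate(regions_per_frame) if regs), None
    )

    for fi, regions in enumerate(regions_per_frame):
        pairs = []
        for ti, tr in enumerate(open_traces):
            tx, ty = tr.centroids_um[-1]
            for ri, reg in enumerate(regions):
                rx, ry = reg.centroid_um
                d = float(np.hypot(rx - tx, ry - ty))
                if d <= max_step_um:
                    pairs.append((d, ti, ri))
        pairs.sort()
        used_t: set[int] = set()
        used_r: set[int] = set()
        for d, ti, ri in pairs:
            if ti in used_t or ri in used_r:
                continue
            used_t.add(ti)
            used_r.add(ri)
            tr = open_traces[ti]
            reg = regions[ri]
            tr.frames.append(fi)
            tr.centroids_um.append(reg.centroid_um)
            tr.areas_um2.append(reg.area_um2)

        still_open = [tr for ti, tr in enumerate(open_traces) if ti in used_t]
        for ri, reg in enumerate(regions):
            if ri in used_r:
                continue
            new = ClusterTrace(
                frames=[fi],
                centroids_um=[reg.centroid_um],
                areas_um2=[reg.area_um2],
            )
            if (
                fi == first_frame_with_regions
                and reg.area_um2 == max(r.area_um2 for r in regions)
            ):
                new.is_primary = True
            traces.append(new)
            still_open.append(new)
        open_traces = still_open

    return traces


def compute_msd(trace: ClusterTrace | np.ndarray, dt_frames: int, mode: str = "squared") -> float:
    """Mean (squared) displacement of a centroid trace at lag ``dt_frames``.

    ``squared`` (default) returns mean ||c(t+dt) - c(t)||² in µm²;
    ``literal_distance`` returns the mean un-squared distance in µm.
    """
    if mode not in ("squared", "literal_distance"):
        raise ValueError("mode must be 'squared' or 'literal_distance'")
    if dt_frames < 0:
        raise ValueError("dt_frames must be >= 0")
    pts = np.asarray(trace.centroids_um if isinstance(trace, ClusterTrace) else trace, dtype=float)
    n = len(pts)
    if dt_frames >= n:
        raise ValueError(f"dt_frames={dt_frames} >= trace length {n}")
    if dt_frames == 0:
        return 0.0
    disp = pts[dt_frames:] - pts[:-dt_frames]
    d = np.hypot(disp[:, 0], disp[:, 1])
    return float(np.mean(d**2 if mode == "squared" else d))


def msd_table(traces: list[ClusterTrace], max_lag: int, mode: str = "squared") -> pd.DataFrame:
    """Per-trace MSD at lags 1..max_lag (NaN where the trace is too short)."""
    rows = []
    for i, tr in enumerate(traces):
        for lag in range(1, max_lag + 1):
            value = np.nan
            if lag < len(tr):
                value = compute_msd(tr, lag, mode=mode)
            rows.append(
                {
                    "trace": i,
                    "is_primary": tr.is_primary,
                    "lag_frames": lag,
                    "msd": value,
                    "mode": mode,
                }
            )
    return pd.DataFrame(rows)
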