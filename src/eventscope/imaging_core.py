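"""Shared image primitives for real-time event detection.

Everything downstream — the detection pipelines, the acquisition controller
and the post-acquisition analysis — is built from a handful of operations on
2-D camera frames: Gaussian smoothing, background reduction, maximum-filter
peak finding, salience thresholding and greedy nearest-neighbour track
linking.

Coordinate convention: points are ``(x, y)`` with ``x`` = column and
``y`` = row, 0-based and continuous, with the origin at the centre of the
top-left pixel. All convolutions use reflective boundary handling so that
frame edges do not darken and create spurious ratiometric peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "Frame",
    "WidefieldTimelapse",
    "Peak",
    "TrackSet",
    "GreedyLinker",
    "gaussian_smooth",
    "subtract_background",
    "find_local_maxima",
    "threshold_peaks",
    "link_tracks",
]


@dataclass(frozen=True)
class Frame:
    """One widefield camera frame.

    Parameters
    ----------
    data
        2-D array of non-negative intensities (camera counts).
    pixel_size
        Physical pixel size in nm (default 100, a typical widefield
        camera sampling for a 100x objective).
    frame_index
        Position of the frame in its timelapse.
    timestamp
        Acquisition time in seconds from the start of the timelapse.
    """

    data: np.ndarray
    pixel_size: float = 100.0
    frame_index: int = 0
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise ValueError(f"frame data must be 2-D, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("frame intensities must be finite")
        if data.size and data.min() < 0:
            raise ValueError("frame intensities must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Frame":
        return Frame(
            data=data,
            pixel_size=self.pixel_size,
            frame_index=self.frame_index,
            timestamp=self.timestamp,
        )


@dataclass(frozen=True)
class WidefieldTimelapse:
    """Ordered stack of widefield frames with acquisition metadata.

    ``frames`` is a (T, H, W) array; ``pixel_size_nm`` the camera sampling
    and ``frame_period_ms`` the time between frame starts.
    """

    frames: np.ndarray
    pixel_size_nm: float = 100.0
    frame_period_ms: float = 50.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError(f"timelapse must be (T, H, W), got shape {frames.shape}")
        if self.pixel_size_nm <= 0 or self.frame_period_ms <= 0:
            raise ValueError("pixel_size_nm and frame_period_ms must be > 0")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def frame(self, index: int) -> Frame:
        return Frame(
            data=self.frames[index],
            pixel_size=self.pixel_size_nm,
            frame_index=index,
            timestamp=index * self.frame_period_ms / 1000.0,
        )

    def iter_frames(self):
        for i in range(len(self)):
            yield self.frame(i)


class Peak(NamedTuple):
    """A detected point: continuous (x, y) pixel coordinate plus salience."""

    x: float
    y: float
    salience: float


def _as_array(frame: "Frame | np.ndarray") -> np.ndarray:
    return frame.data if isinstance(frame, Frame) else np.asarray(frame)


def gaussian_smooth(frame, sigma: float):
    """Gaussian smoothing with reflective boundaries.

    ``sigma`` is in pixels; ``sigma = 0`` returns the input unchanged.
    Accepts either a :class:`Frame` (returns a Frame) or a bare 2-D array
    (returns an array). Smoothing conserves total intensity for interior
    features and is exactly linear in the input.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    data = _as_array(frame)
    if sigma == 0:
        out = data.astype(float, copy=True)
    else:
        out = ndimage.gaussian_filter(data.astype(float), sigma, mode="reflect")
    return frame.with_data(out) if isinstance(frame, Frame) else out


def subtract_background(frame, sigma_bg: float):
    """Remove the slowly varying background estimated by a wide Gaussian.

    Output is ``frame - gaussian_smooth(frame, sigma_bg)`` clipped at zero,
    so additive offsets (camera baseline, out-of-focus haze) are removed
    while compact features survive. ``sigma_bg`` must be larger than any
    smoothing applied to the features of interest downstream.
    """
    if sigma_bg <= 0:
        raise ValueError(f"sigma_bg must be > 0, got {sigma_bg}")
    data = _as_array(frame).astype(float)
    bg = ndimage.gaussian_filter(data, sigma_bg, mode="reflect")
    out = np.clip(data - bg, 0.0, None)
    return frame.with_data(out) if isinstance(frame, Frame) else out


def find_local_maxima(
    image: np.ndarray,
    window: int = 3,
    mask: np.ndarray | None = None,
) -> list[Peak]:
    """Local maxima as pixels equal to their own maximum-filtered image.

    A pixel is a candidate when its value equals the maximum over the
    ``window`` x ``window`` neighbourhood centred on it (reflective
    boundaries). Connected plateaus of equal candidates collapse to one
    representative, the lexicographically smallest (row, column) pixel.
    Candidates outside ``mask`` are dropped. The result is sorted by
    salience descending, ties broken by (row, column) ascending.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")

    maxed = ndimage.maximum_filter(image, size=window, mode="reflect")
    candidates = image == maxed
    if not candidates.any():
        return []

    # Adjacent candidates within one another's window necessarily share the
    # same value, so connected components of the candidate mask are plateaus.
    labels, n = ndimage.label(candidates, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    rows, cols = np.nonzero(labels)
    order = np.lexsort((cols, rows))  # row-major: first hit per label wins
    rows, cols = rows[order], cols[order]
    seen: set[int] = set()
    reps: list[tuple[int, int]] = []
    for r, c in zip(rows.tolist(), cols.tolist()):
        lab = labels[r, c]
        if lab not in seen:
            seen.add(lab)
            reps.append((r, c))

    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != image.shape:
            raise ValueError("mask shape must match image shape")
        reps = [(r, c) for r, c in reps if mask[r, c]]

    reps.sort(key=lambda rc: (-image[rc[0], rc[1]], rc[0], rc[1]))
    return [Peak(float(c), float(r), float(image[r, c])) for r, c in reps]


def threshold_peaks(peaks: Sequence[Peak], threshold: float) -> list[Peak]:
    """Retain peaks with salience >= threshold, preserving order."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return [p for p in peaks if p.salience >= threshold]


@dataclass
class TrackSet:
    """Linked per-frame detections with identities.

    ``tracks`` maps track id to an ordered list of ``(frame_index, x, y)``.
    Frame indices within a track are strictly increasing; consecutive
    linked positions are separated by at most ``max_link_distance``.
    """

    tracks: dict[int, list[tuple[int, float, float]]]
    max_link_distance: float
    memory: int

    def lengths(self) -> dict[int, int]:
        return {tid: len(pts) for tid, pts in self.tracks.items()}

    def n_detections(self) -> int:
        return sum(len(pts) for pts in self.tracks.values())


@dataclass
class _ActiveTrack:
    track_id: int
    last_frame: int
    last_pos: tuple[float, float]


class GreedyLinker:
    """Incremental greedy nearest-neighbour track linker.

    Frame-to-frame assignment: all (active track, detection) pairs within
    ``max_link_distance`` are sorted by distance (ties by track id, then
    detection index) and matched one-to-one. Unmatched detections start new
    tracks. A track unmatched for at most ``memory`` frames may be resumed;
    once the gap exceeds ``memory`` the track is closed. Deterministic
    given input order.

    The incremental form exists because the real-time pipelines link as
    frames arrive; :func:`link_tracks` is the batch wrapper.
    """

    def __init__(self, max_link_distance: float, memory: int = 0):
        if max_link_distance <= 0:
            raise ValueError("max_link_distance must be > 0")
        if memory < 0:
            raise ValueError("memory must be >= 0")
        self.max_link_distance = float(max_link_distance)
        self.memory = int(memory)
        self.tracks: dict[int, list[tuple[int, float, float]]] = {}
        self._active: list[_ActiveTrack] = []
        self.closed: dict[int, int] = {}  # track id -> last detection frame
        self._next_id = 0

    def update(self, frame_index: int, detections: Sequence[tuple[float, float]]) -> dict[int, int]:
        """Link one frame of detections; returns {detection index: track id}."""
        # Retire tracks whose gap now exceeds the memory.
        survivors: list[_ActiveTrack] = []
        for tr in self._active:
            if frame_index - tr.last_frame > self.memory + 1:
                self.closed[tr.track_id] = tr.last_frame
            else:
                survivors.append(tr)
        self._active = survivors

        pts = [(float(x), float(y)) for x, y in detections]
        pairs: list[tuple[float, int, int]] = []
        for ti, tr in enumerate(self._active):
            tx, ty = tr.last_pos
            for di, (x, y) in enumerate(pts):
                d = float(np.hypot(x - tx, y - ty))
                if d <= self.max_link_distance:
                    pairs.append((d, ti, di))
        pairs.sort(key=lambda p: (p[0], self._active[p[1]].track_id, p[2]))

        matched_tracks: set[int] = set()
        matched_dets: set[int] = set()
        assignment: dict[int, int] = {}
        for d, ti, di in pairs:
            if ti in matched_tracks or di in matched_dets:
                continue
            matched_tracks.add(ti)
            matched_dets.add(di)
            tr = self._active[ti]
            tr.last_frame = frame_index
            tr.last_pos = pts[di]
            self.tracks[tr.track_id].append((frame_index, *pts[di]))
            assignment[di] = tr.track_id

        for di, (x, y) in enumerate(pts):
            if di in matched_dets:
                continue
            tid = self._next_id
            self._next_id += 1
            self.tracks[tid] = [(frame_index, x, y)]
            self._active.append(_ActiveTrack(tid, frame_index, (x, y)))
            assignment[di] = tid
        return assignment

    def newly_closed(self, frame_index: int) -> list[int]:
        """Track ids whose gap first exceeded the memory at ``frame_index``."""
        return [
            tid
            for tid, last in self.closed.items()
            if frame_index - last == self.memory + 2
        ]

    def active_ids(self) -> list[int]:
        return [tr.track_id for tr in self._active]

    def result(self) -> TrackSet:
        return TrackSet(
            tracks={tid: list(pts) for tid, pts in self.tracks.items()},
            max_link_distance=self.max_link_distance,
            memory=self.memory,
        )


def link_tracks(
    detections_per_frame: Sequence[Sequence[tuple[float, float]]] | Mapping[int, Sequence[tuple[float, float]]],
    max_link_distance: float,
    memory: int = 0,
) -> TrackSet:
    """Link per-frame point detections into tracks.

    ``detections_per_frame`` is either a sequence indexed by frame or a
    mapping {frame_index: detections}; each detection is an (x, y) pair
    (a :class:`Peak` works too — extra fields are ignored).
    """
    linker = GreedyLinker(max_link_distance, memory)
    if isinstance(detections_per_frame, Mapping):
        items: Iterable[tuple[int, Sequence]] = sorted(detections_per_frame.items())
    else:
        items = enumerate(detections_per_frame)
    for frame_index, dets in items:
        linker.update(frame_index, [(p[0], p[1]) for p in dets])
    return linker.result()
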