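"""Closed-loop acquisition control: widefield surveillance, event-triggered scans.

The controller consumes a frame source, runs the chosen detection pipeline
on every widefield frame, and on a detected event maps the coordinate into
scan space, requests a small high-resolution scan stack centred there,
saves the evidence bundle (pre-event widefield buffer, scan stack, log
entry), resets the pipeline state and resumes surveillance.

The scan request is a callback contract — (centre, size, pixel size,
frames) -> stack — so the same controller drives a synthetic scene or, in
principle, a hardware backend. Run modes:

``endless``
    trigger a scan on every detected event and keep going;
``single_trigger``
    stop after the first triggered scan;
``validation``
    detect and log events but request no scans (pipeline benchmarking);
``visualization``
    like validation, additionally retaining each frame's preprocessed map.

Validation/visualization perform the same pipeline-state reset after a
would-be trigger as the triggering modes, so all modes detect the
identical event stream on the same deterministic source.
"""

from __future__ import annotations

import dataclasses
import json
import time
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

import numpy as np

from .imaging_core import Frame, WidefieldTimelapse
from .pipelines import EventDetection, get_pipeline
from .scenes import SceneGroundTruth, SceneSpec, render_scan_roi
from .transform import PolynomialTransform2D

__all__ = [
    "MODES",
    "AcquisitionConfig",
    "TimingLogEntry",
    "EventBundle",
    "ExperimentRecord",
    "record_binary_mask",
    "run_experiment",
    "write_log",
    "read_log",
    "SceneFrameSource",
    "TimelapseSource",
]

MODES = ("endless", "single_trigger", "validation", "visualization")

LOG_SCHEMA_VERSION = 1

MASK_FRAME_COUNT = 10  # frames averaged when recording the binary sample mask


@dataclass
class AcquisitionConfig:
    """Everything a run needs besides the frame source and the transform."""

    pipeline: str = "rapid_signal_spikes"
    params: object | None = None
    mode: str = "endless"
    buffer_length: int = 10            # widefield frames saved leading up to an event
    scan_size_um: float = 3.0
    scan_pixel_nm: float = 25.0
    scan_frames: int = 5
    scan_frame_period_ms: float = 400.0
    mask_threshold: float | None = None
    refractory_radius_px: float = 0.0  # per-site repeat-trigger suppression, off by default
    refractory_frames: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.buffer_length < 1:
            raise ValueError("buffer_length must be >= 1")
        if self.scan_size_um <= 0 or self.scan_pixel_nm <= 0 or self.scan_frames < 1:
            raise ValueError("invalid scan geometry")


@dataclass
class TimingLogEntry:
    """Measured per-stage wall-clock durations for one event (metadata only)."""

    frame_index: int
    analysis_ms: float
    transform_ms: float
    overhead_ms: float
    total_ms: float
    widefield_xy: tuple[float, float]
    scan_xy: tuple[float, float]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class EventBundle:
    """Evidence saved for one triggered (or validated) event."""

    event: EventDetection
    scan_xy: tuple[float, float]
    widefield_buffer: np.ndarray          # (B, H, W), last frame = triggering frame
    scan_stack: np.ndarray | None         # None in validation/visualization mode
    timing: TimingLogEntry


@dataclass
class ExperimentRecord:
    """Full outcome of one run: bundles, the widefield record, and metadata."""

    config: AcquisitionConfig
    bundles: list[EventBundle] = field(default_factory=list)
    widefield_frames: list[np.ndarray] = field(default_factory=list)
    all_events: list[EventDetection] = field(default_factory=list)
    skipped_events: list[dict] = field(default_factory=list)
    preprocessed_maps: list[np.ndarray | None] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_triggers(self) -> int:
        return sum(1 for b in self.bundles if b.scan_stack is not None)

    def widefield_stack(self) -> np.ndarray:
        return np.stack(self.widefield_frames) if self.widefield_frames else np.empty((0, 0, 0))


def record_binary_mask(frames: Iterable[Frame | np.ndarray], threshold: float, expected_count: int = MASK_FRAME_COUNT) -> np.ndarray:
    """Average ``expected_count`` frames and threshold globally.

    The fixed default frame count follows the instrument's mask-recording
    procedure; overriding it is allowed but should be logged by the caller.
    """
    arrays = [f.data if isinstance(f, Frame) else np.asarray(f) for f in frames]
    if len(arrays) != expected_count:
        raise ValueError(
            f"mask recording expects exactly {expected_count} frames, got {len(arrays)}"
        )
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError("mask frames must share one shape")
    mean = np.mean(np.stack(arrays).astype(float), axis=0)
    return mean >= threshold


# ---------------------------------------------------------------------------
# frame sources


class SceneFrameSource:
    """Frame source backed by a rendered synthetic scene and its truth."""

    def __init__(self, timelapse: WidefieldTimelapse, truth: SceneGroundTruth, seed: int = 0):
        self.timelapse = timelapse
        self.truth = truth
        self.seed = seed
        self._scan_count = 0

    def frames(self) -> Iterator[Frame]:
        yield from self.timelapse.iter_frames()

    @property
    def field_shape(self) -> tuple[int, int]:
        return self.timelapse.frame_shape

    def scan(self, center_xy: tuple[float, float], size_um: float, pixel_nm: float, frames: int, frame_index: int) -> np.ndarray:
        self._scan_count += 1
        return render_scan_roi(
            self.truth,
            center=center_xy,
            size_um=size_um,
            pixel_nm=pixel_nm,
            frames=frames,
            frame_index=frame_index,
            seed=(self.seed * 100003 + self._scan_count) % (2**31),
        )


class TimelapseSource:
    """Replay of a stored timelapse; supports detection-only modes."""

    def __init__(self, timelapse: WidefieldTimelapse):
        self.timelapse = timelapse

    def frames(self) -> Iterator[Frame]:
        yield from self.timelapse.iter_frames()

    @property
    def field_shape(self) -> tuple[int, int]:
        return self.timelapse.frame_shape

    def scan(self, *args, **kwargs):
        raise RuntimeError(
            "a stored timelapse cannot be scanned; use validation/visualization "
            "mode (or the detect command) for archived data"
        )


# ---------------------------------------------------------------------------
# the loop


def _roi_fits(center: tuple[float, float], half_px: float, shape: tuple[int, int]) -> bool:
    h, w = shape
    cx, cy = center
    return half_px <= cx <= w - 1 - half_px and half_px <= cy <= h - 1 - half_px


def run_experiment(
    source,
    config: AcquisitionConfig,
    transform: PolynomialTransform2D,
    mask: np.ndarray | None = None,
) -> ExperimentRecord:
    """Run the closed acquisition loop over a frame source.

    ``mask`` restricts detection to the labeled specimen; when omitted and
    ``config.mask_threshold`` is set, the first ten frames of the stream
    are consumed to record it, otherwise an all-true mask is used.
    Deterministic given source and config.
    """
    if transform is None:
        raise ValueError("a calibrated transform is required to start a run")
    pipeline = get_pipeline(config.pipeline)
    params = config.params if config.params is not None else pipeline.params_type()

    frame_iter = source.frames()
    if mask is None and config.mask_threshold is not None:
        mask_frames = [next(frame_iter) for _ in range(MASK_FRAME_COUNT)]
        mask = record_binary_mask(mask_frames, config.mask_threshold)

    record = ExperimentRecord(config=config)
    record.metadata = {
        "pipeline": config.pipeline,
        "mode": config.mode,
        "params": dataclasses.asdict(params),
        "seed": config.seed,
        "buffer_length": config.buffer_length,
        "scan_size_um": config.scan_size_um,
        "scan_pixel_nm": config.scan_pixel_nm,
        "scan_frames": config.scan_frames,
    }

    state = pipeline.fresh_state()
    buffer: deque[np.ndarray] = deque(maxlen=config.buffer_length)
    triggers_fired: list[tuple[int, float, float]] = []  # (frame, x, y) for refractory

    for frame in frame_iter:
        if mask is None:
            mask = np.ones(frame.shape, dtype=bool)

        t0 = time.perf_counter()
        events, state = pipeline.process(frame, state, mask, params)
        analysis_ms = (time.perf_counter() - t0) * 1000.0

        buffer.append(np.asarray(frame.data))
        record.widefield_frames.append(np.asarray(frame.data))
        record.all_events.extend(events)
        if config.mode == "visualization":
            record.preprocessed_maps.append(state.last_preprocessed)

        if not events:
            continue

        # refractory suppression (off by default)
        if config.refractory_radius_px > 0:
            events = [
                e
                for e in events
                if not any(
                    frame.frame_index - tf <= config.refractory_frames
                    and np.hypot(e.x - tx, e.y - ty) <= config.refractory_radius_px
                    for tf, tx, ty in triggers_fired
                )
            ]
            if not events:
                continue

        half_px_wf = (config.scan_size_um * 1000.0 / frame.pixel_size) / 2.0

        chosen = None
        t1 = time.perf_counter()
        for event in events:  # already salience-descending; take the first that fits
            scan_xy = transform.transform_point(event.x, event.y)
            if _roi_fits(scan_xy, half_px_wf, source.field_shape):
                chosen = (event, scan_xy)
                break
            record.skipped_events.append(
                {
                    "frame_index": event.frame_index,
                    "x": event.x,
                    "y": event.y,
                    "reason": "scan ROI exceeds scan-space bounds",
                }
            )
        transform_ms = (time.perf_counter() - t1) * 1000.0
        if chosen is None:
            continue
        event, scan_xy = chosen

        scan_stack = None
        if config.mode in ("endless", "single_trigger"):
            scan_stack = source.scan(
                scan_xy,
                config.scan_size_um,
                config.scan_pixel_nm,
                config.scan_frames,
                frame_index=event.frame_index,
            )

        timing = TimingLogEntry(
            frame_index=event.frame_index,
            analysis_ms=analysis_ms,
            transform_ms=transform_ms,
            overhead_ms=0.0,
            total_ms=analysis_ms + transform_ms,
            widefield_xy=(event.x, event.y),
            scan_xy=scan_xy,
        )
        record.bundles.append(
            EventBundle(
                event=event,
                scan_xy=scan_xy,
                widefield_buffer=np.stack(list(buffer)),
                scan_stack=scan_stack,
                timing=timing,
            )
        )
        triggers_fired.append((event.frame_index, event.x, event.y))

        # the widefield stream was (conceptually) interrupted: frame-difference
        # state across the gap is invalid, so re-prime from scratch
        state = pipeline.fresh_state()

        if config.mode == "single_trigger":
            break

    return record


# ---------------------------------------------------------------------------
# logging


def write_log(record: ExperimentRecord, path: str | Path, wall_clock: bool = True) -> Path:
    """Write the run log as JSON lines: one run-metadata record, then events.

    Timings are hardware- and load-dependent metadata. With
    ``wall_clock=False`` the per-stage duration values are written as null
    (the fields stay present) so that reruns with the same seed produce
    bit-identical logs.
    """
    path = Path(path)
    lines = [
        json.dumps(
            {
                "type": "run",
                "schema_version": LOG_SCHEMA_VERSION,
                "metadata": record.metadata,
                "wall_clock": wall_clock,
                "n_widefield_frames": len(record.widefield_frames),
                "n_bundles": len(record.bundles),
                "n_triggers": record.n_triggers,
            }
        )
    ]
    for i, b in enumerate(record.bundles):
        timing = b.timing.to_dict()
        if not wall_clock:
            for key in ("analysis_ms", "transform_ms", "overhead_ms", "total_ms"):
                timing[key] = None
        lines.append(
            json.dumps(
                {
                    "type": "event",
                    "schema_version": LOG_SCHEMA_VERSION,
                    "event_index": i,
                    "pipeline": b.event.pipeline,
                    "frame_index": b.event.frame_index,
                    "widefield_xy": [b.event.x, b.event.y],
                    "scan_xy": list(b.scan_xy),
                    "salience": b.event.salience,
                    "timing": timing,
                    "triggered": b.scan_stack is not None,
                }
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_log(path: str | Path) -> dict:
    """Parse a run log; tolerant of truncation (valid records up to the cut)."""
    run = None
    events = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError:
            break  # truncated tail
        if rec.get("type") == "run":
            run = rec
        elif rec.get("type") == "event":
            events.append(rec)
    return {"run": run, "events": events}
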