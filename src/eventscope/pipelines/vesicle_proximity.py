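"""Proximity detection for diffusing vesicles that approach and merge.

Point-like endosomal vesicles are detected and linked frame to frame.
When two vesicles come within the diffraction limit of each other they
become unresolvable: one of the two tracks disappears while the other
survives right next to it. At every frame, each recently disappeared
track is evaluated against every surviving track with five Boolean
conditions; all five true emits one event at the disappeared track's last
position:

1. the track has disappeared (closed under the linking memory rule);
2. the surviving track's current position is within ``proximity_radius``
   of the disappeared track's last position;
3. the disappearance occurred at most ``lookback`` frames ago;
4. both tracks were present in at least a fraction ``presence_fraction``
   of the last ``window_frames`` frames;
5. at least one of the two tracks moved, over those frames, a net
   displacement (magnitude of the summed step vectors) of at least
   ``min_net_displacement`` and a path length (sum of step magnitudes)
   of at least ``min_path_length`` — i.e. it actually travelled rather
   than jittering in place.

Each (disappeared, surviving) track pair triggers at most once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..imaging_core import (
    Frame,
    GreedyLinker,
    find_local_maxima,
    gaussian_smooth,
    subtract_background,
)
from .base import EventDetection, PipelineState, _apply_border_exclusion, _check_inputs, register

__all__ = ["VesicleProximityParams", "vesicle_proximity"]


@dataclass(frozen=True)
class VesicleProximityParams:
    proximity_radius: float = 3.0       # px, condition 2
    lookback: int = 3                   # frames, condition 3
    window_frames: int = 10             # L, conditions 4-5
    presence_fraction: float = 0.7      # q, condition 4
    min_net_displacement: float = 5.0   # px, condition 5
    min_path_length: float = 5.0        # px, condition 5
    link_distance: float = 5.0
    memory: int = 0
    sigma: float = 1.0
    sigma_bg: float = 10.0
    window: int = 5
    low_threshold: float = 5.0
    high_threshold: float = 1e6
    border_px: int = 10

    def __post_init__(self) -> None:
        if min(self.proximity_radius, self.min_net_displacement, self.min_path_length) <= 0:
            raise ValueError("distance thresholds must be > 0")
        if not 0 < self.presence_fraction <= 1:
            raise ValueError("presence_fraction must be in (0, 1]")
        if self.window_frames < self.lookback:
            raise ValueError("window_frames must be >= lookback")
        if self.lookback < 1:
            raise ValueError("lookback must be >= 1")
        if self.link_distance <= 0 or self.memory < 0:
            raise ValueError("invalid link parameters")
        if self.sigma_bg <= self.sigma:
            raise ValueError("sigma_bg must exceed the smoothing sigma")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")


@dataclass
class _ProximityInfo:
    linker: GreedyLinker
    triggered_pairs: set[tuple[int, int]] = field(default_factory=set)


def _window_points(
    trace: list[tuple[int, float, float]], start: int, end: int
) -> list[tuple[int, float, float]]:
    return [p for p in trace if start <= p[0] <= end]


def _movement(points: list[tuple[int, float, float]]) -> tuple[float, float]:
    """(net displacement, path length) over an ordered position list."""
    if len(points) < 2:
        return 0.0, 0.0
    xy = np.array([(p[1], p[2]) for p in points])
    steps = np.diff(xy, axis=0)
    net = float(np.hypot(*(xy[-1] - xy[0])))
    path = float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))
    return net, path


@register("vesicle_proximity", VesicleProximityParams)
def vesicle_proximity(
    current: Frame,
    state: PipelineState,
    mask: np.ndarray,
    params: VesicleProximityParams,
):
    mask = _check_inputs(current, mask)
    info: _ProximityInfo = state.info or _ProximityInfo(
        linker=GreedyLinker(params.link_distance, params.memory)
    )

    pre = subtract_background(gaussian_smooth(current.data, params.sigma), params.sigma_bg)
    peaks = find_local_maxima(pre, params.window, mask)
    peaks = [p for p in peaks if params.low_threshold <= p.salience <= params.high_threshold]
    peaks = _apply_border_exclusion(peaks, current.shape, params.border_px)

    linker = info.linker
    assignment = linker.update(current.frame_index, [(p.x, p.y) for p in peaks])
    current_pos = {tid: (peaks[di].x, peaks[di].y) for di, tid in assignment.items()}

    f = current.frame_index
    w_start, w_end = f - params.window_frames + 1, f
    need = params.presence_fraction * params.window_frames

    events: list[EventDetection] = []
    for dead_id, last_frame in linker.closed.items():
        if f - last_frame > params.lookback:            # condition 3
            continue
        dead_trace = linker.tracks[dead_id]
        dead_last = dead_trace[-1]
        dead_window = _window_points(dead_trace, w_start, w_end)
        if len(dead_window) < need:                     # condition 4 (dead)
            continue
        dead_net, dead_path = _movement(dead_window)
        for surv_id, (sx, sy) in current_pos.items():
            if surv_id == dead_id or (dead_id, surv_id) in info.triggered_pairs:
                continue
            dist = float(np.hypot(sx - dead_last[1], sy - dead_last[2]))
            if dist > params.proximity_radius:          # condition 2
                continue
            surv_window = _window_points(linker.tracks[surv_id], w_start, w_end)
            if len(surv_window) < need:                 # condition 4 (survivor)
                continue
            surv_net, surv_path = _movement(surv_window)
            moved = (
                (dead_net >= params.min_net_displacement and dead_path >= params.min_path_length)
                or (surv_net >= params.min_net_displacement and surv_path >= params.min_path_length)
            )
            if not moved:                               # condition 5
                continue
            info.triggered_pairs.add((dead_id, surv_id))
            events.append(
                EventDetection(
                    frame_index=f,
                    x=dead_last[1],
                    y=dead_last[2],
                    salience=1.0 + max(dead_net, surv_net),
                    pipeline="vesicle_proximity",
                )
            )
    events.sort(key=lambda e: -e.salience)

    return events, PipelineState(
        pipeline=state.pipeline,
        previous=current,
        info=info,
        frames_processed=state.frames_processed + 1,
        last_preprocessed=pre,
    )
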