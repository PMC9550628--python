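"""Slow-rise detection for local protein recruitment (~1 s timescale).

Detects spots whose intensity climbs over several frames, as when dynamin
accumulates at a forming endocytic neck. Each frame is smoothed and
background-reduced, peaks are found and gated between a low and a high
intensity threshold (rejecting noise and large bright clusters), the mean
intensity in a small box around each surviving peak is extracted, and the
peak positions are linked into tracks. When a track has stayed detected
for exactly N frames, the ratio of its last to its first box intensity is
compared with the rise-ratio threshold rho; meeting it emits one event at
the track's last coordinate. A track triggers at most once, and
monotonicity of the rise is deliberately not required (noise-robust).
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

__all__ = ["DynaminRiseParams", "dynamin_rise"]


@dataclass(frozen=True)
class DynaminRiseParams:
    """Parameters of the rising-signal pipeline.

    n_frames is the trace length N required before the rise test;
    rise_ratio is the trigger threshold rho on I_last / I_first of the
    per-peak box intensities; low/high gate the preprocessed peak
    intensity (counts) against noise and large clusters; box_halfwidth a
    sets the (2a+1)^2 intensity-extraction box.
    """

    n_frames: int = 5
    rise_ratio: float = 2.0
    low_threshold: float = 5.0
    high_threshold: float = 1e6
    box_halfwidth: int = 2
    link_distance: float = 5.0
    memory: int = 0
    sigma: float = 1.0
    sigma_bg: float = 10.0
    window: int = 5
    border_px: int = 10

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.rise_ratio <= 1:
            raise ValueError("rise_ratio must be > 1")
        if not self.low_threshold < self.high_threshold:
            raise ValueError("low_threshold must be < high_threshold")
        if self.box_halfwidth < 0 or self.link_distance <= 0 or self.memory < 0:
            raise ValueError("invalid box/link parameters")
        if self.sigma_bg <= self.sigma:
            raise ValueError("sigma_bg must exceed the smoothing sigma")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")


@dataclass
class _RiseInfo:
    linker: GreedyLinker
    # track id -> list of (frame_index, x, y, box_intensity)
    traces: dict[int, list[tuple[int, float, float, float]]] = field(default_factory=dict)
    triggered: set[int] = field(default_factory=set)


def box_mean(image: np.ndarray, x: float, y: float, halfwidth: int) -> float:
    """Mean intensity in the (2a+1)^2 box around (x, y), clipped at edges."""
    h, w = image.shape
    r, c = int(round(y)), int(round(x))
    r0, r1 = max(0, r - halfwidth), min(h, r + halfwidth + 1)
    c0, c1 = max(0, c - halfwidth), min(w, c + halfwidth + 1)
    return float(image[r0:r1, c0:c1].mean())


@register("dynamin_rise", DynaminRiseParams)
def dynamin_rise(
    current: Frame,
    state: PipelineState,
    mask: np.ndarray,
    params: DynaminRiseParams,
):
    mask = _check_inputs(current, mask)

    info: _RiseInfo = state.info or _RiseInfo(
        linker=GreedyLinker(params.link_distance, params.memory)
    )

    pre = subtract_background(gaussian_smooth(current.data, params.sigma), params.sigma_bg)
    peaks = find_local_maxima(pre, params.window, mask)
    peaks = [p for p in peaks if params.low_threshold <= p.salience <= params.high_threshold]
    peaks = _apply_border_exclusion(peaks, current.shape, params.border_px)

    assignment = info.linker.update(current.frame_index, [(p.x, p.y) for p in peaks])

    events: list[EventDetection] = []
    for di, peak in enumerate(peaks):
        tid = assignment[di]
        intensity = box_mean(pre, peak.x, peak.y, params.box_halfwidth)
        trace = info.traces.setdefault(tid, [])
        trace.append((current.frame_index, peak.x, peak.y, intensity))
        if len(trace) == params.n_frames and tid not in info.triggered:
            info.triggered.add(tid)
            first_i = trace[0][3]
            last_i = trace[-1][3]
            if first_i > 0 and last_i / first_i >= params.rise_ratio:
                events.append(
                    EventDetection(
                        frame_index=current.frame_index,
                        x=trace[-1][1],
                        y=trace[-1][2],
                        salience=last_i / first_i,
                        pipeline="dynamin_rise",
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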