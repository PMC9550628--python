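"""Ratiometric spike detection for fast intensity transients.

Detects sudden local intensity increases — calcium-indicator spikes,
pHluorin unquenching on exocytosis — by peak detection in a smoothed
per-pixel ratio of the current to the previous frame. A ratio makes the
trigger threshold a unitless number > 1 independent of local brightness.

Two gates suppress division noise: the binary sample mask, and a minimum
raw-intensity gate, because where the denominator approaches the floor
epsilon the ratio is dominated by noise. Pixels failing either gate are
zeroed in the ratio map before peak finding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..imaging_core import Frame, find_local_maxima, gaussian_smooth, threshold_peaks
from .base import EventDetection, PipelineState, _apply_border_exclusion, _check_inputs, register

__all__ = ["RapidSpikesParams", "rapid_signal_spikes"]


@dataclass(frozen=True)
class RapidSpikesParams:
    """Parameters of the ratiometric spike pipeline.

    ratio_threshold is the unitless trigger level on the smoothed
    current/previous ratio (must exceed 1); min_intensity gates dark
    pixels in raw counts; border_px excludes peaks too close to the frame
    edge for a scan to fit; epsilon floors the division. ``mode`` selects
    the comparison map: ``"ratio"`` (default) or ``"normdiff"``,
    (current - previous) / max(previous, eps), thresholded at
    ratio_threshold - 1 for the same trigger semantics.
    """

    sigma: float = 1.5
    window: int = 7
    ratio_threshold: float = 1.5
    min_intensity: float = 20.0
    border_px: int = 10
    epsilon: float = 1.0
    mode: str = "ratio"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.ratio_threshold <= 1:
            raise ValueError("ratio_threshold must be > 1")
        if self.min_intensity < 0 or self.border_px < 0 or self.epsilon <= 0:
            raise ValueError("min_intensity, border_px >= 0 and epsilon > 0 required")
        if self.mode not in ("ratio", "normdiff"):
            raise ValueError("mode must be 'ratio' or 'normdiff'")


@register("rapid_signal_spikes", RapidSpikesParams)
def rapid_signal_spikes(
    current: Frame,
    state: PipelineState,
    mask: np.ndarray,
    params: RapidSpikesParams,
):
    """Process one frame; the first call only primes the previous-frame state."""
    mask = _check_inputs(current, mask)

    if state.previous is None:
        return [], replace_state(state, current, None)

    sm_cur = gaussian_smooth(current.data, params.sigma)
    sm_prev = gaussian_smooth(state.previous.data, params.sigma)

    if params.mode == "ratio":
        cmp_map = sm_cur / np.maximum(sm_prev, params.epsilon)
        threshold = params.ratio_threshold
    else:
        cmp_map = (sm_cur - sm_prev) / np.maximum(sm_prev, params.epsilon)
        threshold = params.ratio_threshold - 1.0

    cmp_map = np.where(mask, cmp_map, 0.0)
    cmp_map = np.where(current.data >= params.min_intensity, cmp_map, 0.0)

    peaks = find_local_maxima(cmp_map, params.window, mask)
    peaks = threshold_peaks(peaks, threshold)
    peaks = _apply_border_exclusion(peaks, current.shape, params.border_px)

    events = [
        EventDetection(
            frame_index=current.frame_index,
            x=p.x,
            y=p.y,
            salience=p.salience,
            pipeline="rapid_signal_spikes",
        )
        for p in peaks
    ]
    return events, replace_state(state, current, cmp_map)


def replace_state(state: PipelineState, current: Frame, cmp_map) -> PipelineState:
    return PipelineState(
        pipeline=state.pipeline,
        previous=current,
        info=None,
        frames_processed=state.frames_processed + 1,
        last_preprocessed=cmp_map,
    )
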