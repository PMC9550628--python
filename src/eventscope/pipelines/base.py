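"""The real-time pipeline interface contract.

Every detection pipeline is a pure function of (current frame, carry-over
state, binary sample mask, parameters) returning (events, updated state).
The state after frame k suffices to process frame k+1 with no other
history, so replaying a recorded timelapse frame-by-frame yields the same
event stream as a live run. A fresh state is valid input for the first
frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Callable

import numpy as np

from ..imaging_core import Frame, Peak

__all__ = ["EventDetection", "PipelineState", "Pipeline", "get_pipeline", "PIPELINES"]


@dataclass(frozen=True)
class EventDetection:
    """One detected event in widefield space."""

    frame_index: int
    x: float
    y: float
    salience: float
    pipeline: str

    def to_dict(self) -> dict:
        return {
            "frame_index": self.frame_index,
            "x": self.x,
            "y": self.y,
            "salience": self.salience,
            "pipeline": self.pipeline,
        }


@dataclass
class PipelineState:
    """Carry-over between frames: previous frame(s) plus pipeline-specific info."""

    pipeline: str
    previous: Frame | None = None
    info: Any = None
    frames_processed: int = 0
    last_preprocessed: np.ndarray | None = None


def _check_inputs(frame: Frame, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame shape {frame.shape}"
        )
    return mask


def _apply_border_exclusion(peaks: list[Peak], shape: tuple[int, int], border: int) -> list[Peak]:
    """Drop peaks closer than ``border`` px to a frame edge.

    The border is sized to half the triggered scan's footprint so that a
    scan centred on any surviving event always fits inside the field.
    """
    if border <= 0:
        return list(peaks)
    h, w = shape
    return [
        p
        for p in peaks
        if border <= p.x <= w - 1 - border and border <= p.y <= h - 1 - border
    ]


@dataclass(frozen=True)
class Pipeline:
    """A named pipeline: its process function plus its parameter type."""

    name: str
    func: Callable  # (Frame, PipelineState, mask, params) -> (events, state)
    params_type: type

    def fresh_state(self) -> PipelineState:
        return PipelineState(pipeline=self.name)

    def process(self, frame: Frame, state: PipelineState, mask, params):
        return self.func(frame, state, mask, params)


PIPELINES: dict[str, Pipeline] = {}


def register(name: str, params_type: type):
    def deco(func):
        PIPELINES[name] = Pipeline(name=name, func=func, params_type=params_type)
        return func

    return deco


def get_pipeline(name: str) -> Pipeline:
    try:
        return PIPELINES[name]
    except KeyError:
        raise KeyError(
            f"unknown pipeline {name!r}; available: {sorted(PIPELINES)}"
        ) from None
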