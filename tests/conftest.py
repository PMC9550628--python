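import numpy as np
import pytest

from eventscope.imaging_core import Frame
from eventscope.pipelines import get_pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def run_pipeline_over(timelapse, pipeline_name, params, mask=None):
    """Replay a timelapse frame-by-frame through a pipeline; collect events."""
    pipeline = get_pipeline(pipeline_name)
    state = pipeline.fresh_state()
    if mask is None:
        mask = np.ones(timelapse.frame_shape, dtype=bool)
    events = []
    for frame in timelapse.iter_frames():
        frame_events, state = pipeline.process(frame, state, mask, params)
        events.extend(frame_events)
    return events


def frames_from_arrays(arrays, pixel_size=100.0, period_ms=50.0):
    return [
        Frame(np.asarray(a, dtype=float), pixel_size, i, i * period_ms / 1000.0)
        for i, a in enumerate(arrays)
    ]
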