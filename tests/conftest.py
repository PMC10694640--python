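import numpy as np
import pytest

from stepfall import StepEventSeries, WalkingBout


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


def make_series(pid="P1", *segments, gap=3.0):
    """Concatenate step runs (each an array of intervals) separated by `gap` s."""
    t = 0.0
    ts = []
    for intervals in segments:
        times = t + np.concatenate([[0.0], np.cumsum(intervals)])
        ts.append(times)
        t = times[-1] + gap
    return StepEventSeries(pid, np.concatenate(ts) if ts else np.empty(0))


def uniform_bout(n_steps, dt=1.0, start=0.0, trim=5):
    return WalkingBout(start + dt * np.arange(n_steps), trim=trim)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def bout_factory():
    return uniform_bout
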