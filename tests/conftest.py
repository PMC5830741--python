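import numpy as np
import pytest

from stopchrono.synthdata import RaceParams, TraceParams, simulate_race_trials, synth_epochs
from stopchrono.task_behavior import TROI, StaircaseConfig
from stopchrono.trace_pipeline import ZTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_trace_params():
    """Short, low-rate epochs for fast filtering tests."""
    return TraceParams(fs=600.0, epoch_window=(-600.0, 800.0),
                       evoked_onset=260.0, induced_onset=260.0)


@pytest.fixture
def default_trials():
    return simulate_race_trials(RaceParams(), 120, staircase=StaircaseConfig(),
                                seed=11)


def make_ztrace(values, fs=1000.0, troi=(100.0, 300.0), t0=-500.0):
    """ZTrace on a 1 kHz grid starting at t0 ms, with the given tROI."""
    values = np.asarray(values, dtype=float)
    times = t0 + np.arange(values.size) * 1000.0 / fs
    return ZTrace(values=values, times=times, fs=fs, troi=TROI(*troi))
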