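import numpy as np
import pytest

from duovolt import synthgen as sg
from duovolt.preprocess import FrameStack
from duovolt.traces import Trace


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_stack(rng):
    data = rng.uniform(100, 200, size=(12, 8, 8))
    return FrameStack(data, frame_rate=30.0, channel="voltage", origin="test")


@pytest.fixture
def st_sensor():
    return sg.default_sensor("st")


@pytest.fixture
def nobleach_sensor():
    return sg.SensorModel(tau_bleach=np.inf)


@pytest.fixture
def tiny_scene():
    return sg.ScenePlan(
        cell_positions=np.array([[30.0, 30.0], [90.0, 90.0]]),
        soma_radius=8.0, neuropil_level=0.3, fov=(128.0, 128.0), pixel_size=2.0,
    )


def make_trace(y, rate=30.0, kind="dff", label="roi"):
    y = np.asarray(y, dtype=float)
    return Trace(np.arange(y.size) / rate, y, kind=kind, label=label)


@pytest.fixture
def flat_dff():
    return make_trace(np.zeros(300))
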