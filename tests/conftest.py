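import numpy as np
import pytest

from fishmot import motion, stimuli


@pytest.fixture(scope="session")
def arena() -> stimuli.ArenaSpec:
    return stimuli.ArenaSpec()


@pytest.fixture(scope="session")
def reference_motion_model() -> motion.MotionModel:
    """Fish-like motion law with a known ~0.2 waiting-time fraction."""
    from fishmot.pipeline import default_motion_model

    return default_motion_model()


def make_wait_dash_wait(frame_rate: float = 30.0, dash_speed: float = 300.0):
    """Trajectory constructed as WAIT(3 s at A) + dash(300 px) + WAIT(2 s at B)."""
    dash_dur = 300.0 / dash_speed
    t1 = np.arange(0, 3, 1 / frame_rate)
    t2 = np.arange(3, 3 + dash_dur, 1 / frame_rate)
    t3 = np.arange(3 + dash_dur, 5 + dash_dur + 1e-9, 1 / frame_rate)
    x = np.concatenate([np.full(len(t1), 100.0), 100 + (t2 - 3) * dash_speed, np.full(len(t3), 400.0)])
    t = np.concatenate([t1, t2, t3])
    from fishmot.trajectory import Trajectory

    return Trajectory("fish", t, x, np.zeros_like(x))
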