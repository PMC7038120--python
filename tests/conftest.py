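import numpy as np
import pandas as pd
import pytest

from patype.synthetic import (
    ProtocolSpec,
    SubjectProfile,
    default_protocols,
    generate_participant,
    generate_terrain,
)


@pytest.fixture(scope="session")
def terrain():
    return generate_terrain(seed=7)


@pytest.fixture(scope="session")
def profile():
    return SubjectProfile(subject_id="S01", gait_frequency=1.8, amplitude_scale=1.0, noise_sd=0.03)


@pytest.fixture(scope="session")
def participant(terrain, profile):
    """One participant over the two default protocols (short tasks)."""
    return generate_participant(profile, default_protocols(task_duration=40.0), terrain, seed=11)


@pytest.fixture(scope="session")
def small_participant(terrain, profile):
    """A quick two-task semi-structured participant for pipeline tests."""
    spec = ProtocolSpec(
        "semi_structured",
        [("walking_normal", 40.0, "leisure"), ("sitting", 40.0, "leisure")],
        gps_gap_rate=0.0,
    )
    return generate_participant(profile, [spec], terrain, seed=5)


def make_stream(position="chest", n=500, fs=50.0, values=None, seed=0):
    """Raw SensorStream helper: constant 1 g vertical unless values given."""
    from patype.core import SensorStream

    t = np.arange(n) / fs
    if values is None:
        arr = np.zeros((n, 3))
        arr[:, 1] = 1.0
    else:
        arr = np.asarray(values, float)
    return SensorStream(
        position=position,
        samples=pd.DataFrame({"t": t, "ax": arr[:, 0], "ay": arr[:, 1], "az": arr[:, 2]}),
    )
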