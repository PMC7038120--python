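"""Shared domain types and constants for the activity-type detection pipeline.

The study design places one tri-axial accelerometer (50 Hz) on each of five
body positions and a single 1 Hz GPS receiver on the participant.  Ten raw
activity tasks are grouped into seven target classes for classification.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Nominal accelerometer sampling rate, Hz.
ACCEL_RATE = 50.0

#: Nominal GPS fix rate, Hz.
GPS_RATE = 1.0

POSITIONS = ("chest", "left_hip", "right_hip", "pocket", "knee")

#: The seven grouped target classes.
GROUPED_CLASSES = (
    "walking",
    "non_level_walking",
    "running",
    "cycling",
    "sitting",
    "standing",
    "lying",
)

#: Raw annotated tasks -> grouped class.  Level walking at any speed is one
#: class; uphill/downhill/stairs walking forms the non-level class.
RAW_TO_GROUPED = {
    "walking_slow": "walking",
    "walking_normal": "walking",
    "walking_fast": "walking",
    "walking_uphill": "non_level_walking",
    "walking_downhill": "non_level_walking",
    "walking_upstairs": "non_level_walking",
    "walking_downstairs": "non_level_walking",
    "running": "running",
    "cycling": "cycling",
    "sitting": "sitting",
    "standing": "standing",
    "lying": "lying",
}

#: Grouped classes that involve locomotion (stop removal applies only here).
MOTION_CLASSES = frozenset({"walking", "non_level_walking", "running", "cycling"})

#: Device axis -> body direction, per sensor position.  All devices are
#: mounted with y vertical; the right-hip device is rotated so that x is
#: antero-posterior and z medio-lateral, the opposite of the other four.
AXIS_CONVENTION = {
    "chest": {"x": "medio_lateral", "y": "vertical", "z": "antero_posterior"},
    "left_hip": {"x": "medio_lateral", "y": "vertical", "z": "antero_posterior"},
    "pocket": {"x": "medio_lateral", "y": "vertical", "z": "antero_posterior"},
    "knee": {"x": "medio_lateral", "y": "vertical", "z": "antero_posterior"},
    "right_hip": {"x": "antero_posterior", "y": "vertical", "z": "medio_lateral"},
}


def axis_for(position: str, direction: str) -> str:
    """Return the device axis ('x'|'y'|'z') that records `direction` at `position`."""
    for axis, d in AXIS_CONVENTION[position].items():
        if d == direction:
            return axis
    raise KeyError(f"unknown body direction {direction!r}")


def grouped_label(raw: str) -> str:
    """Map a raw task label to its grouped class (identity for grouped labels)."""
    if raw in GROUPED_CLASSES:
        return raw
    try:
        return RAW_TO_GROUPED[raw]
    except KeyError:
        raise KeyError(f"unknown activity label {raw!r}") from None


@dataclass
class SensorStream:
    """One body position's timestamped tri-axial acceleration series.

    `samples` columns: t (seconds, float), ax, ay, az (g).  Annotation adds
    label / protocol / environment / task_id columns.
    """

    position: str
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ValueError(f"unknown sensor position {self.position!r}")

    def __len__(self) -> int:
        return len(self.samples)

    def magnitude(self) -> np.ndarray:
        """Total acceleration, the Euclidean norm of the three axes (g)."""
        a = self.samples[["ax", "ay", "az"]].to_numpy()
        return np.sqrt((a * a).sum(axis=1))

    def copy(self) -> "SensorStream":
        return replace(self, samples=self.samples.copy())


@dataclass
class Segment:
    """A fixed-duration, single-label window of one sensor's samples.

    The window is half-open: a sample at exactly t_end belongs to the next
    window.
    """

    position: str
    t_start: float
    t_end: float
    samples: pd.DataFrame
    label: str
    subject_id: str = ""
    protocol: str = ""
    environment: str = ""

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def array(self) -> np.ndarray:
        """(n, 3) acceleration array in g."""
        return self.samples[["ax", "ay", "az"]].to_numpy()
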