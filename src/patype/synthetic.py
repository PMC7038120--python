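"""Synthetic multi-sensor activity datasets.

Generates complete participants — five 50 Hz tri-axial accelerometer streams,
a 1 Hz GPS track, an annotation log and ground truth — with the statistical
structure the downstream pipeline assumes:

* postures produce quasi-static, orientation-specific gravity vectors;
* locomotion produces gravity plus harmonics of a subject-specific step
  frequency, amplitude-modulated by activity intensity and sensor position;
* every task is bracketed by standing-still / jump / standing-still markers
  (high-g transients) used for inter-stream synchronization;
* GPS follows road polylines at activity-specific speeds over a DEM, with
  configurable noise and dropout gaps; non-level walking follows a ramp road.

The signal model is sum-of-harmonics + gravity + Gaussian noise: it targets
the feature families the classifier uses (means, variances, dominant
frequencies), not biomechanical realism.  Inter-subject variation (step
frequency, amplitude, habitual lean, harmonic shape) makes subject-wise
generalization genuinely harder than segment-wise generalization.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .core import (
    ACCEL_RATE,
    GROUPED_CLASSES,
    MOTION_CLASSES,
    POSITIONS,
    RAW_TO_GROUPED,
    SensorStream,
    axis_for,
    grouped_label,
)

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

#: Marker block bracketing every task: 10 s of standing with one jump.
MARKER_S = 10.0
#: Jump transient: half-sine on the vertical axis, well above the >= 3 g
#: contract so it cannot be confused with vigorous locomotion.
JUMP_AMPLITUDE_G = 6.0
JUMP_WIDTH_S = 0.2
JUMP_OFFSET_S = 4.0  # position of the jump inside a marker block


@dataclass
class SubjectProfile:
    """Per-subject movement parameters.

    gait_frequency is the base step frequency in Hz (walking cadence);
    amplitude_scale multiplies all dynamic acceleration; preferred_speeds
    maps raw activity labels to ground speeds in m/s; noise_sd is the
    per-axis sensor noise in g.  ap_tilt (habitual antero-posterior lean, g
    projection) and harmonic_jitter shape each subject's gait waveform so
    that subjects differ in ways a cross-subject classifier must absorb.
    """

    subject_id: str
    gait_frequency: float = 1.8
    amplitude_scale: float = 1.0
    preferred_speeds: dict = field(default_factory=dict)
    noise_sd: float = 0.04
    ap_tilt: float = 0.0
    harmonic_jitter: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not 1.2 <= self.gait_frequency <= 2.4:
            raise ValueError("gait_frequency outside [1.2, 2.4] Hz")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not self.preferred_speeds:
            self.preferred_speeds = dict(_DEFAULT_SPEEDS)
        sp = self.preferred_speeds
        order = [sp["walking_slow"], sp["walking_normal"], sp["walking_fast"], sp["running"]]
        if sorted(order) != order or len(set(order)) != 4:
            raise ValueError("speeds must order slow walk < normal < fast < run")
        if sp["cycling"] <= sp["walking_fast"]:
            raise ValueError("cycling speed must exceed walking speeds")


_DEFAULT_SPEEDS = {
    "walking_slow": 0.9,
    "walking_normal": 1.4,
    "walking_fast": 1.9,
    "walking_uphill": 1.1,
    "walking_downhill": 1.2,
    "walking_upstairs": 0.6,
    "walking_downstairs": 0.7,
    "running": 2.8,
    "cycling": 5.5,
    "sitting": 0.0,
    "standing": 0.0,
    "lying": 0.0,
}


@dataclass
class ProtocolSpec:
    """One protocol's ordered task list and GPS degradation parameters.

    tasks: list of (raw activity, duration s, environment) where environment
    is 'urban' or 'leisure'.  Urban blocks get heavier GPS gap and noise
    rates (multipliers below), emulating street-canyon reception.
    """

    protocol: str  # 'semi_structured' | 'real_life'
    tasks: list
    gps_gap_rate: float = 0.2  # expected gaps per minute (leisure baseline)
    gps_noise_sd: float = 3.0  # m, horizontal (leisure baseline)
    urban_rate_factor: float = 3.0
    urban_noise_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.protocol not in ("semi_structured", "real_life"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        for activity, duration, env in self.tasks:
            grouped_label(activity)
            if duration <= 0:
                raise ValueError("task durations must be positive")
            if env not in ("urban", "leisure"):
                raise ValueError(f"unknown environment {env!r}")


@dataclass
class Terrain:
    """DEM raster plus road polylines, both in a planar local frame (m).

    dem[row, col] is elevation in m; row 0 is the *southern* edge (y = y0).
    roads are shapely LineStrings tagged 'flat' or 'ramp'.
    """

    dem: np.ndarray
    x0: float
    y0: float
    cell_size: float
    roads: list
    road_kinds: list

    @property
    def ncols(self) -> int:
        return self.dem.shape[1]

    @property
    def nrows(self) -> int:
        return self.dem.shape[0]

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (
            (x >= self.x0)
            & (x < self.x0 + self.ncols * self.cell_size)
            & (y >= self.y0)
            & (y < self.y0 + self.nrows * self.cell_size)
        )

    def elevation_at(self, x, y):
        """Nearest-cell DEM elevation at planar coordinates (vectorized)."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if not np.all(self.contains(x, y)):
            raise ValueError("coordinates outside DEM extent")
        col = np.clip(((x - self.x0) / self.cell_size).astype(int), 0, self.ncols - 1)
        row = np.clip(((y - self.y0) / self.cell_size).astype(int), 0, self.nrows - 1)
        return self.dem[row, col]

    def road(self, kind: str) -> LineString:
        for geom, k in zip(self.roads, self.road_kinds):
            if k == kind:
                return geom
        raise ValueError(f"terrain has no {kind!r} road")


@dataclass
class GapSpec:
    """GPS dropout specification: Poisson gaps of 2-6 s, or forced gaps."""

    rate_per_min: float = 0.0
    forced: list | None = None  # list of (start_s, length_s)


@dataclass
class ParticipantData:
    """Everything generated for one subject, plus ground truth."""

    subject_id: str
    profile: SubjectProfile
    streams: dict  # position -> SensorStream (device-clock timestamps)
    gps: pd.DataFrame
    annotations: pd.DataFrame
    terrain: Terrain
    clock_offsets: dict  # position -> true offset s (ground truth)
    jump_times: list  # true jump instants s (ground truth)


# ---------------------------------------------------------------------------
# Terrain
# ---------------------------------------------------------------------------

def generate_terrain(
    extent_m=(600.0, 600.0),
    slope_spec: str = "composite",
    grade_pct: float = 10.0,
    cell_size: float = 2.0,
    seed: int = 0,
) -> Terrain:
    """Build a DEM raster and road polylines.

    slope_spec: 'flat' (constant elevation), 'ramp' (whole extent slopes
    along +x at grade_pct), or 'composite' (flat western half, ramp rising
    eastward from mid-extent).  Roads: composite and flat terrains get a
    road on flat ground; ramp and composite terrains get a road running up
    the gradient.
    """
    width, height = extent_m
    if width <= 0 or height <= 0 or cell_size <= 0:
        raise ValueError("extent and cell size must be positive")
    if not 0.0 <= grade_pct <= 30.0:
        raise ValueError("grade must be within [0, 30] %")
    ncols = int(round(width / cell_size))
    nrows = int(round(height / cell_size))
    base = 400.0
    g = grade_pct / 100.0
    xc = (np.arange(ncols) + 0.5) * cell_size  # cell-center x
    if slope_spec == "flat":
        elev_profile = np.full(ncols, base)
    elif slope_spec == "ramp":
        elev_profile = base + g * xc
    elif slope_spec == "composite":
        ramp_from = width / 2.0
        elev_profile = base + g * np.maximum(0.0, xc - ramp_from)
    else:
        raise ValueError(f"unknown slope_spec {slope_spec!r}")
    dem = np.tile(elev_profile, (nrows, 1))

    roads: list = []
    kinds: list = []
    margin = 4 * cell_size
    y_flat = height * 0.25
    y_ramp = height * 0.6
    if slope_spec == "flat":
        roads.append(LineString([(margin, y_flat), (width - margin, y_flat)]))
        kinds.append("flat")
    elif slope_spec == "ramp":
        roads.append(LineString([(margin, y_ramp), (width - margin, y_ramp)]))
        kinds.append("ramp")
        # across-slope road: constant elevation, usable as level ground
        roads.append(LineString([(width * 0.5, margin), (width * 0.5, height - margin)]))
        kinds.append("flat")
    else:
        roads.append(LineString([(margin, y_flat), (width / 2.0 - margin, y_flat)]))
        kinds.append("flat")
        roads.append(LineString([(width / 2.0 + margin, y_ramp), (width - margin, y_ramp)]))
        kinds.append("ramp")
    return Terrain(dem=dem, x0=0.0, y0=0.0, cell_size=cell_size, roads=roads, road_kinds=kinds)


# ---------------------------------------------------------------------------
# Accelerometer signal model
# ---------------------------------------------------------------------------

#: Position-specific multiplier of gait amplitude: the knee sensor sees the
#: strongest swing-phase signal, the chest the most damped one.
GAIT_POSITION_FACTOR = {"chest": 0.8, "left_hip": 1.0, "right_hip": 1.0, "pocket": 1.1, "knee": 1.5}
#: Pedaling signature is strongest at knee and pocket (thigh), weak at torso.
CYCLE_POSITION_FACTOR = {"chest": 0.12, "left_hip": 0.25, "right_hip": 0.25, "pocket": 0.7, "knee": 1.0}

#: Gait activities: (step-frequency factor on gait_frequency, vertical
#: amplitude in g before subject/position scaling, antero-posterior lean in
#: g-projection).  Non-level variants overlap level walking in amplitude and
#: frequency; their main accelerometric cue is the modest incline lean,
#: which habitual inter-subject lean partially masks — GPS elevation is the
#: clean discriminator, by design.
_GAIT = {
    "walking_slow": (0.90, 0.22, 0.0),
    "walking_normal": (1.00, 0.35, 0.0),
    "walking_fast": (1.10, 0.50, 0.0),
    "walking_uphill": (0.97, 0.34, +0.087),
    "walking_downhill": (1.00, 0.33, -0.087),
    "walking_upstairs": (0.92, 0.36, +0.06),
    "walking_downstairs": (0.97, 0.34, -0.06),
    "running": (2.00, 0.75, 0.0),
}

#: Posture tilts (radians of the gravity vector toward the antero-posterior
#: axis) per sensor position.  Sitting rotates thigh-mounted devices (knee,
#: pocket) nearly horizontal; lying rotates every device.
_POSTURE_TILT = {
    "standing": {p: 0.0 for p in POSITIONS},
    "sitting": {"chest": 0.18, "left_hip": 0.26, "right_hip": 0.26, "pocket": 1.40, "knee": 1.40},
    "lying": {p: math.pi / 2 for p in POSITIONS},
}
#: Micro-motion (g): standing sway exceeds sitting fidgeting exceeds lying.
_POSTURE_MICRO = {"standing": 0.015, "sitting": 0.006, "lying": 0.003}

_GROUPED_CANONICAL = {"walking": "walking_normal", "non_level_walking": "walking_uphill"}


def _canonical_raw(activity: str) -> str:
    if activity in RAW_TO_GROUPED:
        return activity
    if activity in _GROUPED_CANONICAL:
        return _GROUPED_CANONICAL[activity]
    if activity in GROUPED_CLASSES:
        return activity  # running/cycling/postures are their own raw task
    raise KeyError(f"unknown activity label {activity!r}")


def simulate_accel_window(
    activity: str,
    duration: float,
    position: str,
    profile: SubjectProfile,
    seed,
) -> SensorStream:
    """Simulate one activity's 50 Hz tri-axial acceleration at one position.

    Deterministic given (activity, duration, position, profile, seed).
    Timestamps start at 0.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if position not in POSITIONS:
        raise KeyError(f"unknown sensor position {position!r}")
    act = _canonical_raw(activity)
    rng = np.random.default_rng(seed)
    n = int(round(duration * ACCEL_RATE))
    t = np.arange(n) / ACCEL_RATE
    acc = np.zeros((n, 3))
    cols = {"x": 0, "y": 1, "z": 2}
    iv = cols[axis_for(position, "vertical")]
    iml = cols[axis_for(position, "medio_lateral")]
    iap = cols[axis_for(position, "antero_posterior")]

    j2, j3 = profile.harmonic_jitter
    if act in _GAIT:
        ffac, amp, lean = _GAIT[act]
        f = ffac * profile.gait_frequency if act != "running" else 2.0 * profile.gait_frequency
        a = amp * profile.amplitude_scale * GAIT_POSITION_FACTOR[position]
        lean_total = lean + profile.ap_tilt
        ph = rng.uniform(0, 2 * np.pi, 4)
        acc[:, iv] = (
            math.cos(lean_total)
            + a * np.sin(2 * np.pi * f * t + ph[0])
            + a * 0.40 * (1 + 0.3 * j2) * np.sin(4 * np.pi * f * t + ph[1])
            + a * 0.15 * (1 + 0.3 * j3) * np.sin(6 * np.pi * f * t + ph[2])
        )
        acc[:, iml] = 0.30 * a * np.sin(np.pi * f * t + ph[3])  # stride-rate sway
        acc[:, iap] = math.sin(lean_total) + 0.40 * a * np.sin(2 * np.pi * f * t + ph[1])
    elif act == "cycling":
        cadence = 0.75 * profile.gait_frequency
        a = 0.5 * profile.amplitude_scale * CYCLE_POSITION_FACTOR[position]
        tilt = {"chest": 0.35, "left_hip": 0.50, "right_hip": 0.50, "pocket": 1.00, "knee": 1.00}[position]
        ph = rng.uniform(0, 2 * np.pi, 3)
        acc[:, iv] = math.cos(tilt) + 0.4 * a * np.sin(2 * np.pi * cadence * t + ph[0])
        acc[:, iap] = math.sin(tilt) + a * np.sin(2 * np.pi * cadence * t + ph[1])
        acc[:, iml] = 0.2 * a * np.sin(2 * np.pi * cadence * t + ph[2])
        acc += rng.normal(0.0, 0.08, acc.shape)  # road-surface vibration, all positions
    else:  # posture
        tilt = _POSTURE_TILT[act][position]
        lean = profile.ap_tilt if act == "standing" else 0.0
        acc[:, iv] = math.cos(tilt + lean)
        acc[:, iap] = math.sin(tilt + lean)
        micro = _POSTURE_MICRO[act]
        if act == "standing":
            ph = rng.uniform(0, 2 * np.pi)
            acc[:, iml] += micro * np.sin(2 * np.pi * 0.3 * t + ph)  # postural sway
        acc += rng.normal(0.0, micro * 0.5, acc.shape)
    acc += rng.normal(0.0, profile.noise_sd, acc.shape)

    df = pd.DataFrame({"t": t, "ax": acc[:, 0], "ay": acc[:, 1], "az": acc[:, 2]})
    return SensorStream(position=position, samples=df)


# ---------------------------------------------------------------------------
# GPS simulation
# ---------------------------------------------------------------------------

_RAMP_ACTIVITIES = {"walking_uphill", "walking_downhill", "walking_upstairs", "walking_downstairs"}
_DOWN_ACTIVITIES = {"walking_downhill", "walking_downstairs"}


def simulate_gps(
    schedule,
    terrain: Terrain,
    profile: SubjectProfile,
    gap_spec: GapSpec | None = None,
    seed=0,
    noise_sd: float = 3.0,
    urban_noise_factor: float = 2.0,
    urban_rate_factor: float = 3.0,
    speed_noise_sd: float = 0.15,
    altitude_noise_sd: float = 1.5,
) -> pd.DataFrame:
    """Simulate a 1 Hz GPS track for an ordered activity schedule.

    schedule: list of (activity, duration s) or (activity, duration s,
    environment).  Stationary activities jitter about the current anchor;
    locomotion follows the flat road (ping-pong at its ends); non-level
    walking traverses the ramp road (up or down as the activity dictates).
    Returns a DataFrame of fixes: t, x_m, y_m, altitude_m, speed_ms, hdop,
    nsat, environment — with gaps removed per gap_spec.
    """
    gap_spec = gap_spec or GapSpec()
    rng = np.random.default_rng(seed)
    flat = terrain.road("flat")
    try:
        ramp = terrain.road("ramp")
    except ValueError:
        ramp = None
    chain = {"flat": 0.0, "ramp": 0.0}
    direction = {"flat": 1.0, "ramp": 1.0}
    anchor = flat.interpolate(0.0)
    pos_x, pos_y, speeds, envs, times = [], [], [], [], []
    t = 0.0
    for entry in schedule:
        activity, dur = entry[0], entry[1]
        env = entry[2] if len(entry) > 2 else "leisure"
        act = _canonical_raw(activity)
        if dur < 1.0:
            raise ValueError("schedule durations must be >= 1 s")
        n = int(round(dur))
        speed = profile.preferred_speeds.get(act, 0.0)
        moving = grouped_label(act) in MOTION_CLASSES and speed > 0
        if moving:
            if act in _RAMP_ACTIVITIES:
                if ramp is None:
                    raise ValueError("schedule requires a ramp road but terrain has none")
                road, key = ramp, "ramp"
                need = speed * n
                if need > road.length:
                    raise ValueError("schedule path exceeds road network extent")
                # relocate along the ramp so the whole task runs one way
                if act in _DOWN_ACTIVITIES:
                    chain[key] = min(road.length, max(chain[key], need + 2.0))
                    direction[key] = -1.0
                else:
                    if chain[key] + need > road.length:
                        chain[key] = 0.0
                    direction[key] = 1.0
            else:
                road, key = flat, "flat"
            for _ in range(n):
                s = chain[key] + direction[key] * speed
                if s > road.length or s < 0.0:  # ping-pong reflection
                    direction[key] *= -1.0
                    s = chain[key] + direction[key] * speed
                chain[key] = min(max(s, 0.0), road.length)
                p = road.interpolate(chain[key])
                pos_x.append(p.x)
                pos_y.append(p.y)
                speeds.append(speed)
                envs.append(env)
                times.append(t)
                t += 1.0
            anchor = Point(pos_x[-1], pos_y[-1])
        else:
            for _ in range(n):
                pos_x.append(anchor.x)
                pos_y.append(anchor.y)
                speeds.append(0.0)
                envs.append(env)
                times.append(t)
                t += 1.0

    x = np.array(pos_x)
    y = np.array(pos_y)
    v = np.array(speeds)
    env_arr = np.array(envs)
    tt = np.array(times)
    nf = len(tt)
    sd = np.where(env_arr == "urban", noise_sd * urban_noise_factor, noise_sd)
    xr = x + rng.normal(0, 1, nf) * sd
    yr = y + rng.normal(0, 1, nf) * sd
    xr = np.clip(xr, terrain.x0, terrain.x0 + terrain.ncols * terrain.cell_size - 1e-6)
    yr = np.clip(yr, terrain.y0, terrain.y0 + terrain.nrows * terrain.cell_size - 1e-6)
    vr = np.maximum(0.0, v + rng.normal(0, speed_noise_sd, nf))
    alt = terrain.elevation_at(x, y) + rng.normal(0, altitude_noise_sd, nf)
    hdop = np.where(env_arr == "urban", 2.5, 1.2) + rng.uniform(0, 0.5, nf)
    nsat = rng.integers(6, 12, nf)

    keep = np.ones(nf, bool)
    if gap_spec.forced:
        for start, length in gap_spec.forced:
            keep &= ~((tt >= start) & (tt < start + length))
    elif gap_spec.rate_per_min > 0:
        rate = np.where(env_arr == "urban", gap_spec.rate_per_min * urban_rate_factor, gap_spec.rate_per_min)
        starts = np.flatnonzero(rng.random(nf) < rate / 60.0)
        for s0 in starts:
            length = int(rng.integers(2, 7))
            keep[s0 : s0 + length] = False

    return pd.DataFrame(
        {
            "t": tt,
            "x_m": xr,
            "y_m": yr,
            "altitude_m": alt,
            "speed_ms": vr,
            "hdop": hdop,
            "nsat": nsat,
            "environment": env_arr,
        }
    )[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Participant and cohort generation
# ---------------------------------------------------------------------------

def default_protocols(task_duration: float = 60.0) -> list:
    """The two default protocols: a scripted semi-structured session and a
    real-life session spanning urban and leisure environments."""
    semi = [
        ("lying", task_duration, "leisure"),
        ("sitting", task_duration, "leisure"),
        ("standing", task_duration, "leisure"),
        ("walking_slow", task_duration, "leisure"),
        ("walking_normal", task_duration, "leisure"),
        ("walking_fast", task_duration, "leisure"),
        ("walking_uphill", task_duration, "leisure"),
        ("walking_downhill", task_duration, "leisure"),
        ("running", task_duration, "leisure"),
        ("cycling", task_duration, "leisure"),
    ]
    real = [
        ("sitting", task_duration, "urban"),
        ("walking_normal", task_duration, "urban"),
        ("cycling", task_duration, "urban"),
        ("standing", task_duration, "urban"),
        ("walking_fast", task_duration, "urban"),
        ("running", task_duration, "leisure"),
        ("walking_uphill", task_duration, "leisure"),
        ("walking_downhill", task_duration, "leisure"),
        ("lying", task_duration, "leisure"),
        ("walking_slow", task_duration, "leisure"),
    ]
    return [
        ProtocolSpec("semi_structured", semi, gps_gap_rate=0.2, gps_noise_sd=3.0),
        ProtocolSpec("real_life", real, gps_gap_rate=0.5, gps_noise_sd=4.0),
    ]


def random_profile(subject_id: str, rng: np.random.Generator) -> SubjectProfile:
    """Draw a subject with realistic heterogeneity in gait and noise."""
    f0 = rng.uniform(1.4, 2.2)
    slow = rng.uniform(0.8, 1.0)
    normal = slow + rng.uniform(0.3, 0.5)
    fast = normal + rng.uniform(0.3, 0.5)
    speeds = {
        "walking_slow": slow,
        "walking_normal": normal,
        "walking_fast": fast,
        "walking_uphill": rng.uniform(0.9, 1.2),
        "walking_downhill": rng.uniform(1.0, 1.3),
        "walking_upstairs": rng.uniform(0.5, 0.7),
        "walking_downstairs": rng.uniform(0.6, 0.8),
        "running": rng.uniform(2.4, 3.2),
        "cycling": rng.uniform(4.5, 6.0),
        "sitting": 0.0,
        "standing": 0.0,
        "lying": 0.0,
    }
    return SubjectProfile(
        subject_id=subject_id,
        gait_frequency=f0,
        amplitude_scale=rng.uniform(0.75, 1.3),
        preferred_speeds=speeds,
        noise_sd=rng.uniform(0.03, 0.08),
        ap_tilt=float(np.clip(rng.normal(0.0, 0.08), -0.2, 0.2)),
        harmonic_jitter=(float(rng.uniform(-1, 1)), float(rng.uniform(-1, 1))),
    )


def generate_participant(
    profile: SubjectProfile,
    protocol_specs: list,
    terrain: Terrain,
    seed,
    max_clock_offset: float = 2.0,
) -> ParticipantData:
    """Generate one participant's full session across the given protocols.

    Each task is bracketed by a 10 s standing-still/jump/standing-still
    marker before and after; the annotation row spans marker start to marker
    end, so a 10 s trim recovers exactly the task interval.  Each non-chest
    stream's timestamps are shifted by an independent clock offset in
    +/- max_clock_offset s; the chest device shares the annotation clock and
    serves as the synchronization reference.
    """
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF])
    s_offsets, s_gps, s_blocks = ss.spawn(3)
    rng = np.random.default_rng(s_offsets)

    # --- timeline ----------------------------------------------------------
    blocks = []  # (activity, duration, env, is_marker)
    ann_rows = []
    jump_times = []
    t = 0.0
    for spec in protocol_specs:
        for activity, dur, env in spec.tasks:
            start = t
            blocks.append(("standing", MARKER_S, env, True))
            jump_times.append(t + JUMP_OFFSET_S)
            t += MARKER_S
            blocks.append((activity, float(dur), env, False))
            t += float(dur)
            blocks.append(("standing", MARKER_S, env, True))
            jump_times.append(t + JUMP_OFFSET_S)
            t += MARKER_S
            ann_rows.append(
                {
                    "activity": activity,
                    "start": start,
                    "end": t,
                    "protocol": spec.protocol,
                    "environment": env,
                }
            )
        blocks.append(("standing", 30.0, "leisure", False))  # inter-protocol rest
        t += 30.0

    # --- accelerometer streams --------------------------------------------
    offsets = {}
    streams = {}
    block_seeds = s_blocks.spawn(len(blocks) * len(POSITIONS))
    for ip, position in enumerate(POSITIONS):
        offsets[position] = 0.0 if position == "chest" else float(rng.uniform(-max_clock_offset, max_clock_offset))
        parts = []
        t0 = 0.0
        for ib, (activity, dur, _env, is_marker) in enumerate(blocks):
            win = simulate_accel_window(activity, dur, position, profile, block_seeds[ib * len(POSITIONS) + ip])
            df = win.samples
            if is_marker:
                iv = {"x": "ax", "y": "ay", "z": "az"}[axis_for(position, "vertical")]
                tb = df["t"].to_numpy()
                pulse = np.where(
                    (tb >= JUMP_OFFSET_S) & (tb < JUMP_OFFSET_S + JUMP_WIDTH_S),
                    JUMP_AMPLITUDE_G * np.sin(np.pi * (tb - JUMP_OFFSET_S) / JUMP_WIDTH_S),
                    0.0,
                )
                df[iv] = df[iv] + pulse
            df["t"] = df["t"] + t0
            t0 += dur
            parts.append(df)
        samples = pd.concat(parts, ignore_index=True)
        samples["t"] = samples["t"] + offsets[position]
        streams[position] = SensorStream(position=position, samples=samples)

    # --- GPS ---------------------------------------------------------------
    gps_parts = []
    gps_seeds = s_gps.spawn(len(protocol_specs))
    cursor = 0
    t_gps = 0.0
    for spec, gseed in zip(protocol_specs, gps_seeds):
        n_blocks = 3 * len(spec.tasks) + 1
        sched = [(a, d, e) for a, d, e, _m in blocks[cursor : cursor + n_blocks]]
        cursor += n_blocks
        track = simulate_gps(
            sched,
            terrain,
            profile,
            gap_spec=GapSpec(rate_per_min=spec.gps_gap_rate),
            seed=gseed,
            noise_sd=spec.gps_noise_sd,
            urban_noise_factor=spec.urban_noise_factor,
            urban_rate_factor=spec.urban_rate_factor,
        )
        track["t"] = track["t"] + t_gps
        t_gps += sum(d for _a, d, _e in sched)
        gps_parts.append(track)
    gps = pd.concat(gps_parts, ignore_index=True)

    annotations = pd.DataFrame(ann_rows)
    return ParticipantData(
        subject_id=profile.subject_id,
        profile=profile,
        streams=streams,
        gps=gps,
        annotations=annotations,
        terrain=terrain,
        clock_offsets=offsets,
        jump_times=jump_times,
    )


def generate_cohort(
    n_subjects: int = 10,
    seed: int = 0,
    terrain: Terrain | None = None,
    protocol_specs: list | None = None,
    task_duration: float = 60.0,
) -> list:
    """Generate a cohort of participants with independent subject profiles."""
    terrain = terrain if terrain is not None else generate_terrain(seed=seed)
    specs = protocol_specs if protocol_specs is not None else default_protocols(task_duration)
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 911])
    children = ss.spawn(n_subjects)
    out = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        profile = random_profile(f"S{i + 1:02d}", rng)
        out.append(generate_participant(profile, specs, terrain, seed=int(rng.integers(2**31))))
    return out
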