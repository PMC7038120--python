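"""Accelerometer preprocessing: cleaning, jump-based synchronization,
annotation with 10 s trimming, stop-move filtering, and overlapping
fixed-size windowing.

Five independently clocked devices record the same session; each task is
bracketed by standing-still/jump/standing-still markers whose high-g peaks
let the streams be aligned to a reference device by a constant time shift.
"""
from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import ACCEL_RATE, MOTION_CLASSES, Segment, SensorStream, grouped_label

log = logging.getLogger(__name__)

#: Default jump-peak detector settings.  The marker jumps are generated well
#: above 5 g total acceleration; 4 g keeps a wide margin above vigorous
#: locomotion (which can exceed 3 g at the knee) and below the jump peaks.
DEFAULT_JUMP_HEIGHT_G = 4.0
DEFAULT_JUMP_SEPARATION_S = 1.0

WINDOW_SIZES_S = (2, 5, 10, 20, 30, 60)


class SyncError(RuntimeError):
    """Raised when inter-stream synchronization cannot be established."""


def clean_stream(raw: SensorStream) -> SensorStream:
    """Drop rows with missing channels, sort by time, collapse duplicate
    timestamps to their first occurrence."""
    df = raw.samples.dropna(subset=["t", "ax", "ay", "az"])
    df = df.sort_values("t", kind="stable")
    df = df[~df["t"].duplicated(keep="first")].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"stream {raw.position}: no usable samples after cleaning")
    return replace(raw, samples=df)


def detect_jump_peaks(
    stream: SensorStream,
    min_height: float = DEFAULT_JUMP_HEIGHT_G,
    min_separation: float = DEFAULT_JUMP_SEPARATION_S,
) -> np.ndarray:
    """Timestamps of total-acceleration peaks above min_height (g), at least
    min_separation seconds apart, in time order."""
    t = stream.samples["t"].to_numpy()
    mag = stream.magnitude()
    if len(t) < 3:
        return np.array([])
    dt = np.median(np.diff(t))
    distance = max(1, int(round(min_separation / dt)))
    idx, _ = find_peaks(mag, height=min_height, distance=distance)
    return t[idx]


def synchronize(
    streams: dict,
    reference: str = "chest",
    min_height: float = DEFAULT_JUMP_HEIGHT_G,
    min_separation: float = DEFAULT_JUMP_SEPARATION_S,
) -> tuple[dict, dict]:
    """Align every stream to the reference stream via its marker-jump peaks.

    Each non-reference stream is shifted by a constant so that its jump
    peaks coincide with the reference's.  Returns (aligned streams, shifts).
    Raises SyncError (naming the stream) if a stream's peak count does not
    match the reference's.
    """
    if reference not in streams:
        raise KeyError(f"reference position {reference!r} not among streams")
    ref_peaks = detect_jump_peaks(streams[reference], min_height, min_separation)
    if len(ref_peaks) < 2:
        raise SyncError(f"reference stream {reference}: fewer than 2 jump peaks found")
    aligned = {}
    shifts = {}
    for position, stream in streams.items():
        peaks = detect_jump_peaks(stream, min_height, min_separation)
        if len(peaks) != len(ref_peaks):
            raise SyncError(
                f"stream {position}: {len(peaks)} jump peaks vs {len(ref_peaks)} "
                f"in reference {reference} — cannot match start/end jumps"
            )
        shift = float(np.median(ref_peaks - peaks))
        df = stream.samples.copy()
        df["t"] = df["t"] + shift
        aligned[position] = replace(stream, samples=df)
        shifts[position] = shift
    return aligned, shifts


def annotate_and_trim(stream: SensorStream, log_df: pd.DataFrame, trim: float = 10.0) -> SensorStream:
    """Label samples from the annotation log, trimming `trim` seconds off
    both ends of every row (the jump-marker period); unlabeled samples are
    dropped.  Raw activity labels are mapped to the seven grouped classes.

    Rows shorter than 2*trim cannot contain any usable data and are skipped
    with a warning.
    """
    df = stream.samples
    t = df["t"].to_numpy()
    label = np.full(len(df), None, dtype=object)
    protocol = np.full(len(df), None, dtype=object)
    environment = np.full(len(df), None, dtype=object)
    task_id = np.full(len(df), -1)
    for i, row in log_df.reset_index(drop=True).iterrows():
        if row["end"] - row["start"] <= 2 * trim:
            log.warning(
                "annotation row %d (%s, %.0f s) shorter than 2x trim — skipped",
                i, row["activity"], row["end"] - row["start"],
            )
            continue
        # epsilon guards against sub-ulp timestamp drift from the shift-back
        mask = (t >= row["start"] + trim - 1e-6) & (t < row["end"] - trim - 1e-6)
        label[mask] = grouped_label(row["activity"])
        protocol[mask] = row.get("protocol", "")
        environment[mask] = row.get("environment", "")
        task_id[mask] = i
    out = df.copy()
    out["label"] = label
    out["protocol"] = protocol
    out["environment"] = environment
    out["task_id"] = task_id
    out = out[out["label"].notna()].reset_index(drop=True)
    return replace(stream, samples=out)


def detect_stops(
    stream: SensorStream,
    window: float = 1.0,
    threshold: float = 0.05,
    min_stop: float = 1.0,
) -> list:
    """Maximal intervals within motion-labeled spans where the rolling
    standard deviation of total acceleration stays below `threshold` (g)
    for at least `min_stop` seconds.  Returns [(t_start, t_end), ...]."""
    df = stream.samples
    if df.empty:
        return []
    t = df["t"].to_numpy()
    mag = stream.magnitude()
    w = max(2, int(round(window * ACCEL_RATE)))
    rolling_sd = pd.Series(mag).rolling(w, center=True, min_periods=2).std().to_numpy()
    motion = df["label"].isin(MOTION_CLASSES).to_numpy() if "label" in df else np.ones(len(df), bool)
    quiet = (rolling_sd < threshold) & motion
    intervals = []
    start = None
    for i, q in enumerate(quiet):
        if q and start is None:
            start = i
        elif not q and start is not None:
            if t[i - 1] - t[start] >= min_stop:
                intervals.append((float(t[start]), float(t[i - 1])))
            start = None
    if start is not None and t[-1] - t[start] >= min_stop:
        intervals.append((float(t[start]), float(t[-1])))
    return intervals


def remove_stops(stream: SensorStream, stops: list) -> SensorStream:
    """Remove stop-interval samples from motion-labeled spans only."""
    if not stops:
        return stream
    df = stream.samples
    t = df["t"].to_numpy()
    in_stop = np.zeros(len(df), bool)
    for t0, t1 in stops:
        in_stop |= (t >= t0) & (t <= t1)
    motion = df["label"].isin(MOTION_CLASSES).to_numpy() if "label" in df else np.ones(len(df), bool)
    keep = ~(in_stop & motion)
    return replace(stream, samples=df[keep].reset_index(drop=True))


def segment(
    stream: SensorStream,
    window_s: float,
    overlap_fraction: float = 0.5,
    subject_id: str = "",
    completeness: float = 0.95,
) -> list:
    """Cut a labeled stream into overlapping fixed-size windows.

    Windows advance by window_s * (1 - overlap_fraction) within each
    annotated task span.  A window is emitted only if all its samples share
    one label and it holds at least `completeness` of the nominal
    50 * window_s samples.  Window intervals are half-open [t0, t0+w).
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    df = stream.samples
    if "label" not in df or df.empty:
        return []
    step = window_s * (1.0 - overlap_fraction)
    min_samples = completeness * ACCEL_RATE * window_s
    segments = []
    for _task, span in df.groupby("task_id", sort=True):
        t = span["t"].to_numpy()
        span_start, span_end = t[0], t[-1] + 1.0 / ACCEL_RATE
        if span_end - span_start < window_s - 1e-9:
            log.info("labeled span of %.1f s shorter than %.0f s window — no segments",
                     span_end - span_start, window_s)
            continue
        start = span_start
        while start + window_s <= span_end + 1e-9:
            sel = span[(t >= start - 1e-12) & (t < start + window_s - 1e-12)]
            start_next = start + step
            if len(sel) >= min_samples and sel["label"].nunique() == 1:
                segments.append(
                    Segment(
                        position=stream.position,
                        t_start=float(start),
                        t_end=float(start + window_s),
                        samples=sel[["t", "ax", "ay", "az"]].reset_index(drop=True),
                        label=sel["label"].iloc[0],
                        subject_id=subject_id,
                        protocol=sel["protocol"].iloc[0],
                        environment=sel["environment"].iloc[0],
                    )
                )
            start = start_next
    return segments
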