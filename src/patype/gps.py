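"""GPS track preprocessing and per-segment GPS features.

A 1 Hz track is cleaned, gap-filled by linear interpolation, snapped to the
road network (point-to-curve geometric map matching), enriched with DEM
elevation at each fix, and smoothed; each accelerometer window then gets a
mean speed (m/s) and an elevation difference (last minus first smoothed
elevation, m — uphill positive).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .synthetic import Terrain

log = logging.getLogger(__name__)

DEFAULT_MAX_SNAP_M = 20.0
DEFAULT_MAX_GAP_S = 60.0
DEFAULT_SMOOTH_HALF_WIDTH = 2


@dataclass
class GpsSegmentFeatures:
    """GPS features for one accelerometer window [t_start, t_end)."""

    t_start: float
    t_end: float
    mean_speed: float | None
    elevation_diff: float | None
    gps_missing: bool = False


def clean_gps(track: pd.DataFrame) -> pd.DataFrame:
    """Remove incomplete fixes and duplicate timestamps; sort by time."""
    df = track.dropna(subset=["t", "x_m", "y_m", "speed_ms"])
    df = df.sort_values("t", kind="stable")
    df = df[~df["t"].duplicated(keep="first")].reset_index(drop=True)
    if df.empty:
        raise ValueError("no usable GPS fixes after cleaning")
    return df


def interpolate_gaps(track: pd.DataFrame, max_gap: float = DEFAULT_MAX_GAP_S) -> pd.DataFrame:
    """Fill every integer second between first and last fix by linear
    interpolation of position against time.

    Inserted fixes get speed interpolated linearly, altitude left null (it
    is recovered from the DEM afterwards), and flag interpolated=True.
    Gaps longer than max_gap are left unfilled (their windows are excluded
    downstream).
    """
    df = track.copy().reset_index(drop=True)
    df["interpolated"] = df.get("interpolated", False)
    t = df["t"].to_numpy()
    rows = [df]
    for i in range(len(t) - 1):
        gap = t[i + 1] - t[i]
        if gap <= 1.0:
            continue
        if gap > max_gap:
            log.warning("GPS gap of %.0f s exceeds max_gap %.0f s — left unfilled", gap, max_gap)
            continue
        tt = np.arange(np.floor(t[i]) + 1.0, t[i + 1] - 1e-9)
        tt = tt[tt > t[i]]
        frac = (tt - t[i]) / gap
        ins = pd.DataFrame({"t": tt})
        for col in ("x_m", "y_m", "speed_ms"):
            ins[col] = df[col].iloc[i] + frac * (df[col].iloc[i + 1] - df[col].iloc[i])
        ins["altitude_m"] = np.nan
        for col in df.columns:
            if col not in ins.columns:
                ins[col] = df[col].iloc[i]
        ins["interpolated"] = True
        rows.append(ins)
    out = pd.concat(rows, ignore_index=True).sort_values("t", kind="stable").reset_index(drop=True)
    return out


def map_match(
    track: pd.DataFrame,
    roads: list,
    max_snap: float = DEFAULT_MAX_SNAP_M,
    motion_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Point-to-curve map matching: snap each motion fix to the nearest
    point on the nearest road polyline if within max_snap meters.

    Stationary fixes (motion_mask False) are never snapped.  Fixes farther
    than max_snap from every road keep their coordinates and are flagged
    matched=False.
    """
    df = track.copy().reset_index(drop=True)
    if not roads:
        log.warning("empty road set — map matching skipped")
        df["matched"] = False
        return df
    if motion_mask is None:
        motion_mask = np.ones(len(df), bool)
    motion_mask = np.asarray(motion_mask, bool)
    pts = shapely.points(df["x_m"].to_numpy(), df["y_m"].to_numpy())
    dists = np.stack([shapely.distance(pts, road) for road in roads])
    nearest_road = dists.argmin(axis=0)
    nearest_dist = dists.min(axis=0)
    snap = motion_mask & (nearest_dist <= max_snap)
    matched = np.zeros(len(df), bool)
    x = df["x_m"].to_numpy().copy()
    y = df["y_m"].to_numpy().copy()
    for ri, road in enumerate(roads):
        idx = np.flatnonzero(snap & (nearest_road == ri))
        if idx.size == 0:
            continue
        projected = shapely.line_interpolate_point(road, shapely.line_locate_point(road, pts[idx]))
        x[idx] = shapely.get_x(projected)
        y[idx] = shapely.get_y(projected)
        matched[idx] = True
    df["x_m"] = x
    df["y_m"] = y
    df["matched"] = matched
    return df


def sample_dem(track: pd.DataFrame, terrain: Terrain) -> pd.DataFrame:
    """Attach dem_elevation to every fix (nearest-cell rule).

    Raises if any fix lies outside the DEM extent, naming the first
    offending fix.
    """
    df = track.copy()
    inside = terrain.contains(df["x_m"].to_numpy(), df["y_m"].to_numpy())
    if not np.all(inside):
        i = int(np.flatnonzero(~inside)[0])
        raise ValueError(
            f"GPS fix at t={df['t'].iloc[i]:.0f} s "
            f"({df['x_m'].iloc[i]:.1f}, {df['y_m'].iloc[i]:.1f}) outside DEM extent"
        )
    df["dem_elevation"] = terrain.elevation_at(df["x_m"].to_numpy(), df["y_m"].to_numpy())
    return df


def smooth_elevation(series, half_width: int = DEFAULT_SMOOTH_HALF_WIDTH) -> np.ndarray:
    """Triangular-weighted moving average of window 2*half_width + 1,
    renormalized at the edges; output length equals input length."""
    x = np.asarray(series, float)
    if half_width <= 0 or len(x) == 0:
        return x.copy()
    w = np.concatenate([np.arange(1, half_width + 2), np.arange(half_width, 0, -1)]).astype(float)
    num = np.convolve(x, w, mode="same")
    den = np.convolve(np.ones_like(x), w, mode="same")
    return num / den


def segment_gps_features(
    track: pd.DataFrame,
    windows,
    min_coverage: float = 0.5,
    elevation_col: str = "dem_elevation_smooth",
) -> list:
    """Mean speed and elevation difference per accelerometer window.

    elevation_diff = smoothed elevation at the last fix minus at the first
    fix in [t_start, t_end) — uphill positive.  Windows with less than
    min_coverage GPS coverage yield null features and gps_missing=True.
    """
    t = track["t"].to_numpy()
    out = []
    for t0, t1 in windows:
        mask = (t >= t0) & (t < t1)
        n = int(mask.sum())
        if n < min_coverage * (t1 - t0):
            out.append(GpsSegmentFeatures(t0, t1, None, None, gps_missing=True))
            continue
        sel = track[mask]
        elev = sel[elevation_col].to_numpy()
        out.append(
            GpsSegmentFeatures(
                t0,
                t1,
                mean_speed=float(sel["speed_ms"].mean()),
                elevation_diff=float(elev[-1] - elev[0]),
            )
        )
    return out


def preprocess_track(
    track: pd.DataFrame,
    terrain: Terrain,
    motion_mask_fn=None,
    max_snap: float = DEFAULT_MAX_SNAP_M,
    max_gap: float = DEFAULT_MAX_GAP_S,
    half_width: int = DEFAULT_SMOOTH_HALF_WIDTH,
) -> pd.DataFrame:
    """Full GPS chain: clean -> interpolate -> map-match -> DEM -> smooth.

    motion_mask_fn(t_array) -> bool array marks fixes recorded during
    motion activities (only those are snapped to roads).
    """
    df = clean_gps(track)
    df = interpolate_gaps(df, max_gap=max_gap)
    mask = motion_mask_fn(df["t"].to_numpy()) if motion_mask_fn is not None else None
    df = map_match(df, terrain.roads, max_snap=max_snap, motion_mask=mask)
    df = sample_dem(df, terrain)
    df["dem_elevation_smooth"] = smooth_elevation(df["dem_elevation"].to_numpy(), half_width)
    return df
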