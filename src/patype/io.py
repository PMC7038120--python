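"""File formats, configuration, and the local coordinate shim.

CSV dialects
    sensor:     timestamp_iso,ax_g,ay_g,az_g
    gps:        timestamp_iso,x_m,y_m,lat,lon,altitude_m,speed_ms,hdop,nsat
    annotation: activity,start_iso,end_iso,protocol,environment

Terrain is an ESRI ASCII grid (a 6-line header plus rows of elevations,
north row first) and roads a GeoJSON LineString FeatureCollection.

All synthetic geometry lives in a planar local frame in meters; lat/lon
columns are produced by a fixed equirectangular projection about a
reference origin, purely for format compatibility.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import LineString, mapping, shape

from .core import POSITIONS, SensorStream
from .synthetic import ParticipantData, SubjectProfile, Terrain

#: Session epoch: internal float seconds count from this instant.
EPOCH = pd.Timestamp("2020-01-21T08:00:00Z")

#: Reference origin of the local planar frame (Zurich).
ORIGIN_LAT = 47.3769
ORIGIN_LON = 8.5417
_M_PER_DEG_LAT = 111_320.0


def xy_to_latlon(x, y):
    """Fixed local equirectangular projection: meters -> (lat, lon)."""
    lat = ORIGIN_LAT + np.asarray(y, float) / _M_PER_DEG_LAT
    lon = ORIGIN_LON + np.asarray(x, float) / (_M_PER_DEG_LAT * math.cos(math.radians(ORIGIN_LAT)))
    return lat, lon


def latlon_to_xy(lat, lon):
    y = (np.asarray(lat, float) - ORIGIN_LAT) * _M_PER_DEG_LAT
    x = (np.asarray(lon, float) - ORIGIN_LON) * _M_PER_DEG_LAT * math.cos(math.radians(ORIGIN_LAT))
    return x, y


def seconds_to_iso(t) -> pd.Series:
    ts = EPOCH + pd.to_timedelta(np.asarray(t, float), unit="s")
    return pd.Series(ts).dt.strftime("%Y-%m-%dT%H:%M:%S.%f").str[:-3] + "Z"


def iso_to_seconds(iso) -> np.ndarray:
    ts = pd.to_datetime(iso, utc=True, format="ISO8601")
    return ((ts - EPOCH) / pd.Timedelta(seconds=1)).to_numpy()


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")


def _report_bad_rows(df: pd.DataFrame, numeric_cols, path) -> None:
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            lines = (np.flatnonzero(bad) + 2).tolist()  # +2: header + 1-based
            raise ValueError(f"{path}: non-numeric {col!r} at line(s) {lines[:5]}")
        df[col] = coerced


# --- sensor streams --------------------------------------------------------

def write_sensor_csv(stream: SensorStream, path) -> None:
    out = pd.DataFrame(
        {
            "timestamp_iso": seconds_to_iso(stream.samples["t"]),
            "ax_g": stream.samples["ax"].round(6),
            "ay_g": stream.samples["ay"].round(6),
            "az_g": stream.samples["az"].round(6),
        }
    )
    out.to_csv(path, index=False)


def read_sensor_csv(path, position: str) -> SensorStream:
    df = pd.read_csv(path)
    _require_columns(df, ("timestamp_iso", "ax_g", "ay_g", "az_g"), path)
    _report_bad_rows(df, ("ax_g", "ay_g", "az_g"), path)
    samples = pd.DataFrame(
        {"t": iso_to_seconds(df["timestamp_iso"]), "ax": df["ax_g"], "ay": df["ay_g"], "az": df["az_g"]}
    )
    return SensorStream(position=position, samples=samples)


# --- GPS -------------------------------------------------------------------

def write_gps_csv(track: pd.DataFrame, path) -> None:
    lat, lon = xy_to_latlon(track["x_m"], track["y_m"])
    out = pd.DataFrame(
        {
            "timestamp_iso": seconds_to_iso(track["t"]),
            "x_m": track["x_m"].round(3),
            "y_m": track["y_m"].round(3),
            "lat": np.round(lat, 8),
            "lon": np.round(lon, 8),
            "altitude_m": track["altitude_m"].round(2),
            "speed_ms": track["speed_ms"].round(3),
            "hdop": track["hdop"].round(2),
            "nsat": track["nsat"],
        }
    )
    out.to_csv(path, index=False)


def read_gps_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("timestamp_iso", "x_m", "y_m", "altitude_m", "speed_ms"), path)
    _report_bad_rows(df, ("x_m", "y_m", "altitude_m", "speed_ms"), path)
    df["t"] = iso_to_seconds(df["timestamp_iso"])
    return df.drop(columns=["timestamp_iso"])


# --- annotations -----------------------------------------------------------

def write_annotation_csv(annotations: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "activity": annotations["activity"],
            "start_iso": seconds_to_iso(annotations["start"]),
            "end_iso": seconds_to_iso(annotations["end"]),
            "protocol": annotations["protocol"],
            "environment": annotations["environment"],
        }
    )
    out.to_csv(path, index=False)


def read_annotation_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("activity", "start_iso", "end_iso", "protocol", "environment"), path)
    return pd.DataFrame(
        {
            "activity": df["activity"],
            "start": iso_to_seconds(df["start_iso"]),
            "end": iso_to_seconds(df["end_iso"]),
            "protocol": df["protocol"],
            "environment": df["environment"],
        }
    )


# --- terrain ---------------------------------------------------------------

def write_ascii_grid(terrain: Terrain, path, nodata: float = -9999.0) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {terrain.ncols}\n")
        fh.write(f"nrows {terrain.nrows}\n")
        fh.write(f"xllcorner {terrain.x0}\n")
        fh.write(f"yllcorner {terrain.y0}\n")
        fh.write(f"cellsize {terrain.cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        # ESRI convention: first data row is the northern edge
        np.savetxt(fh, terrain.dem[::-1], fmt="%.3f")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid -> (dem south-row-first, x0, y0, cell, nodata)."""
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        dem = np.loadtxt(fh)
    dem = dem.reshape(int(header["nrows"]), int(header["ncols"]))[::-1]
    nodata = header.get("nodata_value", -9999.0)
    dem = np.where(dem == nodata, np.nan, dem)
    return dem, header["xllcorner"], header["yllcorner"], header["cellsize"], nodata


def write_geojson_roads(terrain: Terrain, path) -> None:
    features = [
        {"type": "Feature", "properties": {"kind": kind}, "geometry": mapping(geom)}
        for geom, kind in zip(terrain.roads, terrain.road_kinds)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson_roads(path):
    with open(path) as fh:
        collection = json.load(fh)
    geoms, kinds = [], []
    for feature in collection["features"]:
        geom = shape(feature["geometry"])
        if not isinstance(geom, LineString):
            raise ValueError(f"{path}: roads must be LineStrings, got {geom.geom_type}")
        geoms.append(geom)
        kinds.append(feature.get("properties", {}).get("kind", "flat"))
    return geoms, kinds


def write_terrain(terrain: Terrain, outdir) -> None:
    outdir = Path(outdir)
    write_ascii_grid(terrain, outdir / "dem.asc")
    write_geojson_roads(terrain, outdir / "roads.geojson")


def read_terrain(outdir) -> Terrain:
    outdir = Path(outdir)
    dem, x0, y0, cell, _ = read_ascii_grid(outdir / "dem.asc")
    roads, kinds = read_geojson_roads(outdir / "roads.geojson")
    return Terrain(dem=dem, x0=x0, y0=y0, cell_size=cell, roads=roads, road_kinds=kinds)


# --- participants ----------------------------------------------------------

def save_participant(p: ParticipantData, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for pos, stream in p.streams.items():
        write_sensor_csv(stream, outdir / f"accel_{pos}.csv")
    write_gps_csv(p.gps, outdir / "gps.csv")
    write_annotation_csv(p.annotations, outdir / "annotations.csv")
    with open(outdir / "profile.json", "w") as fh:
        json.dump(dataclasses.asdict(p.profile), fh, indent=1)


def load_participant(outdir, terrain: Terrain) -> ParticipantData:
    outdir = Path(outdir)
    streams = {pos: read_sensor_csv(outdir / f"accel_{pos}.csv", pos) for pos in POSITIONS}
    gps = read_gps_csv(outdir / "gps.csv")
    annotations = read_annotation_csv(outdir / "annotations.csv")
    with open(outdir / "profile.json") as fh:
        prof = json.load(fh)
    prof["harmonic_jitter"] = tuple(prof.get("harmonic_jitter", (0.0, 0.0)))
    profile = SubjectProfile(**prof)
    return ParticipantData(
        subject_id=profile.subject_id,
        profile=profile,
        streams=streams,
        gps=gps,
        annotations=annotations,
        terrain=terrain,
        clock_offsets={},
        jump_times=[],
    )


# --- reports & config ------------------------------------------------------

def write_report(report, path, fmt: str = "json") -> None:
    path = Path(path)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
    elif fmt == "csv":
        cm = pd.DataFrame(report.confusion.counts, index=report.confusion.classes,
                          columns=report.confusion.classes)
        cm.to_csv(path)
    else:
        raise ValueError(f"unknown report format {fmt!r}")


@dataclass
class RunConfig:
    """Validated run configuration; persisted alongside outputs."""

    n_subjects: int = 10
    seed: int = 0
    window_s: float = 10.0
    overlap: float = 0.5
    task_duration: float = 60.0
    trim: float = 10.0
    jump_height: float = 4.0
    stop_threshold: float = 0.05
    max_snap: float = 20.0
    smooth_half_width: int = 2
    scenario: str = "S2_combined"
    scope: str = "general"
    feature_set: str = "acc"
    n_trees: int = 500
    gps_missing_policy: str = "exclude"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.window_s <= 0 or self.task_duration <= 0 or self.trim < 0:
            raise ValueError("window_s/task_duration must be positive, trim non-negative")
        if self.scope != "general" and self.scope not in POSITIONS:
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.feature_set not in ("acc", "acc_gps"):
            raise ValueError(f"unknown feature_set {self.feature_set!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
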