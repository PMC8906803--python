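"""Trajectory data model and file I/O.

All positions are stored in millimetres, time in seconds, and velocities are
reported downstream in cm/s (the convention of the biplanar X-ray literature).
Missing samples are explicit NaNs — zero is a legal coordinate (the
esophagus-entrance origin of the anatomical frame), so it can never double as
a sentinel.

The on-disk dialect ``xmalab_3d`` mirrors the common 3D-points export of
marker-tracking software: one row per frame, per-track column triplets named
``<track>_X, <track>_Y, <track>_Z``, blank cells for frames where a marker
could not be reconstructed.  Metadata that the bare CSV cannot carry (frame
rate, track kinds, coordinate frame) is written as ``#``-prefixed header
comments, which the reader parses and foreign readers ignore.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySet",
    "FluidProperties",
    "TracerSpec",
    "TrackKind",
    "TrajectoryFormatError",
    "read_trajectories",
    "write_trajectories",
    "fill_gaps",
    "MM_PER_CM",
    "mmps_to_cmps",
]

MM_PER_CM = 10.0

#: Valid track kinds.
TRACK_KINDS = ("bone_marker", "locator", "water_tracer", "food_tracer")
TrackKind = str


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory file violates the expected dialect."""


def mmps_to_cmps(v: np.ndarray | float) -> np.ndarray | float:
    """Convert a velocity from mm/s to cm/s."""
    return np.asarray(v) / MM_PER_CM if isinstance(v, np.ndarray) else v / MM_PER_CM


@dataclass
class FluidProperties:
    """Physical properties of the carrier fluid (defaults: water at 20 °C)."""

    density: float = 1000.0          # kg/m^3
    dynamic_viscosity: float = 1.002e-3  # Pa s
    gravity: float = 9.81            # m/s^2

    def __post_init__(self) -> None:
        for name in ("density", "dynamic_viscosity", "gravity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"FluidProperties.{name} must be > 0")


@dataclass
class TracerSpec:
    """Geometry and density of a spherical flow tracer.

    The default diameter of 1.4 mm is the overall diameter of a metal-cored
    expanded-polystyrene tracer (rod plus foam sphere).
    """

    diameter: float = 1.4e-3  # m
    density: float = 1000.0   # kg/m^3

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("TracerSpec.diameter must be > 0")
        if self.density <= 0:
            raise ValueError("TracerSpec.density must be > 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def volume(self) -> float:
        """Sphere volume in m^3."""
        return (4.0 / 3.0) * np.pi * self.radius**3


@dataclass
class TrajectorySet:
    """Named per-frame 3D point series for one recorded sequence.

    Attributes
    ----------
    frame_rate : float
        Acquisition rate in frames/s (default 750, the X-ray video rate).
    points : dict[str, np.ndarray]
        Track name -> array of shape (n_frames, 3) in mm; NaN marks a
        missing sample (all three components NaN together).
    track_kind : dict[str, str]
        Track name -> one of ``bone_marker | locator | water_tracer |
        food_tracer``.
    frame_index : np.ndarray
        Integer frame numbers, shared by every track.
    coordinate_frame : str
        ``world`` (calibrated lab space) or ``anatomical`` (cranium-bound).
    """

    frame_rate: float = 750.0
    points: dict[str, np.ndarray] = field(default_factory=dict)
    track_kind: dict[str, TrackKind] = field(default_factory=dict)
    frame_index: np.ndarray | None = None
    coordinate_frame: str = "world"
    gap_fill_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        n = None
        for name, arr in list(self.points.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"track {name!r} must have shape (n, 3)")
            self.points[name] = arr
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValueError("all tracks must share the same frame range")
            # a partially-missing sample is promoted to fully missing
            partial = np.isnan(arr).any(axis=1) & ~np.isnan(arr).all(axis=1)
            if partial.any():
                arr[partial] = np.nan
            finite = arr[~np.isnan(arr).any(axis=1)]
            if finite.size and not np.isfinite(finite).all():
                raise ValueError(f"track {name!r} contains non-finite positions")
        if self.frame_index is None:
            self.frame_index = np.arange(n if n is not None else 0)
        else:
            self.frame_index = np.asarray(self.frame_index, dtype=int)
            if n is not None and self.frame_index.shape[0] != n:
                raise ValueError("frame_index length must match track length")
        for name in self.points:
            self.track_kind.setdefault(name, "locator")
        unknown = set(self.track_kind.values()) - set(TRACK_KINDS)
        if unknown:
            raise ValueError(f"unknown track kinds: {sorted(unknown)}")

    # -- convenience ---------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return int(self.frame_index.shape[0])

    @property
    def times(self) -> np.ndarray:
        """Time of each frame in seconds (frame_index / frame_rate)."""
        return self.frame_index / self.frame_rate

    def tracks_of_kind(self, kind: TrackKind) -> list[str]:
        return [n for n, k in self.track_kind.items() if k == kind]

    def valid_mask(self, name: str) -> np.ndarray:
        return ~np.isnan(self.points[name]).any(axis=1)

    def copy(self) -> "TrajectorySet":
        return TrajectorySet(
            frame_rate=self.frame_rate,
            points={k: v.copy() for k, v in self.points.items()},
            track_kind=dict(self.track_kind),
            frame_index=self.frame_index.copy(),
            coordinate_frame=self.coordinate_frame,
            gap_fill_log=list(self.gap_fill_log),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_meta(lines: list[str]) -> dict:
    meta: dict = {"kinds": {}}
    for raw in lines:
        body = raw.lstrip("#").strip()
        if not body or ":" not in body:
            continue
        key, _, value = body.partition(":")
        key, value = key.strip(), value.strip()
        if key == "frame_rate":
            meta["frame_rate"] = float(value)
        elif key == "coordinate_frame":
            meta["coordinate_frame"] = value
        elif key == "kind":
            track, _, kind = value.partition("=")
            meta["kinds"][track.strip()] = kind.strip()
    return meta


def _infer_kind(name: str) -> TrackKind:
    low = name.lower()
    if "water" in low:
        return "water_tracer"
    if "food" in low:
        return "food_tracer"
    if "marker" in low or "neuro" in low or "cranium" in low:
        return "bone_marker"
    return "locator"


def read_trajectories(path: str | Path, dialect: str = "xmalab_3d") -> TrajectorySet:
    """Read a trajectory CSV file into a validated :class:`TrajectorySet`.

    Parameters
    ----------
    path
        CSV file with per-track ``_X/_Y/_Z`` column triplets, one row per
        frame; blank cells mark missing samples.
    dialect
        ``xmalab_3d`` (the 3D-points export convention) or ``generic``
        (identical layout, no naming assumptions).  Both accept optional
        ``#`` metadata comment lines.
    """
    if dialect not in ("xmalab_3d", "generic"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    comment_lines: list[str] = []
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                comment_lines.append(line)
            elif line.strip():
                body_lines.append(line.rstrip("\n"))
    if not body_lines:
        raise TrajectoryFormatError(f"empty trajectory file: {path}")
    meta = _parse_meta(comment_lines)

    n_fields = len(body_lines[0].split(","))
    for row_no, line in enumerate(body_lines[1:], start=1):
        if len(line.split(",")) != n_fields:
            raise TrajectoryFormatError(
                f"inconsistent row length at data row {row_no}: "
                f"expected {n_fields} fields, got {len(line.split(','))}"
            )
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(body_lines)))

    columns = [str(c) for c in df.columns]
    frame_col = None
    if columns and columns[0].lower() in ("frame", "frame_index"):
        frame_col = columns[0]
        columns = columns[1:]

    tracks: dict[str, dict[str, str]] = {}
    for col in columns:
        if "_" not in col or col.rsplit("_", 1)[1].upper() not in ("X", "Y", "Z"):
            raise TrajectoryFormatError(
                f"malformed header: column {col!r} is not of the form <track>_X/Y/Z"
            )
        track, axis = col.rsplit("_", 1)
        tracks.setdefault(track, {})[axis.upper()] = col
    for track, axes in tracks.items():
        missing_axes = set("XYZ") - set(axes)
        if missing_axes:
            raise TrajectoryFormatError(
                f"malformed header: track {track!r} lacks axes {sorted(missing_axes)}"
            )

    n = df.shape[0]
    points = {}
    for track, axes in tracks.items():
        arr = np.column_stack(
            [pd.to_numeric(df[axes[a]], errors="coerce").to_numpy(dtype=float) for a in "XYZ"]
        )
        points[track] = arr

    frame_index = (
        df[frame_col].to_numpy(dtype=int) if frame_col is not None else np.arange(n)
    )
    kinds = {t: meta["kinds"].get(t, _infer_kind(t)) for t in tracks}
    return TrajectorySet(
        frame_rate=meta.get("frame_rate", 750.0),
        points=points,
        track_kind=kinds,
        frame_index=frame_index,
        coordinate_frame=meta.get("coordinate_frame", "world"),
    )


def write_trajectories(ts: TrajectorySet, path: str | Path) -> None:
    """Write ``ts`` so that :func:`read_trajectories` round-trips losslessly."""
    path = Path(path)
    header = [f"# frame_rate: {ts.frame_rate!r}", f"# coordinate_frame: {ts.coordinate_frame}"]
    header += [f"# kind: {name}={kind}" for name, kind in ts.track_kind.items()]
    cols: dict[str, np.ndarray] = {"frame": ts.frame_index}
    for name, arr in ts.points.items():
        for j, axis in enumerate("XYZ"):
            cols[f"{name}_{axis}"] = arr[:, j]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, float_format="%.12g", na_rep="")


def write_table(records: Iterable[Mapping], path: str | Path) -> None:
    """Write derived records (phase tables, profiles, peaks) as CSV or JSON."""
    path = Path(path)
    records = list(records)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1, default=float)
    else:
        pd.DataFrame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# gap filling
# ---------------------------------------------------------------------------

def fill_gaps(ts: TrajectorySet, max_gap: int) -> TrajectorySet:
    """Linearly interpolate interior missing runs of length <= ``max_gap``.

    Leading/trailing gaps and runs longer than ``max_gap`` are left missing.
    Observed samples are never modified.  The returned set carries an audit
    log of filled spans in ``gap_fill_log``.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out = ts.copy()
    log: list[dict] = []
    for name, arr in out.points.items():
        missing = np.isnan(arr).any(axis=1)
        if not missing.any() or max_gap == 0:
            continue
        n = arr.shape[0]
        i = 0
        while i < n:
            if not missing[i]:
                i += 1
                continue
            j = i
            while j < n and missing[j]:
                j += 1
            run = j - i
            interior = i > 0 and j < n
            if interior and run <= max_gap:
                left, right = arr[i - 1], arr[j]
                frac = (np.arange(1, run + 1) / (run + 1))[:, None]
                arr[i:j] = left + frac * (right - left)
                log.append({"track": name, "start": int(i), "stop": int(j), "length": run})
            i = j
    out.gap_fill_log = log
    return out
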