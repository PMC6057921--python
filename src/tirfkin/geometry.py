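"""Filament/branch geometry shared by the simulator and the event classifier.

All coordinates are in micrometres with the origin at the image corner.
A :class:`SiteMap` holds filament centrelines as polylines, branch-junction
points, and (optionally) explicit background sites; it is the source of
site counts for occupancy calculations. A :class:`DetectionBox` is the
square region (default area 1.14 um^2) used to assign binding events to a
location and to measure per-location binding frequency.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point


@dataclass
class DetectionBox:
    """Axis-aligned square detection box centred on a target location."""

    center: tuple[float, float]
    area_um2: float = 1.14

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("detection box area must be positive")

    @property
    def half_side_um(self) -> float:
        return math.sqrt(self.area_um2) / 2.0

    def contains(self, x_um, y_um):
        """Vectorised point-in-box test."""
        h = self.half_side_um
        x_um = np.asarray(x_um, dtype=float)
        y_um = np.asarray(y_um, dtype=float)
        return (np.abs(x_um - self.center[0]) <= h) & (np.abs(y_um - self.center[1]) <= h)


@dataclass
class SiteMap:
    """Geometry of filaments, branch junctions and background sites.

    Parameters
    ----------
    filaments : list of (N, 2) arrays
        Filament centrelines as polylines in um (N >= 2 vertices each).
    branches : (M, 2) array
        Branch-junction points in um.
    extent_um : (width, height)
        Field-of-view extent in um.
    background_sites : (K, 2) array, optional
        Explicit background target locations ("boxes without actin").
    """

    filaments: list[np.ndarray] = field(default_factory=list)
    branches: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    extent_um: tuple[float, float] = (50.0, 50.0)
    background_sites: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        self.filaments = [np.asarray(f, dtype=float) for f in self.filaments]
        for f in self.filaments:
            if f.ndim != 2 or f.shape[1] != 2 or f.shape[0] < 2:
                raise ValueError("each filament must be an (N>=2, 2) polyline")
        self.branches = np.asarray(self.branches, dtype=float).reshape(-1, 2)
        self.background_sites = np.asarray(self.background_sites, dtype=float).reshape(-1, 2)
        if self.extent_um[0] <= 0 or self.extent_um[1] <= 0:
            raise ValueError("extent must be positive")
        self._lines = [LineString(f) for f in self.filaments]

    # -- measurements -------------------------------------------------
    def filament_lengths_um(self) -> np.ndarray:
        return np.array([line.length for line in self._lines])

    @property
    def total_filament_length_um(self) -> float:
        return float(self.filament_lengths_um().sum()) if self.filaments else 0.0

    @property
    def n_branches(self) -> int:
        return int(self.branches.shape[0])

    def distance_to_filaments(self, x_um: float, y_um: float) -> float:
        """Shortest distance from a point to any filament centreline (um)."""
        if not self._lines:
            return math.inf
        p = Point(float(x_um), float(y_um))
        return min(line.distance(p) for line in self._lines)

    def point_along_filament(self, filament_index: int, arc_um: float) -> tuple[float, float]:
        """Point at arclength ``arc_um`` along filament ``filament_index``."""
        p = self._lines[filament_index].interpolate(float(arc_um))
        return (p.x, p.y)

    # -- serialisation (sites.csv) -------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.filaments):
            rows.append(
                {
                    "site_id": f"filament{i}",
                    "class": "filament",
                    "vertices": json.dumps(np.round(f, 6).tolist()),
                    "length_um": round(self._lines[i].length, 6),
                }
            )
        for j, (x, y) in enumerate(self.branches):
            rows.append(
                {
                    "site_id": f"branch{j}",
                    "class": "branch",
                    "vertices": json.dumps([[round(float(x), 6), round(float(y), 6)]]),
                    "length_um": 0.0,
                }
            )
        return pd.DataFrame(rows, columns=["site_id", "class", "vertices", "length_um"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, extent_um=(50.0, 50.0)) -> "SiteMap":
        required = {"site_id", "class", "vertices"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"sites table missing columns: {sorted(missing)}")
        filaments, branches = [], []
        for _, row in frame.iterrows():
            verts = np.asarray(json.loads(row["vertices"]), dtype=float)
            if row["class"] == "filament":
                filaments.append(verts)
            elif row["class"] == "branch":
                branches.append(verts.reshape(-1)[:2])
            else:
                raise ValueError(f"unknown site class {row['class']!r}")
        return cls(filaments=filaments, branches=np.array(branches).reshape(-1, 2), extent_um=extent_um)
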