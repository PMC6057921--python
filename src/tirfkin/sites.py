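"""Per-site-class binding frequency and occupancy statistics.

Binding frequency is the number of event starts inside a detection box
divided by the time the box was *available* (total time minus the union
of intervals during which any detected event occupied it). Occupancy is
the time-averaged fraction of candidate binding sites occupied, with
filament sides carrying 370 sites per um and each branch junction one
site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DetectionBox, SiteMap

SIDE_SITE_DENSITY_PER_UM = 370.0


@dataclass
class FrequencyResult:
    site_class: str
    events_per_second: float
    n_boxes: int
    per_box: np.ndarray
    dispersion: float  # SD across boxes

    def __post_init__(self) -> None:
        if self.events_per_second < 0:
            raise ValueError("frequency must be >= 0")


@dataclass
class OccupancyResult:
    site_class: str
    occupancy: float
    n_sites: int
    observation_s: float
    total_bound_s: float
    per_trial: np.ndarray | None = None
    dispersion: float | None = None


def _union_length(intervals: list[tuple[float, float]]) -> float:
    if not intervals:
        return 0.0
    intervals = sorted(intervals)
    total, cur_a, cur_b = 0.0, *intervals[0]
    for a, b in intervals[1:]:
        if a > cur_b:
            total += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    return total + (cur_b - cur_a)


def binding_frequency(
    events: pd.DataFrame,
    boxes: list[DetectionBox],
    total_time_s: float,
    frame_interval_s: float,
    site_class: str = "",
) -> FrequencyResult:
    """Per-box binding frequency (event starts / available time).

    Overlapping events inside a box are unioned before their occupied
    time is subtracted from ``total_time_s``. Boxes whose available time
    is <= 0 are excluded with a warning.
    """
    if not boxes:
        raise ValueError("need at least one detection box")
    if total_time_s <= 0:
        raise ValueError("total_time_s must be positive")
    x = events["x_um"].to_numpy(dtype=float) if len(events) else np.empty(0)
    y = events["y_um"].to_numpy(dtype=float) if len(events) else np.empty(0)
    t0 = events["start_frame"].to_numpy(dtype=float) * frame_interval_s if len(events) else np.empty(0)
    t1 = t0 + events["n_frames"].to_numpy(dtype=float) * frame_interval_s if len(events) else np.empty(0)
    per_box = []
    excluded = 0
    for box in boxes:
        inside = box.contains(x, y) if len(events) else np.zeros(0, dtype=bool)
        n_starts = int(inside.sum())
        occupied = _union_length(list(zip(t0[inside], np.minimum(t1[inside], total_time_s))))
        available = total_time_s - occupied
        if available <= 0:
            excluded += 1
            continue
        per_box.append(n_starts / available)
    if excluded:
        warnings.warn(f"{excluded} box(es) excluded: no available time", RuntimeWarning,
                      stacklevel=2)
    if not per_box:
        raise ValueError("no box had available time > 0")
    per_box = np.asarray(per_box)
    return FrequencyResult(
        site_class=site_class,
        events_per_second=float(per_box.mean()),
        n_boxes=per_box.size,
        per_box=per_box,
        dispersion=float(per_box.std(ddof=1)) if per_box.size > 1 else 0.0,
    )


def count_sites(site_map: SiteMap, site_class: str,
                density_per_um: float = SIDE_SITE_DENSITY_PER_UM) -> int:
    """Candidate binding sites: round(length * 370/um) for sides, one per branch."""
    if site_class == "side":
        return int(round(site_map.total_filament_length_um * density_per_um))
    if site_class == "branch":
        return site_map.n_branches
    raise ValueError("site_class must be 'side' or 'branch'")


def occupancy(
    events: pd.DataFrame,
    n_sites: int,
    observation_s: float,
    frame_interval_s: float,
    site_class: str = "",
    labeled_fraction: float | None = None,
) -> OccupancyResult:
    """Time-averaged site occupancy, clipped at 1.

    occupancy = sum(n_frames * dt) / (n_sites * observation_s). By
    default this is the occupancy by *labeled* molecules; pass
    ``labeled_fraction`` to rescale to total molecules.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if observation_s <= 0:
        raise ValueError("observation_s must be positive")
    bound_s = float(events["n_frames"].sum() * frame_interval_s) if len(events) else 0.0
    occ = bound_s / (n_sites * observation_s)
    if labeled_fraction is not None:
        if not (0 < labeled_fraction <= 1):
            raise ValueError("labeled_fraction must be in (0, 1]")
        occ /= labeled_fraction
    return OccupancyResult(
        site_class=site_class,
        occupancy=min(occ, 1.0),
        n_sites=int(n_sites),
        observation_s=float(observation_s),
        total_bound_s=bound_s,
    )


def occupancy_ratio(occ_a: OccupancyResult, occ_b: OccupancyResult) -> dict:
    """Fold difference in occupancy, with per-trial spread when available."""
    if occ_b.occupancy == 0:
        raise ValueError("undefined ratio: denominator occupancy is zero")
    out = {"ratio": occ_a.occupancy / occ_b.occupancy}
    if occ_a.per_trial is not None and occ_b.per_trial is not None \
            and len(occ_a.per_trial) == len(occ_b.per_trial):
        ratios = np.asarray(occ_a.per_trial, dtype=float) / np.asarray(occ_b.per_trial, dtype=float)
        out["per_trial"] = ratios
        out["mean_ratio"] = float(ratios.mean())
        out["sd_ratio"] = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    return out
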