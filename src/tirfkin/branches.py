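"""Branch nucleation curves, debranching survival, elongation, pyrene.

Covers the filament-scale measurements: cumulative branch counts per
field of view, cumulative branch survival after flowing in a debranching
factor, filament elongation rates by linear fit of length vs time, and
baseline/plateau normalization of bulk pyrene-actin assembly curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .sites import SIDE_SITE_DENSITY_PER_UM

FOV_AREA_UM2 = 18000.0


@dataclass
class BranchingCurve:
    times: np.ndarray
    per_fov: np.ndarray      # (n_fov, n_times) cumulative counts
    mean: np.ndarray
    sem: np.ndarray
    fov_area_um2: float = FOV_AREA_UM2

    def __post_init__(self) -> None:
        if np.any(np.diff(self.mean) < -1e-9):
            raise ValueError("cumulative counts must be non-decreasing")


@dataclass
class ElongationFit:
    rate_um_per_s: float
    intercept_um: float
    r_squared: float
    rate_subunits_per_s: float


def cumulative_branching(records: pd.DataFrame, times,
                         fov_area_um2: float = FOV_AREA_UM2) -> BranchingCurve:
    """Cumulative branch count per FOV on a time grid, mean +/- SEM.

    ``records`` needs columns ``fov`` (any hashable; combine trial and
    FOV labels upstream if needed) and ``time_s`` (appearance times).
    """
    times = np.asarray(times, dtype=float)
    if "fov" not in records.columns or "time_s" not in records.columns:
        raise ValueError("records must have 'fov' and 'time_s' columns")
    fovs = sorted(records["fov"].unique(), key=str)
    if not fovs:  # no branches at all: one flat zero curve
        z = np.zeros((1, times.size))
        return BranchingCurve(times=times, per_fov=z, mean=z[0], sem=z[0].copy(),
                              fov_area_um2=fov_area_um2)
    per_fov = np.zeros((len(fovs), times.size))
    for i, f in enumerate(fovs):
        t_app = np.sort(records.loc[records["fov"] == f, "time_s"].to_numpy(dtype=float))
        per_fov[i] = np.searchsorted(t_app, times, side="right")
    mean = per_fov.mean(axis=0)
    sem = per_fov.std(axis=0, ddof=1) / np.sqrt(len(fovs)) if len(fovs) > 1 \
        else np.zeros_like(mean)
    return BranchingCurve(times=times, per_fov=per_fov, mean=mean, sem=sem,
                          fov_area_um2=fov_area_um2)


def branch_survival(records: pd.DataFrame, times) -> dict:
    """Per-condition cumulative branch survival, mean +/- SEM over trials.

    ``records`` needs columns ``condition``, ``trial``, ``lifetime_s``
    and ``censored``. Within each trial, S(t) is the fraction of the
    initially present branches surviving beyond t; right-censored
    branches survive through the whole observation window. On fully
    uncensored data S(t) equals 1 minus the empirical CDF exactly.
    """
    times = np.asarray(times, dtype=float)
    required = {"condition", "trial", "lifetime_s", "censored"}
    if not required <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    out = {}
    for cond, grp in records.groupby("condition"):
        trial_curves = []
        for _, tg in grp.groupby("trial"):
            life = tg["lifetime_s"].to_numpy(dtype=float)
            cens = tg["censored"].to_numpy(dtype=bool)
            if life.size == 0:
                raise ValueError("each trial needs at least one branch")
            eff = np.where(cens, np.inf, life)
            trial_curves.append([(eff > t).mean() for t in times])
        curves = np.asarray(trial_curves)
        mean = curves.mean(axis=0)
        sem = curves.std(axis=0, ddof=1) / np.sqrt(curves.shape[0]) if curves.shape[0] > 1 \
            else np.zeros_like(mean)
        out[cond] = {"times": times, "per_trial": curves, "mean": mean, "sem": sem}
    return out


def elongation_rate(times_s, lengths_um,
                    site_density_per_um: float = SIDE_SITE_DENSITY_PER_UM) -> ElongationFit:
    """Ordinary least-squares filament elongation rate (um/s).

    Also reports the rate in subunits/s at 370 subunits per um.
    """
    t = np.asarray(times_s, dtype=float)
    length = np.asarray(lengths_um, dtype=float)
    if t.size < 3 or length.size != t.size:
        raise ValueError("need at least 3 (time, length) points")
    res = linregress(t, length)
    return ElongationFit(
        rate_um_per_s=float(res.slope),
        intercept_um=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        rate_subunits_per_s=float(res.slope * site_density_per_um),
    )


def normalize_pyrene(curves: dict, baseline_frac: float = 0.05,
                     plateau_frac: float = 0.10,
                     plateau_slope_frac_per_100s: float = 0.01) -> dict:
    """Normalize pyrene-fluorescence assembly curves to [0, 1].

    Baselines (mean of the first ``baseline_frac`` of points) are set to
    0. A curve is plateaued when the OLS slope over its final
    ``plateau_frac`` of points is below ``plateau_slope_frac_per_100s``
    of its range per 100 s; plateaued curves are scaled so the plateau
    is 1. Curves that never plateau are scaled by the mean raw plateau
    value of those that did; if no curve plateaus that fallback is
    inapplicable and an error is raised.

    ``curves`` maps condition -> (times, values); returns the same
    mapping plus a ``plateaued`` flag per condition.
    """
    if not curves:
        raise ValueError("need at least one curve")
    shifted, plateau_vals, plateaued = {}, {}, {}
    for name, (t, y) in curves.items():
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        nb = max(3, int(round(baseline_frac * y.size)))
        ysh = y - y[:nb].mean()
        npl = max(3, int(round(plateau_frac * y.size)))
        tail_t, tail_y = t[-npl:], ysh[-npl:]
        slope = linregress(tail_t, tail_y).slope
        rng = float(ysh.max() - ysh.min())
        thresh = plateau_slope_frac_per_100s * rng / 100.0
        plateaued[name] = bool(abs(slope) < thresh) and rng > 0
        shifted[name] = (t, ysh)
        plateau_vals[name] = float(tail_y.mean())
    plateau_set = [plateau_vals[n] for n, p in plateaued.items() if p]
    if not plateau_set:
        raise ValueError(
            "no curve reached a plateau: the shared-plateau fallback rule is inapplicable"
        )
    mean_plateau = float(np.mean(plateau_set))
    out = {}
    for name, (t, ysh) in shifted.items():
        scale = plateau_vals[name] if plateaued[name] else mean_plateau
        out[name] = {"times": t, "values": ysh / scale, "plateaued": plateaued[name]}
    return out
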