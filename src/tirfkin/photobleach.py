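"""Photobleaching step counting in single-spot intensity traces.

Steps are found by greedy binary segmentation: the change point giving
the largest residual-sum-of-squares reduction is added while it improves
a BIC score on Gaussian residuals. Only downward level changes count as
bleaching steps (no blinking recovery); two fluorophores bleaching in
the same frame are counted once — a limitation shared by any step
counter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

__all__ = ["StepFit", "count_steps", "fraction_by_steps", "PhotobleachStepCounter"]


@dataclass
class StepFit:
    n_steps: int
    change_points: list[int]      # frame indices of downward steps
    level_means: list[float]      # one mean per fitted segment
    score: float                  # total residual sum of squares


def _best_split(y: np.ndarray) -> tuple[int, float]:
    """Best single change point in a segment: (index, RSS reduction)."""
    n = y.size
    if n < 2:
        return -1, 0.0
    s = np.cumsum(y)
    s2 = np.cumsum(y * y)
    i = np.arange(1, n)
    rss_left = s2[:-1] - s[:-1] ** 2 / i
    rss_right = (s2[-1] - s2[:-1]) - (s[-1] - s[:-1]) ** 2 / (n - i)
    rss_total = s2[-1] - s[-1] ** 2 / n
    red = rss_total - (rss_left + rss_right)
    j = int(np.argmax(red))
    return j + 1, float(red[j])


def count_steps(trace, max_steps: int = 4, penalty: str = "BIC",
                penalty_scale: float = 2.0) -> StepFit:
    """Count downward photobleaching steps in one intensity trace.

    Piecewise-constant fit by binary segmentation; a change point is
    retained while it lowers BIC = n*ln(RSS/n) + penalty_scale*m*ln(n)
    (m change points, Gaussian residuals). At most ``max_steps`` change
    points are placed; of those, only boundaries where the level drops
    are reported as steps.
    """
    y = np.asarray(trace, dtype=float)
    if y.ndim != 1 or y.size < 10:
        raise ValueError("trace must be 1-D with at least 10 frames")
    if not np.all(np.isfinite(y)):
        raise ValueError("trace contains non-finite intensities")
    if penalty != "BIC":
        raise ValueError("only the BIC penalty is implemented")
    n = y.size
    eps = 1e-12 * max(1.0, float(np.ptp(y)) ** 2)
    bounds = [0, n]  # segment boundaries, sorted
    rss = float(np.sum((y - y.mean()) ** 2))

    def bic(rss_val, m):
        return n * np.log(rss_val / n + eps) + penalty_scale * m * np.log(n)

    m = 0
    while m < max_steps:
        best = None  # (reduction, absolute index)
        for a, b in zip(bounds[:-1], bounds[1:]):
            j, red = _best_split(y[a:b])
            if j > 0 and (best is None or red > best[0]):
                best = (red, a + j)
        if best is None:
            break
        red, idx = best
        if bic(max(rss - red, 0.0), m + 1) >= bic(rss, m):
            break
        bounds = sorted(bounds + [idx])
        rss = max(rss - red, 0.0)
        m += 1

    # backward elimination: greedy insertion can drop a boundary inside a
    # level and then legitimately refine both halves; prune any boundary
    # whose removal lowers BIC (smallest RSS increase first)
    def _seg_rss(a, b):
        seg = y[a:b]
        return float(np.sum((seg - seg.mean()) ** 2))

    while m > 0:
        increases = []
        for i in range(1, len(bounds) - 1):
            a, c, b = bounds[i - 1], bounds[i], bounds[i + 1]
            increases.append(_seg_rss(a, b) - _seg_rss(a, c) - _seg_rss(c, b))
        i_min = int(np.argmin(increases))
        if bic(rss + increases[i_min], m - 1) >= bic(rss, m):
            break
        rss += increases[i_min]
        del bounds[i_min + 1]
        m -= 1

    levels = [float(y[a:b].mean()) for a, b in zip(bounds[:-1], bounds[1:])]
    change_points = [
        bounds[i + 1] for i in range(len(levels) - 1) if levels[i + 1] < levels[i]
    ]
    return StepFit(
        n_steps=len(change_points),
        change_points=change_points,
        level_means=levels,
        score=rss,
    )


def fraction_by_steps(step_counts, trials=None) -> dict:
    """Proportions of traces bleaching in 1, 2, ... steps.

    Traces with 0 detected steps are excluded from the proportions and
    reported separately. When a parallel ``trials`` grouping is given,
    per-category fractions are computed within each trial and the SEM
    across trial means is returned.
    """
    counts = np.asarray(step_counts, dtype=int)
    if counts.size < 1:
        raise ValueError("need at least one trace")
    zero = int((counts == 0).sum())
    pos = counts[counts > 0]
    cats = sorted(set(pos.tolist()))
    out = {
        "fractions": {c: float((pos == c).mean()) for c in cats} if pos.size else {},
        "n_zero_step": zero,
        "n_traces": int(counts.size),
    }
    if trials is not None:
        trials = np.asarray(trials)
        if trials.shape != counts.shape:
            raise ValueError("trials must parallel step_counts")
        sem = {}
        trial_means = {}
        for c in cats:
            means = []
            for t in np.unique(trials):
                p = pos_in = counts[(trials == t) & (counts > 0)]
                if pos_in.size:
                    means.append(float((pos_in == c).mean()))
            means = np.asarray(means)
            trial_means[c] = means
            sem[c] = float(means.std(ddof=1) / np.sqrt(means.size)) if means.size > 1 else 0.0
        out["sem"] = sem
        out["trial_means"] = trial_means
    return out


class PhotobleachStepCounter(BaseEstimator):
    """Estimator-style wrapper: transform traces into step counts.

    Parameters mirror :func:`count_steps`. ``transform`` maps an
    (n_traces, n_frames) array to an integer step count per trace;
    ``fit`` is stateless and returns self (kept for pipeline
    compatibility).
    """

    def __init__(self, max_steps: int = 4, penalty: str = "BIC", penalty_scale: float = 2.0):
        self.max_steps = max_steps
        self.penalty = penalty
        self.penalty_scale = penalty_scale

    def fit(self, traces=None, y=None):
        return self

    def transform(self, traces) -> np.ndarray:
        traces = np.atleast_2d(np.asarray(traces, dtype=float))
        return np.array([
            count_steps(tr, self.max_steps, self.penalty, self.penalty_scale).n_steps
            for tr in traces
        ])

    def fit_transform(self, traces, y=None) -> np.ndarray:
        return self.fit(traces).transform(traces)
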