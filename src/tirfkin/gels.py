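"""Stain-free gel densitometry: standard curves and molar ratios.

Band intensity vs protein amount is fit to a second-order polynomial
forced through zero, I(c) = b1*c + b2*c^2, separately per species (so
tryptophan-content differences never require a cross-species intensity
conversion). Unknown bands are inverted through the curve and the
Abp1:Arp2/3 molar ratio summarised across technical replicates, with
the Arp3 band standing in for whole-complex concentration (one Arp3 per
complex).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "GelStandardCurve",
    "BandQuant",
    "fit_standard_curve",
    "infer_concentration",
    "net_intensity",
    "molar_ratio",
]


@dataclass
class BandQuant:
    lane_id: str
    species: str
    raw_intensity: float
    background_intensity: float
    net_intensity: float
    concentration: float | None = None


class GelStandardCurve(BaseEstimator):
    """Quadratic-through-origin standard curve I(c) = b1*c + b2*c^2.

    Attributes
    ----------
    b1_, b2_ : float
        Least-squares coefficients (no intercept; the curve passes
        through the origin exactly).
    residual_ : float
        Residual sum of squares of the fit.
    conc_range_ : (min, max)
        Fitted concentration range; monotonicity of the curve is
        checked on this range.
    """

    def __init__(self, species: str = ""):
        self.species = species

    def fit(self, concs, intensities):
        c = np.asarray(concs, dtype=float)
        y = np.asarray(intensities, dtype=float)
        if c.size != y.size or np.unique(c).size < 3:
            raise ValueError("need intensities at >= 3 distinct concentrations")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        X = np.column_stack([c, c ** 2])
        if np.linalg.matrix_rank(X) < 2:
            raise ValueError("rank-deficient design: concentrations do not span a quadratic")
        coef, res, _, _ = np.linalg.lstsq(X, y, rcond=None)
        self.b1_, self.b2_ = float(coef[0]), float(coef[1])
        self.residual_ = float(res[0]) if res.size else float(np.sum((X @ coef - y) ** 2))
        self.conc_range_ = (float(c.min()), float(c.max()))
        # derivative b1 + 2 b2 c must stay positive on the fitted range
        dmin = min(self.b1_ + 2 * self.b2_ * self.conc_range_[0],
                   self.b1_ + 2 * self.b2_ * self.conc_range_[1])
        if dmin <= 0:
            warnings.warn("standard curve is not monotone on the fitted range",
                          RuntimeWarning, stacklevel=2)
        return self

    def predict(self, concs):
        c = np.asarray(concs, dtype=float)
        return self.b1_ * c + self.b2_ * c ** 2

    def inverse(self, intensity: float) -> float:
        """Unique nonnegative root of b2*c^2 + b1*c - I = 0."""
        y = float(intensity)
        if y < 0:
            raise ValueError("net intensity must be >= 0")
        if y == 0:
            return 0.0
        b1, b2 = self.b1_, self.b2_
        scale = max(abs(b1), abs(b2), 1e-30)
        if abs(b2) < 1e-12 * scale:
            if b1 <= 0:
                raise ValueError("degenerate curve: cannot invert")
            return y / b1
        disc = b1 ** 2 + 4 * b2 * y
        if disc < 0:
            raise ValueError("no real root: intensity outside curve range")
        roots = [(-b1 + np.sqrt(disc)) / (2 * b2), (-b1 - np.sqrt(disc)) / (2 * b2)]
        pos = [r for r in roots if r >= 0]
        if not pos:
            raise ValueError("no nonnegative root for this intensity")
        return float(min(pos))


def fit_standard_curve(concs, intensities, species: str = "") -> GelStandardCurve:
    return GelStandardCurve(species=species).fit(concs, intensities)


def infer_concentration(net_intensity_value: float, curve: GelStandardCurve) -> float:
    return curve.inverse(net_intensity_value)


def net_intensity(raw: float, background: float) -> float:
    """Background-subtracted band intensity, clipped at zero."""
    net = raw - background
    if net < 0:
        warnings.warn("background exceeds band intensity; clipping net to 0",
                      RuntimeWarning, stacklevel=2)
        net = 0.0
    return net


def quantify_lanes(gel: pd.DataFrame, curves: dict[str, GelStandardCurve]) -> list[BandQuant]:
    """Infer concentrations for the unknown lanes of a gel table.

    ``gel`` follows the gel.csv schema (lane_id, species, conc_known,
    raw_intensity, background_intensity); lanes with blank conc_known
    are unknowns.
    """
    out = []
    unknowns = gel[gel["conc_known"].isna()]
    for _, row in unknowns.iterrows():
        net = net_intensity(float(row["raw_intensity"]), float(row["background_intensity"]))
        curve = curves[row["species"]]
        out.append(BandQuant(
            lane_id=str(row["lane_id"]), species=str(row["species"]),
            raw_intensity=float(row["raw_intensity"]),
            background_intensity=float(row["background_intensity"]),
            net_intensity=net, concentration=curve.inverse(net),
        ))
    return out


def molar_ratio(concs_a, concs_b) -> dict:
    """Per-replicate molar ratio c_A / c_B, summarised as mean +/- SD.

    Replicates where the denominator is zero are flagged and excluded
    from the mean.
    """
    a = np.asarray(concs_a, dtype=float)
    b = np.asarray(concs_b, dtype=float)
    if a.size != b.size or a.size < 1:
        raise ValueError("need >= 1 replicate with both species quantified")
    ok = b > 0
    n_flagged = int((~ok).sum())
    if n_flagged:
        warnings.warn(f"{n_flagged} replicate(s) excluded: zero denominator",
                      RuntimeWarning, stacklevel=2)
    if not ok.any():
        raise ValueError("no replicate with nonzero denominator")
    ratios = a[ok] / b[ok]
    return {
        "per_replicate": ratios,
        "mean": float(ratios.mean()),
        "sd": float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0,
        "n_excluded": n_flagged,
    }
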