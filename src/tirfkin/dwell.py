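"""Dwell-time survival analysis and frame-censored exponential MLE.

Single-molecule dwell times measured from movies are interval censored: a
molecule is observed only at acquisition instants k*dt, so an event that
spans k instants is recorded as a dwell of k*dt seconds, events shorter
than one frame are never seen, and events still bound at the last frame
are right censored. This module fits single- and two-exponential dwell
models to such data, with two likelihood conventions:

``naive``
    Treats the recorded dwells t_i = k_i * dt as exact draws from the
    continuous exponential (mixture) density. Right-censored events enter
    as survival terms. Biased upward when dt is not small relative to the
    mean dwell, because sub-frame events are silently missing.

``phase_marginalized``
    Models the observed frame count directly. With the binding start
    phase uniform on [0, dt) relative to the frame clock, the number of
    acquisition instants covered by an exponential dwell of mean tau is,
    conditional on detection (k >= 1), geometric:

        P(K = k) = (1 - q) q^(k-1),  q = exp(-dt / tau),

    which gives the closed-form MLE tau = dt / ln(kbar / (kbar - 1)). For
    a two-component mixture, each component additionally carries its
    detection probability C(tau) = (tau/dt) (1 - exp(-dt/tau)), so the
    fitted mixture weight refers to the underlying events, not just the
    detected ones; this makes the estimator unbiased for the parameters
    that generated the data.

Bootstrap standard errors are obtained by nonparametric resampling of
events, with mixture components sorted (T_short < T_long) before
aggregation to avoid label switching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

__all__ = [
    "DwellSample",
    "SurvivalCurve",
    "ExpFit",
    "Exp2Fit",
    "survival_curve",
    "fit_exponential",
    "fit_two_exponential",
    "exponential_loglik",
    "two_exponential_loglik",
    "bootstrap_se",
    "compare_models",
    "mean_lifetime",
    "detection_probability",
    "ExponentialDwellModel",
    "TwoExponentialDwellModel",
]

_ESTIMATORS = ("naive", "phase_marginalized")
# tau is reported at dt/_TAU_FLOOR_DIV when the likelihood maximum sits on
# the lower boundary (all dwells exactly one frame).
_TAU_FLOOR_DIV = 50.0


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------
@dataclass
class DwellSample:
    """A set of frame-quantized dwell observations.

    Parameters
    ----------
    frame_counts : array of int
        Number of frames each event was observed (all >= 1).
    frame_interval_s : float
        Acquisition interval dt in seconds.
    right_censored : array of bool, optional
        True for events still bound at the final acquisition instant.
    """

    frame_counts: np.ndarray
    frame_interval_s: float
    right_censored: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frame_counts = np.asarray(self.frame_counts, dtype=int)
        if self.frame_counts.ndim != 1 or self.frame_counts.size < 1:
            raise ValueError("frame_counts must be a non-empty 1-D array")
        if np.any(self.frame_counts < 1):
            raise ValueError("all frame counts must be >= 1")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.right_censored is None:
            self.right_censored = np.zeros(self.frame_counts.shape, dtype=bool)
        else:
            self.right_censored = np.asarray(self.right_censored, dtype=bool)
            if self.right_censored.shape != self.frame_counts.shape:
                raise ValueError("right_censored must parallel frame_counts")

    @property
    def n(self) -> int:
        return int(self.frame_counts.size)

    @property
    def dwell_s(self) -> np.ndarray:
        """Recorded dwell times k * dt in seconds."""
        return self.frame_counts * self.frame_interval_s

    def resample(self, rng: np.random.Generator) -> "DwellSample":
        idx = rng.integers(0, self.n, self.n)
        return DwellSample(self.frame_counts[idx], self.frame_interval_s, self.right_censored[idx])


@dataclass
class SurvivalCurve:
    """Empirical cumulative survival S(t) = fraction of dwells >= t."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if abs(self.survival[0] - 1.0) > 1e-12:
            raise ValueError("survival must start at 1")


@dataclass
class ExpFit:
    """Fitted single-exponential dwell model."""

    tau: float
    loglik: float
    n: int
    estimator: str
    se_tau: float | None = None
    boundary: bool = False


@dataclass
class Exp2Fit:
    """Fitted two-exponential mixture, canonically ordered T_short < T_long."""

    t_short: float
    t_long: float
    frac_long: float
    loglik: float
    n: int
    estimator: str
    se_t_short: float | None = None
    se_t_long: float | None = None
    se_frac_long: float | None = None
    converged: bool = True


# ----------------------------------------------------------------------
# survival curve (product-limit on the frame grid)
# ----------------------------------------------------------------------
def survival_curve(sample: DwellSample) -> SurvivalCurve:
    """Cumulative survival on the frame grid.

    Without censoring S(t) is the plain fraction of dwells >= t. With
    right censoring the Kaplan-Meier product limit is used: censored
    events contribute to the risk set up to their censoring time. The
    curve is evaluated at every multiple of dt up to the longest
    observation, with the convention S(t) = P(T >= t) (so S(0) = 1 and
    the drop caused by deaths at time t appears just after t).
    """
    dt = sample.frame_interval_s
    k = sample.frame_counts
    cens = sample.right_censored
    kmax = int(k.max())
    grid_k = np.arange(0, kmax + 2)

    if not cens.any():
        surv = np.array([(k >= gk).mean() for gk in grid_k])
        return SurvivalCurve(grid_k * dt, surv)

    # product-limit: deaths d_j and risk sets n_j at each frame multiple
    surv = np.empty(grid_k.size)
    s = 1.0
    for i, gk in enumerate(grid_k):
        surv[i] = s  # S(gk*dt) = prod over death times < gk*dt
        at_risk = int((k >= gk).sum())
        deaths = int(((k == gk) & ~cens).sum())
        if at_risk > 0 and deaths > 0:
            s *= 1.0 - deaths / at_risk
    return SurvivalCurve(grid_k * dt, surv)


# ----------------------------------------------------------------------
# likelihoods
# ----------------------------------------------------------------------
def detection_probability(tau: float, frame_interval_s: float) -> float:
    """Probability that an exponential dwell covers >= 1 acquisition instant.

    Under a start phase uniform on [0, dt): C(tau) = (tau/dt)(1 - e^(-dt/tau)).
    """
    x = frame_interval_s / tau
    return float(-np.expm1(-x) / x)


def _aggregate(sample: DwellSample):
    """Collapse to unique (k, censored) rows with multiplicities."""
    key = sample.frame_counts * 2 + sample.right_censored.astype(int)
    uniq, counts = np.unique(key, return_counts=True)
    k = uniq // 2
    cens = (uniq % 2).astype(bool)
    return k.astype(float), cens, counts.astype(float)


def exponential_loglik(sample: DwellSample, tau: float, estimator: str = "phase_marginalized") -> float:
    """Log-likelihood of a single-exponential dwell model at ``tau``."""
    _check_estimator(estimator)
    dt = sample.frame_interval_s
    k, cens, w = _aggregate(sample)
    if estimator == "naive":
        t = k * dt
        ll = np.where(cens, -t / tau, -np.log(tau) - t / tau)
    else:
        lnq = -dt / tau
        ln1mq = np.log(-np.expm1(lnq))
        ll = (k - 1) * lnq + np.where(cens, 0.0, ln1mq)
    return float(np.sum(w * ll))


def two_exponential_loglik(
    sample: DwellSample,
    t_short: float,
    t_long: float,
    frac_long: float,
    estimator: str = "phase_marginalized",
) -> float:
    """Log-likelihood of a two-exponential mixture.

    The ``phase_marginalized`` likelihood conditions on detection with
    per-component detection probabilities, so ``frac_long`` is the long
    component's share of underlying events.
    """
    _check_estimator(estimator)
    k, cens, w = _aggregate(sample)
    return float(
        np.sum(
            w
            * _mixture_logpmf(
                k, cens, sample.frame_interval_s, t_short, t_long, frac_long, estimator
            )
        )
    )


def _mixture_logpmf(k, cens, dt, t_short, t_long, frac_long, estimator):
    a = np.clip(frac_long, 1e-12, 1 - 1e-12)
    if estimator == "naive":
        t = k * dt
        ls = np.log1p(-a) + np.where(cens, 0.0, -np.log(t_short)) - t / t_short
        ll = np.log(a) + np.where(cens, 0.0, -np.log(t_long)) - t / t_long
        return np.logaddexp(ls, ll)
    lnq_s, lnq_l = -dt / t_short, -dt / t_long
    ln1mq_s = np.log(-np.expm1(lnq_s))
    ln1mq_l = np.log(-np.expm1(lnq_l))
    lnC_s = np.log(t_short / dt) + ln1mq_s
    lnC_l = np.log(t_long / dt) + ln1mq_l
    lw_s = np.log1p(-a) + lnC_s
    lw_l = np.log(a) + lnC_l
    logD = np.logaddexp(lw_s, lw_l)
    term_s = lw_s + (k - 1) * lnq_s + np.where(cens, 0.0, ln1mq_s)
    term_l = lw_l + (k - 1) * lnq_l + np.where(cens, 0.0, ln1mq_l)
    return np.logaddexp(term_s, term_l) - logD


def _check_estimator(estimator: str) -> None:
    if estimator not in _ESTIMATORS:
        raise ValueError(f"estimator must be one of {_ESTIMATORS}")


# ----------------------------------------------------------------------
# single-exponential MLE
# ----------------------------------------------------------------------
def fit_exponential(sample: DwellSample, estimator: str = "phase_marginalized") -> ExpFit:
    """Maximum-likelihood single-exponential fit (closed form).

    ``naive``: tau = (sum of recorded dwells) / (number uncensored).
    ``phase_marginalized``: geometric MLE with censored events entering
    as survival terms; tau = -dt / ln(qhat), qhat = S / (S + n_u) with
    S = sum(k_i - 1) and n_u the number of uncensored events. An
    all-ones uncensored sample sits on the boundary q = 0; tau is then
    reported at the lower bound dt/50 with a warning.
    """
    _check_estimator(estimator)
    if sample.n < 2:
        raise ValueError("need at least 2 events to fit")
    dt = sample.frame_interval_s
    n_u = int((~sample.right_censored).sum())
    boundary = False
    if estimator == "naive":
        if n_u == 0:
            raise ValueError("cannot fit: every event is right-censored")
        tau = float(sample.dwell_s.sum() / n_u)
    else:
        S = float((sample.frame_counts - 1).sum())
        if n_u == 0:
            raise ValueError("cannot fit: every event is right-censored")
        if S == 0.0:
            warnings.warn(
                "all dwells are a single frame: likelihood maximum on the "
                "boundary, tau reported at its lower bound",
                RuntimeWarning,
                stacklevel=2,
            )
            tau = dt / _TAU_FLOOR_DIV
            boundary = True
        else:
            q = S / (S + n_u)
            tau = float(-dt / np.log(q))
    ll = exponential_loglik(sample, tau, estimator)
    return ExpFit(tau=tau, loglik=ll, n=sample.n, estimator=estimator, boundary=boundary)


# ----------------------------------------------------------------------
# two-exponential MLE
# ----------------------------------------------------------------------
def _pack(t_short, t_long, frac_long):
    return np.array([np.log(t_short), np.log(t_long), logit(np.clip(frac_long, 1e-9, 1 - 1e-9))])


def _unpack(theta):
    return float(np.exp(theta[0])), float(np.exp(theta[1])), float(expit(theta[2]))


def fit_two_exponential(
    sample: DwellSample,
    estimator: str = "phase_marginalized",
    n_starts: int = 10,
    seed: int = 0,
    init: tuple[float, float, float] | None = None,
) -> Exp2Fit:
    """Maximum-likelihood two-exponential mixture fit.

    Bounded quasi-Newton (L-BFGS-B) on (log T_short, log T_long,
    logit frac_long), multi-start from method-of-moments, quantile-split
    and near-degenerate initialisations plus seeded log-uniform jitter.
    The near-degenerate start at the single-exponential solution
    guarantees loglik(2exp) >= loglik(1exp). Components are returned in
    canonical order T_short < T_long.

    Parameters
    ----------
    init : tuple, optional
        Explicit (t_short, t_long, frac_long) first start; used to
        warm-start bootstrap refits.
    """
    _check_estimator(estimator)
    if sample.n < 10:
        raise ValueError("need at least 10 events for a mixture fit")
    dt = sample.frame_interval_s
    k, cens, w = _aggregate(sample)

    def nll(theta):
        ts, tl, a = _unpack(theta)
        return -np.sum(w * _mixture_logpmf(k, cens, dt, ts, tl, a, estimator))

    fit1 = fit_exponential(sample, estimator=estimator)
    tau1 = max(fit1.tau, dt / _TAU_FLOOR_DIV)
    dwells = np.sort(sample.dwell_s)
    lo = max(float(dwells[: max(1, sample.n // 2)].mean()), dt * 0.05)
    hi = max(float(dwells[-max(1, sample.n // 10):].mean()), lo * 1.5)

    starts = []
    if init is not None:
        starts.append(init)
    starts += [
        (0.5 * tau1, 3.0 * tau1, 0.2),
        (lo, hi, 0.1),
        (tau1, 5.0 * tau1, 0.02),
        (tau1, tau1 * (1.0 + 1e-6), 0.5),  # single-exponential ridge
    ]
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts + (init is not None):
        m1, m2 = np.exp(rng.uniform(np.log(0.2), np.log(5.0), 2))
        starts.append((tau1 * min(m1, m2), tau1 * max(m1, m2) * 2.0, rng.uniform(0.02, 0.5)))

    bounds = [(np.log(dt * 1e-3), np.log(dt * 1e6))] * 2 + [(-14.0, 14.0)]
    best, best_nll = None, np.inf
    n_ok = 0
    for s in starts:
        try:
            res = minimize(nll, _pack(*s), method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": 500, "ftol": 1e-12})
        except (FloatingPointError, ValueError):
            continue
        if np.isfinite(res.fun):
            n_ok += 1
            if res.fun < best_nll:
                best, best_nll = res.x, float(res.fun)
    if best is None:
        raise RuntimeError(
            f"two-exponential fit failed to converge from any of {len(starts)} starts"
        )
    ts, tl, a = _unpack(best)
    if ts > tl:
        ts, tl, a = tl, ts, 1.0 - a
    ll = -best_nll
    # nesting safeguard: the mixture contains the single exponential
    if ll < fit1.loglik - 1e-9:
        ts = tl = fit1.tau
        a = 0.5
        ll = fit1.loglik
    return Exp2Fit(
        t_short=ts, t_long=tl, frac_long=a, loglik=ll, n=sample.n,
        estimator=estimator, converged=n_ok > 0,
    )


# ----------------------------------------------------------------------
# bootstrap, model comparison, summaries
# ----------------------------------------------------------------------
def _fit_params(fit) -> dict[str, float]:
    if isinstance(fit, ExpFit):
        return {"tau": fit.tau}
    if isinstance(fit, Exp2Fit):
        return {"t_short": fit.t_short, "t_long": fit.t_long, "frac_long": fit.frac_long}
    raise TypeError(f"unsupported fit type {type(fit)!r}")


def bootstrap_se(
    sample: DwellSample,
    fit_function,
    n_boot: int = 10000,
    seed: int | None = None,
) -> dict:
    """Nonparametric bootstrap standard errors for a dwell fit.

    Events are resampled with replacement ``n_boot`` times; the SE of each
    parameter is the standard deviation of the refitted values. Mixture
    replicates are canonically ordered before aggregation (handled inside
    the fit), which resolves label switching. Replicates where the fit
    raises are counted as failures; more than 5% failures triggers a
    warning.

    Returns
    -------
    dict with per-parameter ``se``, the replicate matrix and failure count.
    """
    if sample.n < 2:
        raise ValueError("need at least 2 events to bootstrap")
    rng = np.random.default_rng(seed)
    names = None
    rows = []
    failures = 0
    for _ in range(n_boot):
        rep = sample.resample(rng)
        try:
            fit = fit_function(rep)
        except (ValueError, RuntimeError):
            failures += 1
            continue
        p = _fit_params(fit)
        if names is None:
            names = list(p)
        rows.append([p[name] for name in names])
    if not rows:
        raise RuntimeError("every bootstrap replicate failed to fit")
    if failures > 0.05 * n_boot:
        warnings.warn(
            f"{failures}/{n_boot} bootstrap replicates failed to fit",
            RuntimeWarning,
            stacklevel=2,
        )
    arr = np.asarray(rows, dtype=float)
    se = {name: float(arr[:, j].std(ddof=1)) if arr.shape[0] > 1 else 0.0
          for j, name in enumerate(names)}
    return {"se": se, "replicates": arr, "param_names": names, "n_failures": failures}


def compare_models(fit1: ExpFit, fit2: Exp2Fit) -> dict:
    """AIC comparison of nested single- vs two-exponential fits."""
    if fit1.n != fit2.n:
        raise ValueError("fits must be computed on the same sample")
    aic1 = 2 * 1 - 2 * fit1.loglik
    aic2 = 2 * 3 - 2 * fit2.loglik
    return {
        "delta_loglik": fit2.loglik - fit1.loglik,
        "aic_1exp": aic1,
        "aic_2exp": aic2,
        "preferred": "1exp" if aic1 <= aic2 else "2exp",
    }


def mean_lifetime(fit) -> float:
    """Mean dwell time implied by a fit: tau, or (1-a)T_short + a T_long."""
    if isinstance(fit, ExpFit):
        return float(fit.tau)
    if isinstance(fit, Exp2Fit):
        return float((1.0 - fit.frac_long) * fit.t_short + fit.frac_long * fit.t_long)
    raise TypeError(f"unsupported fit type {type(fit)!r}")


# ----------------------------------------------------------------------
# estimator-style front ends
# ----------------------------------------------------------------------
class ExponentialDwellModel(BaseEstimator):
    """Single-exponential dwell model with frame-interval censoring.

    Scikit-learn-style front end over :func:`fit_exponential`.

    Parameters
    ----------
    frame_interval_s : float
        Acquisition interval dt (s).
    estimator : {"phase_marginalized", "naive"}
        Likelihood convention (see module docstring).

    Attributes
    ----------
    tau_ : float
        Fitted mean dwell time (s).
    loglik_ : float
    se_tau_ : float or None
        Set by :meth:`bootstrap`.
    """

    def __init__(self, frame_interval_s: float = 0.25, estimator: str = "phase_marginalized"):
        self.frame_interval_s = frame_interval_s
        self.estimator = estimator

    def _sample(self, frame_counts, censored):
        return DwellSample(frame_counts, self.frame_interval_s, censored)

    def fit(self, frame_counts, censored=None):
        fit = fit_exponential(self._sample(frame_counts, censored), self.estimator)
        self.tau_ = fit.tau
        self.loglik_ = fit.loglik
        self.n_ = fit.n
        self.se_tau_ = None
        self.fit_ = fit
        return self

    def bootstrap(self, frame_counts, censored=None, n_boot: int = 10000, seed: int | None = None):
        boot = bootstrap_se(
            self._sample(frame_counts, censored),
            lambda s: fit_exponential(s, self.estimator),
            n_boot=n_boot,
            seed=seed,
        )
        self.se_tau_ = boot["se"]["tau"]
        return boot

    def score(self, frame_counts, censored=None) -> float:
        """Mean log-likelihood per event under the fitted model."""
        s = self._sample(frame_counts, censored)
        return exponential_loglik(s, self.tau_, self.estimator) / s.n


class TwoExponentialDwellModel(BaseEstimator):
    """Two-exponential dwell mixture, canonical order T_short < T_long.

    Attributes after :meth:`fit`: ``t_short_``, ``t_long_``,
    ``frac_long_``, ``loglik_``; bootstrap SEs via :meth:`bootstrap`.
    """

    def __init__(
        self,
        frame_interval_s: float = 0.25,
        estimator: str = "phase_marginalized",
        n_starts: int = 10,
        seed: int = 0,
    ):
        self.frame_interval_s = frame_interval_s
        self.estimator = estimator
        self.n_starts = n_starts
        self.seed = seed

    def _sample(self, frame_counts, censored):
        return DwellSample(frame_counts, self.frame_interval_s, censored)

    def fit(self, frame_counts, censored=None):
        fit = fit_two_exponential(
            self._sample(frame_counts, censored),
            estimator=self.estimator,
            n_starts=self.n_starts,
            seed=self.seed,
        )
        self.t_short_ = fit.t_short
        self.t_long_ = fit.t_long
        self.frac_long_ = fit.frac_long
        self.loglik_ = fit.loglik
        self.n_ = fit.n
        self.fit_ = fit
        return self

    def bootstrap(self, frame_counts, censored=None, n_boot: int = 1000, seed: int | None = None):
        init = (self.t_short_, self.t_long_, self.frac_long_)
        boot = bootstrap_se(
            self._sample(frame_counts, censored),
            lambda s: fit_two_exponential(
                s, estimator=self.estimator, n_starts=1, seed=self.seed, init=init
            ),
            n_boot=n_boot,
            seed=seed,
        )
        self.se_t_short_ = boot["se"]["t_short"]
        self.se_t_long_ = boot["se"]["t_long"]
        self.se_frac_long_ = boot["se"]["frac_long"]
        return boot

    def score(self, frame_counts, censored=None) -> float:
        s = self._sample(frame_counts, censored)
        return (
            two_exponential_loglik(
                s, self.t_short_, self.t_long_, self.frac_long_, self.estimator
            )
            / s.n
        )
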