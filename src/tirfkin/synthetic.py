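"""Ground-truth generators emulating single-molecule TIRF observations.

Every downstream stage of the package is validated by parameter
recovery: these generators draw binding events, photobleaching traces,
branch lifetimes, gel intensities and image stacks from known kinetic
parameters so the analysis modules can be checked against the values
that produced the data.

Conventions (shared with the rest of the package):

* a molecule is "present in frame k" iff it is bound at the
  instantaneous acquisition time k*dt (exposure is short relative to
  the interval and is not integrated);
* the binding start phase relative to the frame clock is uniform on
  [0, dt) — binding chemistry is asynchronous with the camera;
* events still bound at the final acquisition instant are emitted with
  a right-censoring flag (a drop option exists);
* identical (seed, scenario) reproduce identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dwell import DwellSample
from .events import BindingEvent
from .geometry import SiteMap

__all__ = [
    "KineticModel",
    "SimScenario",
    "TrueEvent",
    "MovieParams",
    "draw_dwells",
    "simulate_binding_events",
    "quantize_to_frames",
    "simulate_dwell_sample",
    "render_movie",
    "simulate_photobleach_traces",
    "simulate_debranching",
    "simulate_gel_standards",
    "simulate_two_state_occupancy",
]


# ----------------------------------------------------------------------
# parameter containers
# ----------------------------------------------------------------------
def _validate_dwell(dwell: dict) -> dict:
    """Normalise a dwell spec: {tau}, {t_short,t_long,frac_long} or {fixed}."""
    d = {k.lower(): v for k, v in dwell.items()}
    if "tau" in d:
        if d["tau"] <= 0:
            raise ValueError("tau must be positive")
        return {"tau": float(d["tau"])}
    if "fixed" in d:
        if d["fixed"] <= 0:
            raise ValueError("fixed dwell must be positive")
        return {"fixed": float(d["fixed"])}
    if {"t_short", "t_long", "frac_long"} <= set(d):
        ts, tl, a = float(d["t_short"]), float(d["t_long"]), float(d["frac_long"])
        if not (0 < ts < tl):
            raise ValueError("need 0 < t_short < t_long")
        if not (0 <= a <= 1):
            raise ValueError("frac_long must be in [0, 1]")
        return {"t_short": ts, "t_long": tl, "frac_long": a}
    raise ValueError(
        "dwell spec must be {'tau': s}, {'fixed': s} or "
        "{'t_short': s, 't_long': s, 'frac_long': f}"
    )


@dataclass
class KineticModel:
    """Arrival rate (events/s/site) plus a dwell-time model."""

    arrival_rate: float
    dwell: dict

    def __post_init__(self) -> None:
        if self.arrival_rate < 0:
            raise ValueError("arrival_rate must be >= 0")
        self.dwell = _validate_dwell(self.dwell)

    @property
    def mean_dwell_s(self) -> float:
        d = self.dwell
        if "tau" in d:
            return d["tau"]
        if "fixed" in d:
            return d["fixed"]
        return (1 - d["frac_long"]) * d["t_short"] + d["frac_long"] * d["t_long"]


@dataclass
class SimScenario:
    """A complete simulated recording: geometry, kinetics, sampling."""

    seed: int
    duration_s: float
    frame_interval_s: float
    site_map: SiteMap
    kinetics_per_class: dict[str, KineticModel]
    labeled_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if not (0.0 <= self.labeled_fraction <= 1.0):
            raise ValueError("labeled_fraction must be in [0, 1]")
        for cls in self.kinetics_per_class:
            if cls not in ("background", "side", "branch"):
                raise ValueError(f"unknown site class {cls!r}")

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration_s / self.frame_interval_s * (1 + 1e-12))) + 1


@dataclass
class TrueEvent:
    """Latent truth behind an observed event (continuous times)."""

    site_id: str
    site_class: str
    t_start: float
    duration: float
    x_um: float = 0.0
    y_um: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class MovieParams:
    pixel_size_um: float = 0.27
    image_shape: tuple[int, int] = (64, 64)
    psf_sigma_px: float = 1.2
    photons_per_spot: float = 500.0
    background_level: float = 0.0
    noise_model: str = "none"  # none | poisson | gaussian
    gaussian_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        if self.noise_model not in ("none", "poisson", "gaussian"):
            raise ValueError("noise_model must be none, poisson or gaussian")


# ----------------------------------------------------------------------
# dwell draws and binding events
# ----------------------------------------------------------------------
def draw_dwells(dwell: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    d = _validate_dwell(dwell)
    if "tau" in d:
        return rng.exponential(d["tau"], n)
    if "fixed" in d:
        return np.full(n, d["fixed"])
    is_long = rng.random(n) < d["frac_long"]
    out = rng.exponential(d["t_short"], n)
    out[is_long] = rng.exponential(d["t_long"], is_long.sum())
    return out


def _site_positions(scenario: SimScenario, rng: np.random.Generator):
    """Enumerate (site_id, site_class, position sampler) triples."""
    sm = scenario.site_map
    sites = []
    for i in range(len(sm.filaments)):
        length = float(sm.filament_lengths_um()[i])

        def sampler(i=i, length=length):
            return sm.point_along_filament(i, rng.uniform(0.0, length))

        sites.append((f"filament{i}", "side", sampler))
    for j, (bx, by) in enumerate(sm.branches):
        sites.append((f"branch{j}", "branch", lambda bx=bx, by=by: (bx, by)))
    if sm.background_sites.size:
        for kk, (gx, gy) in enumerate(sm.background_sites):
            sites.append((f"bg{kk}", "background", lambda gx=gx, gy=gy: (gx, gy)))
    elif "background" in scenario.kinetics_per_class:
        # one diffuse background "site": uniform over non-filament area
        def bg_sampler():
            for _ in range(1000):
                x = rng.uniform(0, sm.extent_um[0])
                y = rng.uniform(0, sm.extent_um[1])
                if sm.distance_to_filaments(x, y) > 0.5:
                    return (x, y)
            return (x, y)

        sites.append(("bg0", "background", bg_sampler))
    return sites


def simulate_binding_events(scenario: SimScenario) -> list[TrueEvent]:
    """Homogeneous-Poisson arrivals per site with class-specific dwells.

    Events are i.i.d. per site: arrival count ~ Poisson(rate * duration),
    start times uniform over the recording, durations from the class
    dwell model. Only a ``labeled_fraction`` of events is emitted (an
    unlabeled molecule is invisible). Deterministic given the scenario
    seed; events are returned sorted by start time.
    """
    rng = np.random.default_rng(scenario.seed)
    events: list[TrueEvent] = []
    for site_id, site_class, sampler in _site_positions(scenario, rng):
        km = scenario.kinetics_per_class.get(site_class)
        if km is None or km.arrival_rate == 0:
            continue
        n = rng.poisson(km.arrival_rate * scenario.duration_s)
        if n == 0:
            continue
        t0 = np.sort(rng.uniform(0.0, scenario.duration_s, n))
        durs = draw_dwells(km.dwell, n, rng)
        keep = (rng.random(n) < scenario.labeled_fraction) if scenario.labeled_fraction < 1 \
            else np.ones(n, dtype=bool)
        for t, dur, k in zip(t0, durs, keep):
            if not k:
                continue
            x, y = sampler()
            events.append(TrueEvent(site_id, site_class, float(t), float(dur), float(x), float(y)))
    events.sort(key=lambda e: e.t_start)
    return events


def quantize_to_frames(
    events: list[TrueEvent],
    frame_interval_s: float,
    min_frames: int = 1,
    duration_s: float | None = None,
    end_handling: str = "censor",
    channel: str = "a",
) -> list[BindingEvent]:
    """Sample continuous events at the acquisition instants k*dt.

    An event occupies the acquisition instants k*dt falling inside
    [t_start, t_start + duration); events covering fewer than
    ``min_frames`` instants are dropped (detection censoring). When the
    recording length ``duration_s`` is given, events bound at the final
    instant are flagged right-censored (``end_handling='censor'``,
    default) or dropped (``'drop'``).
    """
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    if end_handling not in ("censor", "drop"):
        raise ValueError("end_handling must be 'censor' or 'drop'")
    dt = frame_interval_s
    eps = 1e-9
    n_instants = None
    if duration_s is not None:
        n_instants = int(math.floor(duration_s / dt * (1 + 1e-12))) + 1
    out: list[BindingEvent] = []
    eid = 0
    for ev in events:
        k0 = int(math.ceil(ev.t_start / dt - eps))
        kend = int(math.ceil((ev.t_start + ev.duration) / dt - eps))
        censored = False
        if n_instants is not None:
            k0 = max(k0, 0)
            if kend >= n_instants:
                censored = True
                kend = n_instants
        n = kend - k0
        if n < min_frames:
            continue
        if censored and end_handling == "drop":
            continue
        out.append(BindingEvent(
            event_id=eid, channel=channel, site_id=ev.site_id, site_class=ev.site_class,
            x_um=ev.x_um, y_um=ev.y_um, start_frame=k0, n_frames=n,
            frame_interval_s=dt, censored=censored,
        ))
        eid += 1
    return out


def simulate_dwell_sample(
    dwell: dict,
    frame_interval_s: float,
    seed: int,
    n_events: int | None = None,
    n_detected: int | None = None,
    min_frames: int = 1,
) -> DwellSample:
    """Draw dwell durations, apply uniform start phase, quantize.

    Either ``n_events`` underlying events are drawn (the detected count
    is then random) or events are drawn until exactly ``n_detected``
    survive detection (>= ``min_frames`` covered instants). The
    recording is effectively infinite, so no right censoring occurs.
    """
    if (n_events is None) == (n_detected is None):
        raise ValueError("give exactly one of n_events or n_detected")
    rng = np.random.default_rng(seed)
    dt = frame_interval_s
    counts: list[int] = []
    remaining_draws = n_events
    while True:
        batch = remaining_draws if n_events is not None else max(256, (n_detected - len(counts)) * 2)
        durs = draw_dwells(dwell, batch, rng)
        phases = rng.uniform(0.0, dt, batch)
        k = np.ceil((phases + durs) / dt - 1e-9).astype(int) - 1
        k = k[k >= min_frames]
        counts.extend(k.tolist())
        if n_events is not None:
            break
        if len(counts) >= n_detected:
            counts = counts[:n_detected]
            break
    if not counts:
        raise ValueError("no events survived detection; increase n or mean dwell")
    return DwellSample(np.asarray(counts), dt)


# ----------------------------------------------------------------------
# movie rendering
# ----------------------------------------------------------------------
def render_movie(
    events: list[TrueEvent],
    site_map: SiteMap,
    movie_params: MovieParams,
    n_frames: int,
    frame_interval_s: float,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render binding events into an image stack with ground truth.

    Each bound molecule contributes a 2-D Gaussian of ``psf_sigma_px``
    integrating to ``photons_per_spot``; a constant background is added
    and Poisson or Gaussian noise applied per frame. Returns the stack
    (frames, H, W) and a ground-truth table (frame, event_id, x_px, y_px).
    """
    mp = movie_params
    H, W = mp.image_shape
    px = mp.pixel_size_um
    for ev in events:
        if not (0 <= ev.x_um / px <= W - 1 and 0 <= ev.y_um / px <= H - 1):
            raise ValueError(f"event at ({ev.x_um}, {ev.y_um}) um outside image bounds")
    rng = np.random.default_rng(seed)
    stack = np.full((n_frames, H, W), float(mp.background_level))
    dt = frame_interval_s
    truth_rows = []
    r = int(math.ceil(4 * mp.psf_sigma_px))
    for eid, ev in enumerate(events):
        k0 = max(0, int(math.ceil(ev.t_start / dt - 1e-9)))
        kend = min(n_frames, int(math.ceil((ev.t_start + ev.duration) / dt - 1e-9)))
        if kend <= k0:
            continue
        xc, yc = ev.x_um / px, ev.y_um / px
        x0, x1 = max(0, int(xc) - r), min(W, int(xc) + r + 1)
        y0, y1 = max(0, int(yc) - r), min(H, int(yc) + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        g = np.exp(-((xx - xc) ** 2 + (yy - yc) ** 2) / (2 * mp.psf_sigma_px ** 2))
        g *= mp.photons_per_spot / (2 * np.pi * mp.psf_sigma_px ** 2)
        for k in range(k0, kend):
            stack[k, y0:y1, x0:x1] += g
            truth_rows.append({"frame": k, "event_id": eid, "x_px": xc, "y_px": yc})
    if mp.noise_model == "poisson":
        stack = rng.poisson(np.clip(stack, 0, None)).astype(float)
    elif mp.noise_model == "gaussian":
        stack = stack + rng.normal(0.0, mp.gaussian_sd, stack.shape)
    truth = pd.DataFrame(truth_rows, columns=["frame", "event_id", "x_px", "y_px"])
    return stack, truth


# ----------------------------------------------------------------------
# photobleaching traces
# ----------------------------------------------------------------------
def simulate_photobleach_traces(
    n_traces: int,
    multi_step_fraction: float,
    step_amplitude: float,
    bleach_rate_per_frame: float,
    noise_sd: float,
    n_frames: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Stepwise-bleaching intensity traces with Gaussian noise.

    A fraction ``multi_step_fraction`` of traces carries two
    fluorophores (the rest one). Each fluorophore bleaches at an
    independent geometric frame (success probability
    ``bleach_rate_per_frame``), dropping the trace by
    ``step_amplitude``. Returns (traces [n_traces, n_frames], true
    fluorophore counts). Two fluorophores bleaching in the same frame
    still count as 2 in the truth — resolving them is the counter's
    (documented) limitation.
    """
    if not (0.0 <= multi_step_fraction <= 1.0):
        raise ValueError("multi_step_fraction must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not (0.0 < bleach_rate_per_frame <= 1.0):
        raise ValueError("bleach_rate_per_frame must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_fluor = np.where(rng.random(n_traces) < multi_step_fraction, 2, 1)
    traces = np.zeros((n_traces, n_frames))
    frames = np.arange(n_frames)
    for i in range(n_traces):
        for _ in range(n_fluor[i]):
            bleach_frame = rng.geometric(bleach_rate_per_frame)  # >= 1
            traces[i] += step_amplitude * (frames < bleach_frame)
    if noise_sd > 0:
        traces += rng.normal(0.0, noise_sd, traces.shape)
    return traces, n_fluor


# ----------------------------------------------------------------------
# debranching lifetimes
# ----------------------------------------------------------------------
def simulate_debranching(
    n_branches: int,
    lifetime_model: dict,
    observation_window_s: float,
    seed: int,
) -> pd.DataFrame:
    """Branch lifetimes with right censoring at the observation window."""
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    if observation_window_s <= 0:
        raise ValueError("observation_window_s must be positive")
    rng = np.random.default_rng(seed)
    life = draw_dwells(lifetime_model, n_branches, rng)
    censored = life > observation_window_s
    life = np.minimum(life, observation_window_s)
    return pd.DataFrame({
        "branch_id": np.arange(n_branches),
        "lifetime_s": life,
        "censored": censored.astype(int),
    })


# ----------------------------------------------------------------------
# gel standards
# ----------------------------------------------------------------------
def simulate_gel_standards(
    true_coeffs: tuple[float, float],
    standard_concs,
    sample_concs,
    noise_cv: float,
    seed: int,
    species: str = "A",
) -> pd.DataFrame:
    """Stain-free gel band intensities: I = (b1 c + b2 c^2)(1 + eps).

    eps is Gaussian with CV ``noise_cv``; intensities are clipped at 0
    and the curve passes through the origin exactly (c = 0 gives 0).
    Returns a gel.csv-shaped table with known-concentration standard
    lanes followed by unknown sample lanes.
    """
    b1, b2 = true_coeffs
    if b1 < 0:
        raise ValueError("b1 must be >= 0")
    standard_concs = np.asarray(standard_concs, dtype=float)
    sample_concs = np.asarray(sample_concs, dtype=float)
    if np.any(standard_concs < 0) or np.any(sample_concs < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)

    def intensity(c):
        base = b1 * c + b2 * c ** 2
        noisy = base * (1.0 + rng.normal(0.0, noise_cv, np.shape(c)))
        return np.clip(np.where(c == 0, 0.0, noisy), 0.0, None)

    rows = []
    for i, c in enumerate(standard_concs):
        rows.append({"lane_id": f"{species}_std{i}", "species": species,
                     "conc_known": c, "raw_intensity": float(intensity(np.array(c))),
                     "background_intensity": 0.0})
    for i, c in enumerate(sample_concs):
        rows.append({"lane_id": f"{species}_sample{i}", "species": species,
                     "conc_known": np.nan, "raw_intensity": float(intensity(np.array(c))),
                     "background_intensity": 0.0})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# two-state occupancy process
# ----------------------------------------------------------------------
def simulate_two_state_occupancy(
    n_sites: int,
    duty_ratio: float,
    mean_bound_s: float,
    duration_s: float,
    frame_interval_s: float,
    seed: int,
) -> list[BindingEvent]:
    """Stationary alternating bound/unbound telegraph process per site.

    Bound intervals are exponential with mean ``mean_bound_s``; unbound
    intervals have mean ``mean_bound_s * (1 - duty) / duty`` so the
    stationary bound fraction equals ``duty_ratio``. The process starts
    in its stationary distribution; bound intervals are clipped to the
    recording and quantized at the acquisition instants.
    """
    if not (0.0 < duty_ratio < 1.0):
        raise ValueError("duty_ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    tau_b = mean_bound_s
    tau_u = mean_bound_s * (1.0 - duty_ratio) / duty_ratio
    true_events: list[TrueEvent] = []
    for s in range(n_sites):
        t = 0.0
        bound = rng.random() < duty_ratio
        while t < duration_s:
            if bound:
                dur = rng.exponential(tau_b)
                end = min(t + dur, duration_s + frame_interval_s)
                true_events.append(TrueEvent(
                    site_id=f"site{s}", site_class="branch",
                    t_start=t, duration=end - t if end > t else 1e-12,
                ))
                t += dur
            else:
                t += rng.exponential(tau_u)
            bound = not bound
    return quantize_to_frames(true_events, frame_interval_s, min_frames=1,
                              duration_s=duration_s, end_handling="censor")
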