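"""Table/image readers and writers, run configuration, pipeline driver.

Public schemas use seconds, micrometres and arbitrary intensity units;
frames are 0-based and event time intervals half-open. Floating-point
table output is serialised at fixed precision so every artifact is
regenerable bit-identically from config + inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .dwell import DwellSample, bootstrap_se, fit_exponential, fit_two_exponential
from .events import EVENT_COLUMNS
from .geometry import SiteMap
from .sites import count_sites, occupancy
from .branches import branch_survival

log = logging.getLogger("tirfkin")

FLOAT_FORMAT = "%.9g"

REQUIRED_EVENT_COLS = EVENT_COLUMNS
REQUIRED_TRACE_COLS = ["trace_id", "frame", "time_s", "intensity"]
REQUIRED_GEL_COLS = ["lane_id", "species", "conc_known", "raw_intensity", "background_intensity"]
REQUIRED_BRANCH_COLS = ["branch_id", "condition", "trial", "fov", "event_type", "time_s", "censored"]


def _check_columns(frame: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{what} table missing required columns: {missing}")


def read_events(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _check_columns(frame, REQUIRED_EVENT_COLS, "events")
    return frame


def write_events(frame: pd.DataFrame, path) -> None:
    _check_columns(frame, REQUIRED_EVENT_COLS, "events")
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_sites(path, extent_um=(50.0, 50.0)) -> SiteMap:
    return SiteMap.from_frame(pd.read_csv(path), extent_um=extent_um)


def write_sites(site_map: SiteMap, path) -> None:
    site_map.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_traces(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _check_columns(frame, REQUIRED_TRACE_COLS, "traces")
    return frame


def write_traces(traces: np.ndarray, frame_interval_s: float, path) -> None:
    """Write an (n_traces, n_frames) intensity array in traces.csv layout."""
    n_traces, n_frames = traces.shape
    tid = np.repeat(np.arange(n_traces), n_frames)
    fr = np.tile(np.arange(n_frames), n_traces)
    pd.DataFrame({
        "trace_id": tid,
        "frame": fr,
        "time_s": fr * frame_interval_s,
        "intensity": traces.ravel(),
    }).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def traces_to_array(frame: pd.DataFrame) -> np.ndarray:
    return frame.pivot(index="trace_id", columns="frame", values="intensity").to_numpy()


def read_gel(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _check_columns(frame, REQUIRED_GEL_COLS, "gel")
    return frame


def read_branches(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _check_columns(frame, REQUIRED_BRANCH_COLS, "branches")
    return frame


def read_stack(path) -> np.ndarray:
    return tifffile.imread(path)


def write_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------
@dataclass
class RunConfig:
    """Configuration for a pipeline run; round-trips losslessly."""

    seed: int = 0
    frame_interval_s: float = 0.25
    pixel_size_um: float = 0.27
    box_area_um2: float = 1.14
    site_density_per_um: float = 370.0
    n_boot: int = 10000
    estimator: str = "phase_marginalized"
    model: str = "1exp"          # 1exp | 2exp | both
    duration_s: float = 120.0
    # simulation kinetics for the `simulate` stage
    arrival_rate: float = 0.05
    dwell: dict = field(default_factory=lambda: {"tau": 0.46})
    n_filaments: int = 4
    filament_length_um: float = 10.0
    n_branch_sites: int = 8
    extent_um: float = 50.0
    input_dir: str = "."
    output_dir: str = "."

    def __post_init__(self) -> None:
        for name in ("frame_interval_s", "pixel_size_um", "box_area_um2",
                     "site_density_per_um", "duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def read_config(path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        d = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
    return RunConfig.from_dict(d)


def write_config(config: RunConfig, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yml", ".yaml"):
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        else:
            json.dump(config.to_dict(), fh, indent=2, sort_keys=True)


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------
STAGE_DEPS = {
    "simulate": [],
    "fit-dwell": ["simulate"],
    "occupancy": ["simulate"],
    "survival": [],
}


def _provenance(config: RunConfig) -> dict:
    return {"config_hash": config.config_hash, "seed": config.seed, "version": __version__}


def run_pipeline(config: RunConfig, stages: list[str], out_dir=None) -> dict:
    """Run a chain of analysis stages, writing JSON/CSV artifacts.

    Stage dependencies must be satisfied either earlier in the stage
    list or by files already present in the output directory; this is
    validated before anything executes. Every JSON artifact records the
    config hash, seed and package version.
    """
    from . import synthetic  # deferred: synthetic imports events/dwell

    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in stages:
        if s not in STAGE_DEPS:
            raise ValueError(f"unknown stage {s!r}; choose from {sorted(STAGE_DEPS)}")
    seen: set[str] = set()
    for s in stages:
        for dep in STAGE_DEPS[s]:
            if dep not in seen and not (out / "events.csv").exists():
                raise ValueError(f"stage {s!r} requires {dep!r} earlier in the stage list")
        seen.add(s)

    results: dict = {}
    for s in stages:
        log.info("stage %s starting", s)
        if s == "simulate":
            results[s] = _stage_simulate(config, out)
        elif s == "fit-dwell":
            results[s] = _stage_fit_dwell(config, out)
        elif s == "occupancy":
            results[s] = _stage_occupancy(config, out)
        elif s == "survival":
            results[s] = _stage_survival(config, out)
        log.info("stage %s done", s)
    return results


def _default_site_map(config: RunConfig) -> SiteMap:
    rng = np.random.default_rng(config.seed + 1)
    filaments = []
    for _ in range(config.n_filaments):
        x0 = rng.uniform(5, config.extent_um - 5 - config.filament_length_um)
        y0 = rng.uniform(5, config.extent_um - 5)
        filaments.append(np.array([[x0, y0], [x0 + config.filament_length_um, y0]]))
    branches = []
    for _ in range(config.n_branch_sites):
        f = rng.integers(0, config.n_filaments)
        arc = rng.uniform(0.0, config.filament_length_um)
        branches.append([filaments[f][0, 0] + arc, filaments[f][0, 1]])
    return SiteMap(filaments=filaments, branches=np.array(branches),
                   extent_um=(config.extent_um, config.extent_um))


def _stage_simulate(config: RunConfig, out: Path) -> dict:
    from .synthetic import KineticModel, SimScenario, quantize_to_frames, simulate_binding_events
    from .events import events_to_frame

    site_map = _default_site_map(config)
    scenario = SimScenario(
        seed=config.seed,
        duration_s=config.duration_s,
        frame_interval_s=config.frame_interval_s,
        site_map=site_map,
        kinetics_per_class={
            "side": KineticModel(config.arrival_rate, config.dwell),
            "branch": KineticModel(config.arrival_rate, config.dwell),
        },
    )
    true_events = simulate_binding_events(scenario)
    observed = quantize_to_frames(true_events, config.frame_interval_s,
                                  duration_s=config.duration_s)
    frame = events_to_frame(observed)
    write_events(frame, out / "events.csv")
    write_sites(site_map, out / "sites.csv")
    info = {**_provenance(config), "n_true_events": len(true_events),
            "n_observed_events": len(frame)}
    (out / "simulate.json").write_text(json.dumps(info, indent=2, sort_keys=True))
    return info


def _events_sample(config: RunConfig, out: Path) -> DwellSample:
    frame = read_events(out / "events.csv")
    return DwellSample(
        frame["n_frames"].to_numpy(dtype=int),
        config.frame_interval_s,
        frame["censored"].to_numpy(dtype=bool),
    )


def _stage_fit_dwell(config: RunConfig, out: Path) -> dict:
    sample = _events_sample(config, out)
    info: dict = {**_provenance(config), "n_events": sample.n,
                  "estimator": config.estimator}
    if config.model in ("1exp", "both"):
        fit = fit_exponential(sample, config.estimator)
        boot = bootstrap_se(sample, lambda s: fit_exponential(s, config.estimator),
                            n_boot=config.n_boot, seed=config.seed + 2)
        info["1exp"] = {"tau": fit.tau, "loglik": fit.loglik, "se_tau": boot["se"]["tau"]}
    if config.model in ("2exp", "both"):
        fit2 = fit_two_exponential(sample, config.estimator, seed=config.seed + 3)
        init = (fit2.t_short, fit2.t_long, fit2.frac_long)
        boot2 = bootstrap_se(
            sample,
            lambda s: fit_two_exponential(s, config.estimator, n_starts=1,
                                          seed=config.seed + 3, init=init),
            n_boot=min(config.n_boot, 1000), seed=config.seed + 4,
        )
        info["2exp"] = {
            "t_short": fit2.t_short, "t_long": fit2.t_long, "frac_long": fit2.frac_long,
            "loglik": fit2.loglik, "se": boot2["se"],
        }
    (out / "dwell_fit.json").write_text(json.dumps(info, indent=2, sort_keys=True))
    from .dwell import survival_curve
    curve = survival_curve(_events_sample(config, out))
    pd.DataFrame({"time_s": curve.times, "survival": curve.survival}).to_csv(
        out / "survival.csv", index=False, float_format=FLOAT_FORMAT)
    return info


def _stage_occupancy(config: RunConfig, out: Path) -> dict:
    frame = read_events(out / "events.csv")
    site_map = read_sites(out / "sites.csv", extent_um=(config.extent_um, config.extent_um))
    info: dict = {**_provenance(config)}
    for cls in ("side", "branch"):
        sub = frame[frame["site_class"] == cls]
        n_sites = count_sites(site_map, cls, config.site_density_per_um)
        if n_sites < 1:
            continue
        occ = occupancy(sub, n_sites, config.duration_s, config.frame_interval_s,
                        site_class=cls)
        info[cls] = {"occupancy": occ.occupancy, "n_sites": occ.n_sites,
                     "total_bound_s": occ.total_bound_s, "n_events": int(len(sub))}
    (out / "occupancy.json").write_text(json.dumps(info, indent=2, sort_keys=True))
    return info


def _stage_survival(config: RunConfig, out: Path) -> dict:
    frame = read_branches(Path(config.input_dir) / "branches.csv")
    deb = frame[frame["event_type"] == "debranch"].rename(columns={"time_s": "lifetime_s"})
    times = np.arange(0.0, deb["lifetime_s"].max() + 10.0, 10.0)
    curves = branch_survival(deb, times)
    rows = []
    for cond, c in curves.items():
        for t, m, sem in zip(c["times"], c["mean"], c["sem"]):
            rows.append({"condition": cond, "time_s": t, "survival": m, "sem": sem})
    pd.DataFrame(rows).to_csv(out / "branch_survival.csv", index=False,
                              float_format=FLOAT_FORMAT)
    info = {**_provenance(config), "conditions": sorted(curves)}
    (out / "survival.json").write_text(json.dumps(info, indent=2, sort_keys=True))
    return info
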