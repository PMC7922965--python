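"""Configuration, figure presets, and plain-text readers/writers.

All files are text: trajectories as TSV (time, x, state), densities and
histograms as CSV with '#'-prefixed metadata headers carrying the seed,
model parameters and any point masses.  Configs are YAML or JSON documents;
physical quantities are in consistent arbitrary units (time, length^2/time).
"""

from __future__ import annotations

import io as _io
import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .simulate import (
    ModelParams,
    TrajectoryGrid,
    sample_endpoint_ensemble,
    simulate_path,
)
from .waiting_times import ConfigurationError, sojourn_from_spec
from . import occupation as occ
from . import propagator as prop
from . import tamsd as _tamsd

__all__ = [
    "RunConfig",
    "load_config",
    "model_from_spec",
    "model_spec",
    "FIGURE_PRESETS",
    "preset_model",
    "reproduce_figure",
    "write_trajectory",
    "read_trajectory",
    "write_density_csv",
    "read_density_csv",
    "write_endpoints_csv",
]

EXPERIMENTS = ("simulate", "occupation-pdf", "propagator", "tamsd", "msd", "reproduce-figure")


def model_from_spec(spec: dict) -> ModelParams:
    """Build a ModelParams from a config mapping.

    Required keys: D_plus, D_minus, dist_plus, dist_minus; optional
    initial_condition (default equilibrium).
    """
    if not isinstance(spec, dict):
        raise ConfigurationError(f"model spec must be a mapping, got {type(spec).__name__}")
    for key in ("D_plus", "D_minus", "dist_plus", "dist_minus"):
        if key not in spec:
            raise ConfigurationError(f"model spec missing required field {key!r}")
    return ModelParams(
        D_plus=float(spec["D_plus"]),
        D_minus=float(spec["D_minus"]),
        dist_plus=sojourn_from_spec(spec["dist_plus"]),
        dist_minus=sojourn_from_spec(spec["dist_minus"]),
        initial_condition=spec.get("initial_condition", "equilibrium"),
    )


def model_spec(params: ModelParams) -> dict:
    return {
        "D_plus": params.D_plus,
        "D_minus": params.D_minus,
        "dist_plus": params.dist_plus.spec(),
        "dist_minus": params.dist_minus.spec(),
        "initial_condition": params.initial_condition,
    }


# ---------------------------------------------------------------------------
# Figure presets: the parameter sets behind the package's reference figures.
# Immutable: each entry is rebuilt on access.

def _exp_model(tau_p, tau_m, D_plus=10.0, D_minus=0.0):
    return {
        "D_plus": D_plus,
        "D_minus": D_minus,
        "dist_plus": {"family": "exponential", "params": {"mean": tau_p}},
        "dist_minus": {"family": "exponential", "params": {"mean": tau_m}},
    }


FIGURE_PRESETS: Dict[str, dict] = {
    # short-time tent vs simulation: uniform sojourns U(0,5)/U(0,10), t=1
    "fig3_left_uniform": {
        "model": {
            "D_plus": 10.0,
            "D_minus": 0.0,
            "dist_plus": {"family": "uniform", "params": {"a": 0.0, "b": 5.0}},
            "dist_minus": {"family": "uniform", "params": {"a": 0.0, "b": 10.0}},
        },
        "t": 1.0,
    },
    # short-time tent: gamma sojourns Gamma(0.5,8)/Gamma(0.5,12), t=2
    "fig3_left_gamma": {
        "model": {
            "D_plus": 10.0,
            "D_minus": 0.0,
            "dist_plus": {"family": "gamma", "params": {"shape": 0.5, "scale": 8.0}},
            "dist_minus": {"family": "gamma", "params": {"shape": 0.5, "scale": 12.0}},
        },
        "t": 2.0,
    },
    # long-time Gaussian limits of the same models
    "fig3_right_uniform": {
        "model": {
            "D_plus": 10.0,
            "D_minus": 0.0,
            "dist_plus": {"family": "uniform", "params": {"a": 0.0, "b": 5.0}},
            "dist_minus": {"family": "uniform", "params": {"a": 0.0, "b": 10.0}},
        },
        "t": 30.0,
    },
    "fig3_right_gamma": {
        "model": {
            "D_plus": 10.0,
            "D_minus": 0.0,
            "dist_plus": {"family": "gamma", "params": {"shape": 2.0, "scale": 1.0}},
            "dist_minus": {"family": "gamma", "params": {"shape": 8.0, "scale": 1.0}},
        },
        "t": 30.0,
    },
    # occupation-fraction laws, equal-means exponential
    "fig4": {"model": _exp_model(1.0, 1.0), "t": 0.1,
             "t_panel": [0.1, 0.5, 1.0, 2.0, 5.0, 10.0]},
    # equal-means propagator: tent at short t, Gaussian at long t
    "fig5": {"model": _exp_model(1.0, 1.0), "t_short": [0.1, 0.5], "t_long": [5.0, 10.0]},
    # unequal-means occupation-fraction laws
    "fig6": {"model": _exp_model(1.0, 5.0), "t": 0.1,
             "t_panel": [0.1, 0.5, 2.0, 5.0, 10.0, 20.0]},
    # unequal-means propagator
    "fig7": {"model": _exp_model(1.0, 5.0), "t_short": [0.1, 0.5], "t_long": [20.0, 30.0]},
    # TAMSD diffusivity distributions
    "fig8_equal": {"model": _exp_model(1.0, 1.0), "t": 1000.0, "n_traj": 1000},
    "fig8_unequal": {"model": _exp_model(1.0, 5.0), "t": 1000.0, "n_traj": 1000},
}


def preset_model(name: str) -> ModelParams:
    if name not in FIGURE_PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(FIGURE_PRESETS)}"
        )
    return model_from_spec(FIGURE_PRESETS[name]["model"])


@dataclass
class RunConfig:
    """Validated top-level run description (file values, CLI may override)."""

    experiment: str
    model: Optional[ModelParams] = None
    t: Optional[float] = None
    dt: Optional[float] = None
    n_traj: int = 1
    seed: int = 0
    out: Optional[str] = None
    fixture: Optional[str] = None

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ConfigurationError(
                f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}"
            )
        if self.model is None and self.fixture is None:
            raise ConfigurationError("config requires either 'model' or 'fixture'")
        if self.model is None:
            self.model = preset_model(self.fixture)


def load_config(path, overrides: Optional[dict] = None) -> RunConfig:
    """Load and validate a YAML/JSON run config; overrides win over the file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError("config document must be a mapping")
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
    if "experiment" not in raw:
        raise ConfigurationError("config missing required field 'experiment'")
    model = model_from_spec(raw["model"]) if "model" in raw else None
    known = {"experiment", "model", "t", "dt", "n_traj", "seed", "out", "fixture"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
    return RunConfig(
        experiment=raw["experiment"],
        model=model,
        t=raw.get("t"),
        dt=raw.get("dt"),
        n_traj=int(raw.get("n_traj", 1)),
        seed=int(raw.get("seed", 0)),
        out=raw.get("out"),
        fixture=raw.get("fixture"),
    )


# ---------------------------------------------------------------------------
# Writers / readers (lossless to double precision: %.17g)

_FMT = "%.17g"


def _write_with_header(path, header_lines: Sequence[str], frame: pd.DataFrame, sep: str):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep=sep, index=False, float_format=_FMT)


def _meta_header(seed=None, params: Optional[ModelParams] = None, **extra) -> List[str]:
    lines = []
    if seed is not None:
        lines.append(f"seed: {seed}")
    if params is not None:
        lines.append("model: " + json.dumps(model_spec(params)))
    for k, v in extra.items():
        lines.append(f"{k}: {json.dumps(v) if isinstance(v, (dict, list)) else v}")
    return lines


def write_trajectory(path, traj: TrajectoryGrid, *, seed=None, params=None):
    frame = pd.DataFrame({"time": traj.times, "x": traj.positions, "state": traj.states})
    _write_with_header(path, _meta_header(seed=seed, params=params), frame, sep="\t")


def read_trajectory(path) -> TrajectoryGrid:
    frame = pd.read_csv(path, sep="\t", comment="#")
    states = frame["state"].to_numpy() if "state" in frame else np.full(len(frame), "?")
    return TrajectoryGrid(
        times=frame["time"].to_numpy(float),
        positions=frame["x"].to_numpy(float),
        states=states,
    )


def write_density_csv(path, x, density, *, atoms: Optional[dict] = None, seed=None,
                      params=None, columns=("x", "density"), **extra):
    header = _meta_header(seed=seed, params=params, **extra)
    if atoms:
        for k, v in atoms.items():
            header.append(f"{k}: {v!r}")
    frame = pd.DataFrame({columns[0]: np.asarray(x), columns[1]: np.asarray(density)})
    _write_with_header(path, header, frame, sep=",")


def read_density_csv(path):
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition(":")
            meta[key.strip()] = val.strip()
    frame = pd.read_csv(path, comment="#")
    return frame, meta


def write_endpoints_csv(path, x, T_plus, N, start_plus, *, seed=None, params=None):
    frame = pd.DataFrame(
        {
            "x": np.asarray(x),
            "T_plus": np.asarray(T_plus),
            "N": np.asarray(N),
            "start_state": np.where(np.asarray(start_plus, bool), "+", "-"),
        }
    )
    _write_with_header(path, _meta_header(seed=seed, params=params), frame, sep=",")


# ---------------------------------------------------------------------------
# Figure reproduction: simulation histograms + analytic curves as CSV pairs.

_FIG_NAMES = ("fig3_left", "fig3_right", "fig4", "fig5", "fig6", "fig7", "fig8")


def _endpoint_histogram(params, t, n, rng, n_bins=61):
    x = sample_endpoint_ensemble(params, t, n, rng)
    lim = 8.0 * np.sqrt(2 * params.D_plus * t)
    edges = np.linspace(-lim, lim, n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = counts / (n * (edges[1] - edges[0]))
    return centers, dens


def _xgrid(params, t, n=801):
    lim = 8.0 * np.sqrt(2 * params.D_plus * t)
    return np.linspace(-lim, lim, n)


def _check_out(out_dir, force):
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty; pass force=True to overwrite")
    out_dir.mkdir(parents=True, exist_ok=True)
    return out_dir


def reproduce_figure(
    name: str, out_dir, rng: np.random.Generator, *, n_endpoints: int = 100_000,
    force: bool = False, seed=None,
) -> List[Path]:
    """Write the simulation histograms and analytic curves behind one figure.

    Outputs are CSV files with x (and the diffusive rescaling z = x/sqrt(t))
    or p+ columns; point masses travel in the header metadata, never binned
    into the density.  Ensemble sizes are reduced relative to the original
    runs; pass ``n_endpoints`` to change them.
    """
    if name not in _FIG_NAMES:
        raise ConfigurationError(f"unknown figure {name!r}; available: {_FIG_NAMES}")
    out_dir = _check_out(out_dir, force)
    written: List[Path] = []

    def emit(fname, x, dens, params=None, t=None, atoms=None, with_z=False):
        path = out_dir / fname
        header = _meta_header(seed=seed, params=params, t=t)
        if atoms:
            header += [f"{k}: {v!r}" for k, v in atoms.items()]
        cols = {"x": x, "density": dens}
        if with_z and t:
            cols = {"x": x, "z": x / np.sqrt(t), "density": dens}
        _write_with_header(path, header, pd.DataFrame(cols), sep=",")
        written.append(path)

    if name in ("fig3_left", "fig3_right"):
        side = "left" if name.endswith("left") else "right"
        for flavor in ("uniform", "gamma"):
            preset = FIGURE_PRESETS[f"fig3_{side}_{flavor}"]
            params, t = model_from_spec(preset["model"]), preset["t"]
            cx, cd = _endpoint_histogram(params, t, n_endpoints, rng)
            emit(f"{name}_{flavor}_sim.csv", cx, cd, params, t)
            xg = _xgrid(params, t)
            if side == "left":
                pdf = prop.propagator_short_time(params, t)
                emit(f"{name}_{flavor}_theory.csv", xg, pdf.density(xg), params, t,
                     atoms={"atom_at_zero": pdf.atom_at_zero})
            else:
                pdf = prop.propagator_long_time(params, t)
                emit(f"{name}_{flavor}_theory.csv", xg, pdf.density(xg), params, t)
        return written

    if name in ("fig4", "fig6"):
        preset = FIGURE_PRESETS[name]
        params = model_from_spec(preset["model"])
        tp, tm = params.mean_plus, params.mean_minus
        p = np.linspace(0.005, 0.995, 199)
        gshort = occ.g_short_time(params, preset["t"])
        path = out_dir / f"{name}_short_time_overlay.csv"
        _write_with_header(
            path,
            _meta_header(seed=seed, params=params, t=preset["t"]) + [
                f"uniform_atoms: ({gshort.atom0!r}, {gshort.atom1!r})",
            ],
            pd.DataFrame({
                "p_plus": p,
                "density_exact": occ.g_exact_exponential(tp, tm, preset["t"]).density(p),
                "density_uniform": gshort.density(p),
            }),
            sep=",",
        )
        written.append(path)
        for t in preset["t_panel"]:
            g = occ.g_exact_exponential(tp, tm, t)
            path = out_dir / f"{name}_exact_t{t:g}.csv"
            _write_with_header(
                path,
                _meta_header(seed=seed, params=params, t=t)
                + [f"atom0: {g.atom0!r}", f"atom1: {g.atom1!r}"],
                pd.DataFrame({"p_plus": p, "density": g.density(p)}),
                sep=",",
            )
            written.append(path)
        return written

    if name in ("fig5", "fig7"):
        preset = FIGURE_PRESETS[name]
        params = model_from_spec(preset["model"])
        for t in preset["t_short"]:
            pdf = prop.propagator_short_time(params, t, exponential_weights=True)
            xg = _xgrid(params, t)
            emit(f"{name}_tent_t{t:g}.csv", xg, pdf.density(xg), params, t,
                 atoms={"atom_at_zero": pdf.atom_at_zero}, with_z=True)
            cx, cd = _endpoint_histogram(params, t, n_endpoints, rng)
            emit(f"{name}_sim_t{t:g}.csv", cx, cd, params, t, with_z=True)
        for t in preset["t_long"]:
            pdf = prop.propagator_long_time(params, t)
            xg = _xgrid(params, t)
            emit(f"{name}_gauss_t{t:g}.csv", xg, pdf.density(xg), params, t, with_z=True)
            cx, cd = _endpoint_histogram(params, t, n_endpoints, rng)
            emit(f"{name}_sim_t{t:g}.csv", cx, cd, params, t, with_z=True)
        return written

    # fig8: TAMSD diffusivity histograms, both sojourn-mean settings
    for tag in ("equal", "unequal"):
        preset = FIGURE_PRESETS[f"fig8_{tag}"]
        params = model_from_spec(preset["model"])
        n_traj = min(preset["n_traj"], max(1, n_endpoints // 100))
        dist = _tamsd.diffusivity_distribution(
            params, preset["t"], None, n_traj, rng=rng
        )
        centers = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
        path = out_dir / f"fig8_{tag}_pD.csv"
        _write_with_header(
            path,
            _meta_header(seed=seed, params=params, t=preset["t"])
            + [f"mean_D: {dist.mean!r}", f"n_traj: {n_traj}"],
            pd.DataFrame({"D": centers, "density": dist.density}),
            sep=",",
        )
        written.append(path)
    return written
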