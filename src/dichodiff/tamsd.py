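"""Time-averaged MSD analysis and per-trajectory diffusivity estimation.

Single-particle-tracking practice estimates a diffusivity per trajectory
from the small-lag slope of the time-averaged mean squared displacement

    tamsd(lag) = mean over windows of [x(t' + lag) - x(t')]^2,

fitting tamsd = 2 D lag through the origin.  Over an ensemble of two-state
trajectories the fitted values spread around the state diffusivities and
their mean converges to (D+<tau>+ + D-<tau>-)/(<tau>+ + <tau>-).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .simulate import ModelParams, TrajectoryGrid, simulate_path

__all__ = [
    "TamsdResult",
    "DiffusivityDistribution",
    "tamsd_curve",
    "fit_diffusivity",
    "diffusivity_distribution",
    "default_grid_step",
    "default_fit_window",
]


@dataclass
class TamsdResult:
    lags: np.ndarray
    values: np.ndarray
    fitted_D: Optional[float] = None
    fit_window: Optional[Tuple[float, float]] = None


@dataclass
class DiffusivityDistribution:
    """Empirical law of TAMSD-fitted diffusivities over an ensemble."""

    fitted_D: np.ndarray
    bin_edges: np.ndarray
    density: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.fitted_D))


def tamsd_curve(traj: TrajectoryGrid, lags: Sequence[float]) -> TamsdResult:
    """Sliding-window TAMSD at the requested lag times.

    Lags must be (near-)multiples of the grid step and smaller than the
    trajectory span; every window is used.
    """
    dt = traj.dt
    x = traj.positions
    lags = np.asarray(lags, dtype=float)
    if lags.size == 0:
        raise ValueError("need at least one lag")
    steps = np.rint(lags / dt).astype(int)
    if np.any(np.abs(steps * dt - lags) > 1e-9 * max(dt, 1.0)) or np.any(steps < 1):
        raise ValueError("lags must be positive multiples of the grid step dt")
    if np.any(steps >= x.size):
        raise ValueError("lags must be smaller than the trajectory length")
    values = np.empty(lags.size)
    for i, m in enumerate(steps):
        d = x[m:] - x[:-m]
        values[i] = np.mean(d * d)
    return TamsdResult(lags=steps * dt, values=values)


def fit_diffusivity(
    result: TamsdResult, window: Optional[Tuple[float, float]] = None
) -> float:
    """Least-squares slope fit tamsd = 2 D lag through the origin.

    ``window`` restricts the fit to lags in [wmin, wmax]; D is clipped at 0.
    """
    lags, values = result.lags, result.values
    if window is not None:
        keep = (lags >= window[0] - 1e-12) & (lags <= window[1] + 1e-12)
        lags, values = lags[keep], values[keep]
    if lags.size == 0:
        raise ValueError("fit window contains no lags")
    D = float(np.dot(values, lags) / (2.0 * np.dot(lags, lags)))
    D = max(D, 0.0)
    result.fitted_D = D
    result.fit_window = (float(lags.min()), float(lags.max()))
    return D


def default_grid_step(params: ModelParams) -> float:
    """Grid step resolving the faster state: 0.01 * min(<tau>+, <tau>-)."""
    return 0.01 * min(params.mean_plus, params.mean_minus)


def default_fit_window(t: float, dt: float) -> Tuple[float, float]:
    """Short-lag window [dt, t/100]: keeps TAMSD points weakly correlated."""
    return dt, t / 100.0


def _default_lags(t: float, dt: float, n_lags: int = 20) -> np.ndarray:
    lo, hi = default_fit_window(t, dt)
    steps = np.unique(np.rint(np.geomspace(1, hi / dt, n_lags)).astype(int))
    return steps * dt


def diffusivity_distribution(
    params: ModelParams,
    t: float,
    dt: Optional[float],
    n_traj: int,
    window: Optional[Tuple[float, float]] = None,
    rng: Optional[np.random.Generator] = None,
    *,
    lags: Optional[Sequence[float]] = None,
    n_bins: int = 30,
) -> DiffusivityDistribution:
    """Simulate n_traj paths, TAMSD-fit each, return the empirical D law.

    The histogram uses ``n_bins`` equal-width bins over [0, D+]; the mean is
    reported from the raw fitted values, independent of binning.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    if dt is None:
        dt = default_grid_step(params)
    if window is None:
        window = default_fit_window(t, dt)
    if lags is None:
        lags = _default_lags(t, dt)
    fitted = np.empty(n_traj)
    for i in range(n_traj):
        traj = simulate_path(params, t, dt, rng)
        fitted[i] = fit_diffusivity(tamsd_curve(traj, lags), window)
    edges = np.linspace(0.0, params.D_plus, n_bins + 1)
    counts, _ = np.histogram(fitted, bins=edges)
    width = edges[1] - edges[0]
    density = counts / (n_traj * width)
    return DiffusivityDistribution(fitted_D=fitted, bin_edges=edges, density=density)
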