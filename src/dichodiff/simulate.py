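"""Monte-Carlo simulation of the alternating two-state diffusivity process.

The diffusion coefficient D(t) alternates between D+ and D- at renewal
epochs; sojourn durations in each state are i.i.d. draws from the state's
law.  Under the equilibrium initial condition the process started long
before observation: the starting state is chosen with probability
proportional to its mean sojourn time and the first observed sojourn
follows the forward-recurrence law.  Positions follow dx = sqrt(2 D(t)) dW,
so the endpoint displacement conditioned on the occupation times is
Gaussian with variance 2 D+ T+ + 2 D- T-.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .waiting_times import SojournDistribution

__all__ = [
    "ModelParams",
    "RenewalRealization",
    "TrajectoryGrid",
    "draw_initial_state",
    "simulate_renewal",
    "sample_endpoint",
    "simulate_path",
    "sample_occupation_ensemble",
    "sample_endpoint_ensemble",
]

PLUS, MINUS = "plus", "minus"
_INITIAL_MODES = ("equilibrium", "ordinary_from_plus", "ordinary_from_minus")


@dataclass(frozen=True)
class ModelParams:
    """Full two-state model specification.

    D_plus, D_minus : diffusivities (length^2/time), D_plus > D_minus >= 0
    dist_plus, dist_minus : sojourn laws of the fast and slow states
    initial_condition : 'equilibrium' (default), 'ordinary_from_plus' or
        'ordinary_from_minus'; the ordinary modes start a fresh renewal
        sequence at t=0 in the named state.
    """

    D_plus: float
    D_minus: float
    dist_plus: SojournDistribution
    dist_minus: SojournDistribution
    initial_condition: str = "equilibrium"

    def __post_init__(self):
        # convention: '+' is the fast state; equality is allowed so the
        # degenerate single-diffusivity limit stays expressible
        if not (self.D_plus > 0 and self.D_plus >= self.D_minus >= 0):
            raise ValueError("require D_plus > 0 and D_plus >= D_minus >= 0")
        for d in (self.dist_plus, self.dist_minus):
            if not (math.isfinite(d.mean) and d.mean > 0):
                raise ValueError("both sojourn means must be finite and positive")
        if self.initial_condition not in _INITIAL_MODES:
            raise ValueError(f"initial_condition must be one of {_INITIAL_MODES}")

    @property
    def mean_plus(self) -> float:
        return self.dist_plus.mean

    @property
    def mean_minus(self) -> float:
        return self.dist_minus.mean

    @property
    def stationary_plus_fraction(self) -> float:
        """Equilibrium probability of observing the fast state."""
        return self.mean_plus / (self.mean_plus + self.mean_minus)


@dataclass
class RenewalRealization:
    """One realized alternating sequence up to measurement time t."""

    start_state: str
    sojourns: List[Tuple[str, float]]  # completed sojourns in order
    backward_recurrence: float  # tau* = t - t_N, elapsed part of the open sojourn
    T_plus: float
    T_minus: float
    N: int  # number of completed sojourns (= transitions performed)
    t: float

    @property
    def occupation_fraction(self) -> float:
        return self.T_plus / self.t


@dataclass
class TrajectoryGrid:
    """Displacement path on a uniform time grid; x(0) = 0."""

    times: np.ndarray
    positions: np.ndarray
    states: np.ndarray  # '+' or '-' at each grid point

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def draw_initial_state(params: ModelParams, rng: np.random.Generator) -> str:
    if params.initial_condition == "ordinary_from_plus":
        return PLUS
    if params.initial_condition == "ordinary_from_minus":
        return MINUS
    return PLUS if rng.random() < params.stationary_plus_fraction else MINUS


def _draw_switch_times(
    params: ModelParams, t: float, rng: np.random.Generator
) -> Tuple[str, np.ndarray]:
    """Switch epochs 0 < t_1 < ... <= last > t for one realization.

    Returns (start_state, switch_times) where the final epoch is the first
    one exceeding t (the open sojourn).  Draws are made in blocks so long
    observation windows stay cheap.
    """
    start = draw_initial_state(params, rng)
    dist0 = params.dist_plus if start == PLUS else params.dist_minus
    dist1 = params.dist_minus if start == PLUS else params.dist_plus
    if params.initial_condition == "equilibrium":
        first = float(dist0.sample_forward_recurrence(rng))
    else:
        first = float(dist0.sample(rng))
    epochs = [np.array([first])]
    total = first
    mean_cycle = params.mean_plus + params.mean_minus
    while total < t:
        # expected remaining switches, with slack; at least a handful
        n_pairs = max(4, int(1.5 * (t - total) / mean_cycle) + 2)
        a = dist1.sample(rng, n_pairs)
        b = dist0.sample(rng, n_pairs)
        block = np.empty(2 * n_pairs)
        block[0::2], block[1::2] = a, b
        epochs.append(total + np.cumsum(block))
        total = float(epochs[-1][-1])
    times = np.concatenate(epochs)
    cut = int(np.searchsorted(times, t, side="right"))
    return start, times[: cut + 1]


def simulate_renewal(
    params: ModelParams, t: float, rng: np.random.Generator
) -> RenewalRealization:
    """One realization of the alternating sequence truncated at time t."""
    if not t > 0:
        raise ValueError("measurement time t must be > 0")
    start, switches = _draw_switch_times(params, t, rng)
    completed = switches[:-1]  # epochs <= t
    n = completed.size
    durations = np.diff(np.concatenate([[0.0], completed]))
    states = [start if i % 2 == 0 else (MINUS if start == PLUS else PLUS) for i in range(n)]
    tau_star = t - (completed[-1] if n else 0.0)
    open_state = states[-1] if n else start
    open_state = (MINUS if open_state == PLUS else PLUS) if n else start
    T_plus = float(np.sum(durations[np.array([s == PLUS for s in states], bool)])) if n else 0.0
    if open_state == PLUS:
        T_plus += tau_star
    return RenewalRealization(
        start_state=start,
        sojourns=list(zip(states, durations.tolist())),
        backward_recurrence=float(tau_star),
        T_plus=T_plus,
        T_minus=t - T_plus,
        N=n,
        t=float(t),
    )


def sample_endpoint(
    params: ModelParams, realization: RenewalRealization, rng: np.random.Generator
) -> float:
    """One endpoint displacement draw conditioned on the realization.

    x = sqrt(2 D+ T+ + 2 D- T-) * xi with xi standard normal; with D- = 0
    this is exactly the product form sqrt(2 D+ T+) * xi.
    """
    var = 2.0 * (params.D_plus * realization.T_plus + params.D_minus * realization.T_minus)
    return math.sqrt(var) * rng.standard_normal()


def simulate_path(
    params: ModelParams, t: float, dt: float, rng: np.random.Generator
) -> TrajectoryGrid:
    """Exact-in-distribution path on a uniform grid of step dt.

    The Gaussian step variance integrates D(t) exactly across the step from
    the underlying renewal sequence, so state switches inside a step are
    honored rather than rounded to grid points.
    """
    if not dt > 0:
        raise ValueError("grid step dt must be > 0")
    if dt > t:
        raise ValueError("grid step dt must not exceed t")
    n_steps = int(round(t / dt))
    if abs(n_steps * dt - t) > 1e-9 * max(t, 1.0):
        n_steps = int(t / dt)
    times = np.arange(n_steps + 1) * dt

    start, switches = _draw_switch_times(params, t, rng)
    # cumulative time spent in '+' as a piecewise-linear function of time
    bounds = np.concatenate([[0.0], switches])
    seg_plus = np.arange(bounds.size - 1) % 2 == (0 if start == PLUS else 1)
    cum_plus = np.concatenate([[0.0], np.cumsum(np.diff(bounds) * seg_plus)])
    Tplus_grid = np.interp(times, bounds, cum_plus)
    d_plus = np.diff(Tplus_grid)
    step_var = 2.0 * (params.D_plus * d_plus + params.D_minus * (dt - d_plus))
    steps = np.sqrt(np.maximum(step_var, 0.0)) * rng.standard_normal(n_steps)
    positions = np.concatenate([[0.0], np.cumsum(steps)])

    seg_idx = np.clip(np.searchsorted(switches, times, side="right"), 0, seg_plus.size - 1)
    states = np.where(seg_plus[seg_idx], "+", "-")
    return TrajectoryGrid(times=times, positions=positions, states=states)


def sample_occupation_ensemble(
    params: ModelParams, t: float, n: int, rng: np.random.Generator
):
    """Vectorised ensemble of (T_plus, N, start_state) over n realizations.

    Returns a dict of arrays; equivalent in distribution to repeated
    :func:`simulate_renewal` but drawing sojourns in state-grouped batches.
    """
    if not t > 0:
        raise ValueError("measurement time t must be > 0")
    n = int(n)
    if params.initial_condition == "ordinary_from_plus":
        start_plus = np.ones(n, dtype=bool)
    elif params.initial_condition == "ordinary_from_minus":
        start_plus = np.zeros(n, dtype=bool)
    else:
        start_plus = rng.random(n) < params.stationary_plus_fraction

    T_plus = np.zeros(n)
    N = np.zeros(n, dtype=np.int64)
    elapsed = np.zeros(n)
    state_plus = start_plus.copy()
    active = np.ones(n, dtype=bool)
    equilibrium_first = params.initial_condition == "equilibrium"
    first_round = True
    while active.any():
        idx = np.nonzero(active)[0]
        tau = np.empty(idx.size)
        in_plus = state_plus[idx]
        for flag, dist in ((in_plus, params.dist_plus), (~in_plus, params.dist_minus)):
            m = int(flag.sum())
            if m == 0:
                continue
            if first_round and equilibrium_first:
                tau[flag] = np.atleast_1d(dist.sample_forward_recurrence(rng, m))
            else:
                tau[flag] = np.atleast_1d(dist.sample(rng, m))
        new_elapsed = elapsed[idx] + tau
        done = new_elapsed >= t
        fin, cont = idx[done], idx[~done]
        T_plus[fin] += np.where(state_plus[fin], t - elapsed[fin], 0.0)
        active[fin] = False
        T_plus[cont] += np.where(state_plus[cont], tau[~done], 0.0)
        elapsed[cont] = new_elapsed[~done]
        N[cont] += 1
        state_plus[cont] = ~state_plus[cont]
        first_round = False
    return {"T_plus": T_plus, "N": N, "start_plus": start_plus}


def sample_endpoint_ensemble(
    params: ModelParams, t: float, n: int, rng: np.random.Generator, *, full: bool = False
):
    """n independent endpoint displacements x(t) (optionally with occupations)."""
    occ = sample_occupation_ensemble(params, t, n, rng)
    var = 2.0 * (params.D_plus * occ["T_plus"] + params.D_minus * (t - occ["T_plus"]))
    x = np.sqrt(var) * rng.standard_normal(int(n))
    if full:
        occ["x"] = x
        return occ
    return x
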