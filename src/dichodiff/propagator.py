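"""Displacement distributions P(x,t) of the two-state diffusivity model.

Conditioned on the occupation time of the fast state, the displacement is
Gaussian; the unconditional propagator is a mixture of those Gaussians over
the occupation-fraction law.  At short measurement times (and D- = 0) the
flat occupation-fraction law produces a closed-form three-part propagator:
a Gaussian of the never-switching fast realizations, a delta at the origin
from the never-switching slow realizations, and a "tent" term with a
non-analytic |x| cusp at the origin.  At long times ergodic concentration
yields a single Gaussian with an effective diffusivity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Tuple, Union

import numpy as np
from scipy import integrate
from scipy.special import erf, erfc, gammaln, hyperu

from .occupation import MixedUnitIntervalPDF, MeansLike, _means, g_short_time
from .simulate import ModelParams

__all__ = [
    "DisplacementPDF",
    "conditional_gaussian",
    "propagator_from_g",
    "propagator_short_time",
    "small_x_expansion",
    "propagator_long_time",
    "tail_gaussian",
    "series_exact_equal_means",
    "superstat_laplace",
    "msd",
    "effective_diffusivity",
    "interval_probability",
]


@dataclass
class DisplacementPDF:
    """Distribution on the real line: optional point mass at x=0 + density.

    The atom collects realizations that never left the D-=0 state (the
    non-movers); the density is symmetric in x.
    """

    atom_at_zero: float
    density: Callable[[np.ndarray], np.ndarray]
    t: Optional[float] = None
    params: Optional[dict] = None

    def __call__(self, x):
        return self.density(np.asarray(x, dtype=float))

    def interval_probability(self, a: float, b: float) -> float:
        return interval_probability(self, a, b)

    def total_mass(self) -> float:
        return self.interval_probability(-np.inf, np.inf)

    def variance(self) -> float:
        val, _ = integrate.quad(
            lambda x: 2 * x * x * float(self.density(np.array(x))), 0, np.inf, limit=400
        )
        return val


def _gauss(x, var):
    return np.exp(-np.asarray(x, dtype=float) ** 2 / (2 * var)) / math.sqrt(2 * math.pi * var)


def conditional_gaussian(x, occupancy, D_plus: float, t: Optional[float] = None):
    """Gaussian density of x given the fast-state occupancy.

    ``occupancy`` is the occupation time T+ when ``t`` is omitted, or the
    occupation fraction p+ (so T+ = p+ t) when ``t`` is given.  A zero
    occupancy has no finite density — that probability sits in the delta
    atom at the origin — and raises.
    """
    T = occupancy if t is None else occupancy * t
    if np.any(np.asarray(T) <= 0):
        raise ValueError("occupancy must be > 0; zero occupancy is the delta atom")
    return _gauss(x, 2.0 * D_plus * np.asarray(T, dtype=float))


def propagator_from_g(
    g: MixedUnitIntervalPDF, D_plus: float, t: float, *, check_tol: float = 1e-6
) -> DisplacementPDF:
    """Mixture of conditional Gaussians over an occupation-fraction law.

    density(x) = atom1 N(0, 2D+t)(x) + int_0^1 N(0, 2D+ p t)(x) g(p) dp,
    with the integrable 1/sqrt(p) endpoint behavior tamed by substituting
    p = w^2; the p+=0 atom becomes the point mass at x=0.
    """
    mass = g.total_mass()
    if abs(mass - 1.0) > check_tol:
        raise ValueError(f"occupation-fraction law normalises to {mass:.6g}, not 1")

    def density(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.empty_like(x)
        for i, xi in enumerate(x):
            def integrand(w):
                p = w * w
                return 2 * w * float(g.density(np.array(p))) * float(
                    _gauss(xi, 2.0 * D_plus * p * t)
                )
            val, _ = integrate.quad(integrand, 0, 1, epsabs=1e-10, limit=400)
            out[i] = val + g.atom1 * float(_gauss(xi, 2.0 * D_plus * t))
        return out if out.size > 1 else out[0]

    return DisplacementPDF(
        atom_at_zero=g.atom0, density=density, t=t, params={"D_plus": D_plus, "from_g": True}
    )


def _tent(x, D_plus, t):
    """Unit-mass tent density from a flat occupation-fraction law."""
    x = np.abs(np.asarray(x, dtype=float))
    s = math.sqrt(4.0 * D_plus * t)
    return np.exp(-(x**2) / (s * s)) / math.sqrt(math.pi * D_plus * t) - (
        x / (2.0 * D_plus * t)
    ) * erfc(x / s)


def propagator_short_time(
    params: MeansLike, t: float, *, exponential_weights: bool = False, strict: bool = False
) -> DisplacementPDF:
    """Closed-form short-time propagator (D- = 0): Gaussian + delta + tent.

    Default weights are (1 - t/<tau>±); with ``exponential_weights`` the
    exponential-sojourn refinement e^{-t/<tau>±} is used instead (which
    normalises only to O(t^2)).  Only the sojourn means enter — the shape is
    family-independent.
    """
    if isinstance(params, ModelParams):
        if params.D_minus != 0:
            raise ValueError(
                "the closed-form short-time propagator requires D_minus = 0; "
                "use the simulator for D_minus > 0"
            )
        D_plus = params.D_plus
        tau_p, tau_m = params.mean_plus, params.mean_minus
    else:
        raise TypeError("propagator_short_time expects a ModelParams")
    if t <= 0:
        raise ValueError("t must be > 0")
    if t >= min(tau_p, tau_m):
        msg = f"t={t} is not small against the sojourn means ({tau_p}, {tau_m})"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    tot = tau_p + tau_m
    if exponential_weights:
        w1 = tau_p * math.exp(-t / tau_p) / tot
        w0 = tau_m * math.exp(-t / tau_m) / tot
    else:
        w1 = (tau_p / tot) * (1 - t / tau_p)
        w0 = (tau_m / tot) * (1 - t / tau_m)
    wu = 2.0 * t / tot

    def density(x):
        return w1 * _gauss(x, 2.0 * D_plus * t) + wu * _tent(x, D_plus, t)

    return DisplacementPDF(
        atom_at_zero=w0,
        density=density,
        t=t,
        params={
            "D_plus": D_plus,
            "tau_plus": tau_p,
            "tau_minus": tau_m,
            "law": "short_time",
            "exponential_weights": exponential_weights,
        },
    )


def small_x_expansion(params: ModelParams, t: float) -> Tuple[float, float, float]:
    """Coefficients (c0, c1, c2) of P(x,t) ~ c0 - c1|x| + c2 x^2 near x=0.

    c1 = 1/(D+ (<tau>+ + <tau>-)) > 0 always: the cusp exists for every
    valid parameter set.  c2 may be negative at small t.
    """
    if params.D_minus != 0:
        raise ValueError("the cusp expansion requires D_minus = 0")
    D, tau_p, tau_m = params.D_plus, params.mean_plus, params.mean_minus
    tot = tau_p + tau_m
    c0 = (3 * t + tau_p) / (2 * math.sqrt(math.pi * D * t) * tot)
    c1 = 1.0 / (D * tot)
    c2 = (5 * t - tau_p) / (8 * tot * math.sqrt(math.pi) * (D * t) ** 1.5)
    return c0, c1, c2


def effective_diffusivity(params: ModelParams) -> float:
    """Long-time effective D = (D+<tau>+ + D-<tau>-)/(<tau>+ + <tau>-)."""
    tot = params.mean_plus + params.mean_minus
    return (params.D_plus * params.mean_plus + params.D_minus * params.mean_minus) / tot


def propagator_long_time(params: ModelParams, t: float, *, strict: bool = False) -> DisplacementPDF:
    """Long-time Gaussian propagator with the effective diffusivity."""
    if t <= max(params.mean_plus, params.mean_minus):
        msg = f"t={t} is not large against the sojourn means"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    D_eff = effective_diffusivity(params)
    return DisplacementPDF(
        atom_at_zero=0.0,
        density=lambda x: _gauss(x, 2.0 * D_eff * t),
        t=t,
        params={"D_eff": D_eff, "law": "long_time"},
    )


def tail_gaussian(params: ModelParams, t: float, x):
    """Large-|x| Gaussian branch for equal-means exponential sojourns.

    The far tail is dominated by realizations that never switched out of the
    fast state: weight e^{-t/<tau>}/2 times N(0, 2D+t).
    """
    tau_p, tau_m = params.mean_plus, params.mean_minus
    if abs(tau_p - tau_m) > 1e-12 * max(tau_p, tau_m):
        raise ValueError("tail_gaussian is the equal-means exponential form")
    return 0.5 * math.exp(-t / tau_p) * _gauss(x, 2.0 * params.D_plus * t)


def series_exact_equal_means(
    tau: float,
    D_plus: float,
    t: float,
    x,
    n_terms: int = 200,
    rtol: float = 1e-10,
):
    """Exact continuous propagator density for equal-means exponential sojourns.

    Expands the Bessel functions of the exact occupation-fraction law and
    integrates term by term; each term's pair of confluent-hypergeometric
    pieces is evaluated together as Tricomi's function U(k+1, 1/2-k, x^2/4D+t).
    Truncates adaptively once the last term falls below ``rtol`` of the sum.
    Includes the Gaussian branch of the p+=1 atom; the p+=0 atom (delta at
    x=0, weight e^{-t/tau}/2) is excluded, as for every density here.
    """
    tau, D_plus, t = float(tau), float(D_plus), float(t)
    if min(tau, D_plus, t) <= 0 or n_terms < 1:
        raise ValueError("tau, D_plus, t must be > 0 and n_terms >= 1")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    beta = x * x / (4.0 * D_plus * t)
    r = t / tau
    pref = r * np.exp(-r - beta) / math.sqrt(4 * math.pi * D_plus * t)

    total = np.zeros_like(beta)
    converged = np.zeros_like(beta, dtype=bool)
    for k in range(n_terms):
        ck = r ** (2 * k) / math.exp(2 * gammaln(k + 1)) + r ** (2 * k + 1) / (
            2 * math.exp(gammaln(k + 1) + gammaln(k + 2))
        )
        # k! * U(k+1, 1/2-k, beta); at beta=0, U = Gamma(k+1/2)/Gamma(2k+3/2)
        u0 = math.exp(gammaln(k + 0.5) - gammaln(2 * k + 1.5))
        uval = np.where(beta > 0, hyperu(k + 1.0, 0.5 - k, np.maximum(beta, 1e-300)), u0)
        term = ck * math.exp(gammaln(k + 1)) * uval
        total += term
        converged |= np.abs(term) <= rtol * np.abs(total)
        if converged.all() and k >= 1:
            break
    else:
        raise ArithmeticError(
            f"series not converged to rtol={rtol} within {n_terms} terms "
            f"(t/tau={r:.3g}, max beta={float(beta.max()):.3g})"
        )
    gauss_branch = 0.5 * math.exp(-r) * _gauss(x, 2.0 * D_plus * t)
    out = gauss_branch + pref * total
    return out if out.size > 1 else float(out[0])


def superstat_laplace(x, mean_D: float, t: float):
    """Super-statistics baseline: exponential mixture of diffusivities.

    A static exponential law of D turns the Gaussian propagator into the
    Laplace density exp(-|x|/sqrt(<D>t))/sqrt(4<D>t) — log-linear globally,
    unlike the two-state tent law.
    """
    if mean_D <= 0 or t <= 0:
        raise ValueError("mean_D and t must be > 0")
    x = np.asarray(x, dtype=float)
    s = math.sqrt(mean_D * t)
    return np.exp(-np.abs(x) / s) / (2.0 * s)


def msd(params: ModelParams, t):
    """Ensemble MSD under equilibrium initial conditions, exact at all t.

    <x^2(t)> = 2 (D+<tau>+ + D-<tau>-) t / (<tau>+ + <tau>-) — linear for
    all times, consistent with the conditional-Gaussian construction and
    with the variance of the long-time propagator.
    """
    return 2.0 * effective_diffusivity(params) * np.asarray(t, dtype=float)


def interval_probability(pdf: DisplacementPDF, a: float, b: float) -> float:
    """P(a < x < b): quadrature of the density plus the atom if 0 in (a,b)."""
    if not a < b:
        raise ValueError("require a < b")
    val, _ = integrate.quad(
        lambda x: float(np.atleast_1d(pdf.density(np.array(x)))[0]),
        a,
        b,
        points=[0.0] if (a < 0 < b and np.isfinite(a) and np.isfinite(b)) else None,
        limit=400,
    )
    if a < 0 < b:
        val += pdf.atom_at_zero
    return val
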