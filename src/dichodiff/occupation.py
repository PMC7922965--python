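"""Distributions of the occupation time T+ and occupation fraction p+ = T+/t.

The fraction of the measurement window spent in the fast state controls the
displacement statistics of the two-state model.  Three regimes are exposed:

* short measurement times — for *any* sojourn laws with finite means the
  interior of the law of p+ is flat (uniform), with point masses at p+=0
  and p+=1 from realizations that never switched;
* exponential sojourns — an exact law at all times, built from modified
  Bessel functions, with the short-time uniform law as its t->0 limit;
* long measurement times — ergodic concentration of p+ on
  <tau>+/(<tau>+ + <tau>-).

Laplace-space representations of the exponential-sojourn laws are provided
for cross-validation by numerical inversion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple, Union

import numpy as np
from scipy import integrate
from scipy.special import i0e, i1e

from .simulate import ModelParams
from .waiting_times import SojournDistribution

__all__ = [
    "MixedUnitIntervalPDF",
    "OccupationTimePDF",
    "ValidityError",
    "g_short_time",
    "g_exact_exponential",
    "g_long_time_location",
    "occupation_time_pdf_short_time",
    "q_short_time",
    "laplace_occupation",
    "laplace_st_difference",
]


class ValidityError(ValueError):
    """Raised when a small-t approximation is requested outside its regime."""


MeansLike = Union[ModelParams, Tuple[float, float]]


def _means(params: MeansLike) -> Tuple[float, float]:
    if isinstance(params, ModelParams):
        return params.mean_plus, params.mean_minus
    tp, tm = params
    return float(tp), float(tm)


@dataclass
class MixedUnitIntervalPDF:
    """Distribution of p+ on [0,1]: point masses at 0 and 1 plus a density.

    atom0, atom1 : probability masses of realizations frozen in the slow
        (p+=0) and fast (p+=1) state for the whole window
    density : continuous density on the open interval (0,1)
    """

    atom0: float
    atom1: float
    density: Callable[[np.ndarray], np.ndarray]
    t: Optional[float] = None
    params: Optional[dict] = None

    def __post_init__(self):
        if not (0 <= self.atom0 <= 1 and 0 <= self.atom1 <= 1):
            raise ValueError("atoms must be probabilities in [0,1]")

    def pdf(self, p):
        """Continuous density at interior points p in (0,1)."""
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("density is defined on the open interval (0,1)")
        return self.density(p)

    def interior_mass(self) -> float:
        # p = w^2 substitution regularises the endpoints
        val, _ = integrate.quad(
            lambda w: 2 * w * float(self.density(np.array(w * w))), 0, 1, limit=200
        )
        return val

    def total_mass(self) -> float:
        return self.atom0 + self.atom1 + self.interior_mass()

    def moment(self, order: int = 1) -> float:
        val, _ = integrate.quad(
            lambda p: p**order * float(self.density(np.array(p))), 0, 1, limit=200
        )
        return self.atom1 + val

    def mean(self) -> float:
        return self.moment(1)

    def variance(self) -> float:
        m = self.mean()
        return self.moment(2) - m * m


@dataclass
class OccupationTimePDF:
    """Distribution of T+ on [0, t]: atoms at the endpoints plus a density."""

    atom_at_zero: float
    atom_at_t: float
    density: Callable[[np.ndarray], np.ndarray]
    t: float

    def pdf(self, T):
        T = np.asarray(T, dtype=float)
        if np.any((T <= 0) | (T >= self.t)):
            raise ValueError("density is defined on the open interval (0,t)")
        return self.density(T)

    def total_mass(self) -> float:
        val, _ = integrate.quad(lambda T: float(self.density(np.array(T))), 0, self.t)
        return self.atom_at_zero + self.atom_at_t + val


def _check_short_time(t: float, tau_p: float, tau_m: float, strict: bool):
    if t >= min(tau_p, tau_m):
        msg = (
            f"t={t} is not small compared with the sojourn means "
            f"({tau_p}, {tau_m}); the short-time law is a small-t approximation"
        )
        if strict:
            raise ValidityError(msg)
        warnings.warn(msg, stacklevel=3)


def g_short_time(params: MeansLike, t: float, *, strict: bool = False) -> MixedUnitIntervalPDF:
    """Short-time law of p+: flat interior, family-independent.

    Valid for any sojourn laws with finite means; only the means enter.
    atom1 = [tau+/(tau+ + tau-)](1 - t/tau+), atom0 analogous, and the
    interior density is the constant 2t/(tau+ + tau-).  The three weights
    sum to one algebraically.
    """
    tau_p, tau_m = _means(params)
    if t <= 0:
        raise ValueError("t must be > 0")
    _check_short_time(t, tau_p, tau_m, strict)
    tot = tau_p + tau_m
    atom1 = (tau_p / tot) * (1 - t / tau_p)
    atom0 = (tau_m / tot) * (1 - t / tau_m)
    level = 2 * t / tot
    return MixedUnitIntervalPDF(
        atom0=atom0,
        atom1=atom1,
        density=lambda p: np.full_like(np.asarray(p, dtype=float), level),
        t=t,
        params={"tau_plus": tau_p, "tau_minus": tau_m, "law": "short_time"},
    )


def occupation_time_pdf_short_time(
    params: MeansLike, t: float, *, strict: bool = False
) -> OccupationTimePDF:
    """Short-time law of the occupation time T+ (same structure, on [0,t])."""
    g = g_short_time(params, t, strict=strict)
    tau_p, tau_m = _means(params)
    level = 2.0 / (tau_p + tau_m)
    return OccupationTimePDF(
        atom_at_zero=g.atom0,
        atom_at_t=g.atom1,
        density=lambda T: np.full_like(np.asarray(T, dtype=float), level),
        t=t,
    )


def q_short_time(dist_start: SojournDistribution, t: float) -> Tuple[float, float]:
    """Small-t probabilities of zero and one transition from the start state.

    Under equilibrium initial conditions only N in {0,1} matter as t->0:
    Q0 ~ 1 - t/<tau>_start and Q1 ~ t/<tau>_start.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t >= dist_start.mean:
        warnings.warn("q_short_time used outside its small-t regime", stacklevel=2)
    q1 = t / dist_start.mean
    return 1.0 - q1, q1


def g_exact_exponential(tau_plus: float, tau_minus: float, t: float) -> MixedUnitIntervalPDF:
    """Exact law of p+ for exponential sojourns, valid at every t.

    Atoms <tau>-e^{-t/<tau>-}/(<tau>+ + <tau>-) at p+=0 and the mirrored
    weight at p+=1; the interior density combines I0 and I1 with the factor
    exp(-t p+/<tau>+ - t(1-p+)/<tau>-).  Bessel evaluation uses the
    exponentially scaled routines so large t/<tau> cannot overflow, and the
    removable I1(z)/z singularity at the endpoints is evaluated by its
    limit.  Equal means reduce to the classical single-rate law exactly.
    """
    tau_p, tau_m, t = float(tau_plus), float(tau_minus), float(t)
    if min(tau_p, tau_m, t) <= 0:
        raise ValueError("tau_plus, tau_minus and t must all be > 0")
    tot = tau_p + tau_m
    atom0 = tau_m * math.exp(-t / tau_m) / tot
    atom1 = tau_p * math.exp(-t / tau_p) / tot
    geo = math.sqrt(tau_p * tau_m)

    def density(p):
        p = np.asarray(p, dtype=float)
        q = 1.0 - p
        z = 2.0 * t * np.sqrt(p * q) / geo
        log_damp = z - t * p / tau_p - t * q / tau_m  # i*e are scaled by e^{-z}
        damp = np.exp(log_damp)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = i1e(z) / (2.0 * np.sqrt(p * q))
        # I1(z)/(2 sqrt(pq)) -> (t/geo) * lim I1(z)/z = t/(2 geo) at the endpoints
        i1_over = np.where(z > 1e-8, ratio, t / geo / 2.0)
        coef = (q / tau_p + p / tau_m) * geo
        return (2.0 * t / tot) * damp * (i0e(z) + coef * i1_over)

    return MixedUnitIntervalPDF(
        atom0=atom0,
        atom1=atom1,
        density=density,
        t=t,
        params={"tau_plus": tau_p, "tau_minus": tau_m, "law": "exact_exponential"},
    )


def g_long_time_location(params: MeansLike) -> float:
    """Location of the long-time delta concentration of p+."""
    tau_p, tau_m = _means(params)
    return tau_p / (tau_p + tau_m)


def laplace_occupation(tau_plus: float, tau_minus: float, s: float, u: float) -> float:
    """Double Laplace transform of the T+ law for exponential sojourns.

    Laplace pairs t<->s and T+<->u, under equilibrium initial conditions.
    At u=0 it reduces to 1/s (normalisation) and its -d/du at u=0 is the
    transform of <T+> = <tau>+ t/(<tau>+ + <tau>-).
    """
    tau_p, tau_m = float(tau_plus), float(tau_minus)
    # the printed form continues analytically off the real axis, where
    # contour-inversion rules evaluate it; validate real arguments only
    if not (np.iscomplexobj(s) or np.iscomplexobj(u)):
        if s <= 0 or u < 0:
            raise ValueError("require s > 0 and u >= 0")
    num = tau_m**2 + tau_p**2 * (1 + tau_m * s) + tau_p * tau_m * (2 + tau_m * (s + u))
    den = (tau_p + tau_m) * (tau_m * s + tau_p * (1 + tau_m * s) * (s + u))
    return num / den


def laplace_st_difference(tau: float, s: float, v: float) -> float:
    """Double Laplace transform of the occupation-time difference S_t = T+ - T-.

    Equal-means exponential sojourns; pairs S_t<->v and t<->s, valid for
    s > |v|.  Even in v, and 1/s at v=0.
    """
    tau = float(tau)
    if tau <= 0:
        raise ValueError("tau must be > 0")
    # convergence strip s > |v| on the real axis; complex s (contour
    # inversion) evaluates the analytic continuation
    if not np.iscomplexobj(s) and not s > abs(v):
        raise ValueError("outside the convergence region: require s > |v|")
    return (s + 2.0 / tau) / (s * s + 2.0 * s / tau - v * v)
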