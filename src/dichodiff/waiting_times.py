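"""Sojourn-time distributions and the equilibrium forward-recurrence law.

A two-state diffusivity process spends a random sojourn time in each state
before switching.  The sojourn law :math:`\\psi_\\pm(\\tau)` may be anything
with a finite positive mean; this module provides the named families used in
practice (exponential, uniform, gamma) plus a generic custom contract, each
with an exact plain sampler and an exact sampler of the *forward recurrence
time* — the remaining time to the first switch when observation starts in
statistical equilibrium,

.. math:: f_{eq}(\\tau_1) = \\frac{1 - \\int_0^{\\tau_1}\\psi(\\tau)d\\tau}
                                 {\\langle\\tau\\rangle}.

For the named families the forward-recurrence draw uses the length-biased
construction (the interval covering a stationary observation point is
length-biased, and the observation point is uniform within it), which is
exact and vectorised.  The custom family falls back to inverse-CDF
root-finding.
"""

from __future__ import annotations

import math
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "SojournDistribution",
    "Exponential",
    "Uniform",
    "Gamma",
    "CustomSojourn",
    "sojourn_from_spec",
]


class ConfigurationError(ValueError):
    """Invalid distribution family or parameters."""


class SojournDistribution:
    """Abstract waiting-time law psi(tau) on [0, inf) with finite mean.

    Subclasses must define :attr:`mean`, :meth:`pdf`, :meth:`survival`,
    :meth:`sample` and :meth:`sample_forward_recurrence`.
    """

    family: str = "abstract"

    @property
    def mean(self) -> float:
        raise NotImplementedError

    def pdf(self, tau):
        raise NotImplementedError

    def survival(self, tau):
        """P(sojourn > tau), evaluated from the closed-form CDF."""
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, size=None):
        """i.i.d. draws from psi."""
        raise NotImplementedError

    def forward_recurrence_density(self, tau1):
        """Equilibrium density of the first observed sojourn, survival/mean."""
        tau1 = np.asarray(tau1, dtype=float)
        if np.any(tau1 < 0):
            raise ValueError("forward recurrence time must be >= 0")
        return self.survival(tau1) / self.mean

    def sample_forward_recurrence(self, rng: np.random.Generator, size=None):
        raise NotImplementedError

    def spec(self) -> dict:
        """Config-file representation {family, params}."""
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}({self.spec()['params']})"


class Exponential(SojournDistribution):
    """Exponential sojourns, psi(tau) = exp(-tau/mean)/mean."""

    family = "exponential"

    def __init__(self, mean: float):
        mean = float(mean)
        if not (mean > 0 and math.isfinite(mean)):
            raise ConfigurationError("exponential mean must be finite and > 0")
        self._mean = mean

    @property
    def mean(self) -> float:
        return self._mean

    def pdf(self, tau):
        tau = np.asarray(tau, dtype=float)
        return np.where(tau >= 0, np.exp(-tau / self._mean) / self._mean, 0.0)

    def survival(self, tau):
        tau = np.asarray(tau, dtype=float)
        return np.where(tau >= 0, np.exp(-tau / self._mean), 1.0)

    def sample(self, rng, size=None):
        return rng.exponential(self._mean, size)

    def sample_forward_recurrence(self, rng, size=None):
        # memoryless: the forward-recurrence law is psi itself
        return rng.exponential(self._mean, size)

    def spec(self):
        return {"family": "exponential", "params": {"mean": self._mean}}


class Uniform(SojournDistribution):
    """Uniform sojourns on [a, b), 0 <= a < b."""

    family = "uniform"

    def __init__(self, a: float, b: float):
        a, b = float(a), float(b)
        if not (0 <= a < b and math.isfinite(b)):
            raise ConfigurationError("uniform bounds require 0 <= a < b < inf")
        self.a, self.b = a, b

    @property
    def mean(self) -> float:
        return 0.5 * (self.a + self.b)

    def pdf(self, tau):
        tau = np.asarray(tau, dtype=float)
        inside = (tau >= self.a) & (tau <= self.b)
        return np.where(inside, 1.0 / (self.b - self.a), 0.0)

    def survival(self, tau):
        tau = np.asarray(tau, dtype=float)
        s = (self.b - tau) / (self.b - self.a)
        return np.clip(s, 0.0, 1.0)

    def sample(self, rng, size=None):
        return rng.uniform(self.a, self.b, size)

    def sample_forward_recurrence(self, rng, size=None):
        # length-biased interval has CDF (l^2-a^2)/(b^2-a^2); scale by U(0,1)
        u = rng.random(size)
        length_biased = np.sqrt(self.a**2 + u * (self.b**2 - self.a**2))
        return length_biased * rng.random(size)

    def spec(self):
        return {"family": "uniform", "params": {"a": self.a, "b": self.b}}


class Gamma(SojournDistribution):
    """Gamma sojourns with shape k and scale theta, mean k*theta."""

    family = "gamma"

    def __init__(self, shape: float, scale: float):
        shape, scale = float(shape), float(scale)
        if not (shape > 0 and scale > 0 and math.isfinite(shape * scale)):
            raise ConfigurationError("gamma shape and scale must be finite and > 0")
        self.shape, self.scale = shape, scale
        self._frozen = stats.gamma(a=shape, scale=scale)

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    def pdf(self, tau):
        return self._frozen.pdf(np.asarray(tau, dtype=float))

    def survival(self, tau):
        tau = np.asarray(tau, dtype=float)
        return np.where(tau >= 0, self._frozen.sf(tau), 1.0)

    def sample(self, rng, size=None):
        return rng.gamma(self.shape, self.scale, size)

    def sample_forward_recurrence(self, rng, size=None):
        # length-biased Gamma(k, theta) is Gamma(k+1, theta)
        return rng.gamma(self.shape + 1.0, self.scale, size) * rng.random(size)

    def spec(self):
        return {"family": "gamma", "params": {"shape": self.shape, "scale": self.scale}}


class CustomSojourn(SojournDistribution):
    """User-supplied sojourn law given as a (pdf, survival, mean, sampler) contract.

    The density is numerically checked to integrate to one, and the mean must
    be finite and positive: the occupation-time theory rests on finite first
    moments, so heavy-tailed laws with infinite mean are rejected outright.
    Forward-recurrence draws invert the equilibrium CDF
    ``F_eq(tau) = (1/mean) * int_0^tau survival`` by bracketed root-finding.
    """

    family = "custom"

    def __init__(
        self,
        pdf: Callable[[np.ndarray], np.ndarray],
        survival: Callable[[np.ndarray], np.ndarray],
        mean: float,
        sampler: Callable[[np.random.Generator, Optional[int]], np.ndarray],
        *,
        check_tol: float = 1e-6,
    ):
        mean = float(mean)
        if not (mean > 0 and math.isfinite(mean)):
            raise ConfigurationError(
                "custom sojourn mean must be finite and > 0 "
                "(infinite-mean laws are outside the model's assumptions)"
            )
        total, _ = integrate.quad(lambda u: float(pdf(u)), 0, np.inf, limit=200)
        if abs(total - 1.0) > check_tol:
            raise ConfigurationError(
                f"custom density integrates to {total:.6g}, expected 1"
            )
        if float(survival(0.0)) != 1.0 and abs(float(survival(0.0)) - 1.0) > check_tol:
            raise ConfigurationError("custom survival must satisfy survival(0)=1")
        self._pdf, self._survival, self._mean, self._sampler = pdf, survival, mean, sampler

    @property
    def mean(self) -> float:
        return self._mean

    def pdf(self, tau):
        return np.asarray(self._pdf(np.asarray(tau, dtype=float)), dtype=float)

    def survival(self, tau):
        tau = np.asarray(tau, dtype=float)
        if np.any(tau < 0):
            raise ValueError("negative sojourn time")
        return np.asarray(self._survival(tau), dtype=float)

    def sample(self, rng, size=None):
        return np.asarray(self._sampler(rng, size), dtype=float)

    def _feq_cdf(self, tau: float) -> float:
        val, _ = integrate.quad(lambda u: float(self._survival(u)), 0.0, tau, limit=200)
        return val / self._mean

    def _feq_ppf(self, u: float) -> float:
        hi = self._mean
        while self._feq_cdf(hi) < u:
            hi *= 2.0
            if hi > 1e12 * self._mean:  # pragma: no cover - defensive
                raise RuntimeError("forward-recurrence quantile bracket failed")
        return optimize.brentq(lambda x: self._feq_cdf(x) - u, 0.0, hi, xtol=1e-10)

    def sample_forward_recurrence(self, rng, size=None):
        if size is None:
            return self._feq_ppf(rng.random())
        return np.array([self._feq_ppf(v) for v in rng.random(size)])

    def spec(self):
        return {"family": "custom", "params": {"mean": self._mean}}


def sojourn_mean(dist: SojournDistribution) -> float:
    """Exact first moment of a sojourn law."""
    if not isinstance(dist, SojournDistribution):
        raise ConfigurationError(f"unknown sojourn distribution {dist!r}")
    return dist.mean


def sample_sojourn(dist: SojournDistribution, rng: np.random.Generator, n: int):
    """n i.i.d. sojourn draws, reproducible under a fixed generator state."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return dist.sample(rng, n)


def forward_recurrence_density(dist: SojournDistribution, tau1):
    return dist.forward_recurrence_density(tau1)


def sample_forward_recurrence(dist: SojournDistribution, rng: np.random.Generator, size=None):
    return dist.sample_forward_recurrence(rng, size)


_FAMILIES = {
    "exponential": lambda p: Exponential(p["mean"]),
    "uniform": lambda p: Uniform(p["a"], p["b"]),
    "gamma": lambda p: Gamma(p["shape"], p["scale"]),
}


def sojourn_from_spec(spec: dict) -> SojournDistribution:
    """Build a sojourn law from a config mapping {family, params}.

    Exact key names: exponential -> {mean}; uniform -> {a, b};
    gamma -> {shape, scale}.  The custom family cannot be expressed in a
    config file (it needs callables) and must be built in code.
    """
    try:
        family = spec["family"]
        params = spec.get("params", {})
    except (TypeError, KeyError) as exc:
        raise ConfigurationError(f"sojourn spec must map family->params: {spec!r}") from exc
    if family not in _FAMILIES:
        raise ConfigurationError(
            f"unknown sojourn family {family!r}; expected one of {sorted(_FAMILIES)}"
        )
    try:
        return _FAMILIES[family](params)
    except KeyError as exc:
        raise ConfigurationError(f"missing parameter {exc} for family {family!r}") from exc
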