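"""Parametric timer distributions.

Every random time in the Cyton2 model (time to first division, subsequent
division times, division destiny, death) is a non-negative random variable
drawn from one of a small set of parametric families. The parameterization
conventions are fixed here once and used everywhere else:

``gamma(alpha_g, beta_g)``
    shape ``alpha_g``, scale ``beta_g`` (hours).
``lognormal(m, s)``
    median ``m`` (hours) and log-scale shape ``s``: ``log T ~ N(log m, s^2)``,
    so ``cdf(m) = 0.5`` exactly.
``normal(mu, sigma)``
    mean and standard deviation in hours. May put mass at negative times;
    consumers of the mean model treat that mass as mass at zero.
``weibull(alpha_w, beta_w)``
    shape ``alpha_w``, scale ``beta_w``.
``delayed_exponential(lam, c)``
    exponential with rate ``lam`` (1/h) shifted right by ``c`` hours.
``delayed_lognormal(m_d, s_d, c)``
    lognormal with median ``m_d`` and shape ``s_d`` shifted right by ``c``.
``point_mass(t0)``
    degenerate distribution at ``t0``; used for exact hand-checkable tests.

Survival is the strict-inequality tail ``P(T > t) = 1 - cdf(t)`` with the
conventional right-continuous cdf, so ``survival(point_mass(t0), t0) == 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats
from scipy.special import ndtr

_SQRT2PI = np.sqrt(2.0 * np.pi)

__all__ = [
    "TimerDistribution",
    "make_distribution",
    "UnknownFamilyError",
    "DistributionParameterError",
    "FAMILIES",
]


class UnknownFamilyError(ValueError):
    """Raised for a distribution family name outside the supported set."""


class DistributionParameterError(ValueError):
    """Raised for missing, extra, or out-of-range family parameters."""


#: family name -> ordered tuple of required parameter names
FAMILIES: dict[str, tuple[str, ...]] = {
    "gamma": ("alpha_g", "beta_g"),
    "lognormal": ("m", "s"),
    "normal": ("mu", "sigma"),
    "weibull": ("alpha_w", "beta_w"),
    "delayed_exponential": ("lam", "c"),
    "delayed_lognormal": ("m_d", "s_d", "c"),
    "point_mass": ("t0",),
}

# parameters that must be strictly positive / merely non-negative
_POSITIVE = {"alpha_g", "beta_g", "m", "s", "sigma", "alpha_w", "beta_w",
             "lam", "m_d", "s_d"}
_NON_NEGATIVE = {"c", "t0"}


@dataclass(frozen=True)
class TimerDistribution:
    """A timer distribution with cdf/pdf/survival/quantile/sample.

    Instances are created through :func:`make_distribution`, which validates
    the parameter set for the family. Times are in hours from stimulation.
    """

    family: str
    params: Mapping[str, float]

    @property
    def _frozen(self):
        # scipy frozen distributions are built lazily; cdf/pdf for the
        # lognormal and normal families bypass them entirely for speed
        cached = self.__dict__.get("_frozen_cache")
        if cached is None:
            cached = _freeze(self.family, self.params)
            object.__setattr__(self, "_frozen_cache", cached)
        return cached

    # -- basic probability interface ------------------------------------
    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "point_mass":
            return (t >= self.params["t0"]).astype(float)
        if self.family == "lognormal":
            m, s = self.params["m"], self.params["s"]
            with np.errstate(divide="ignore"):
                z = np.where(t > 0, np.log(np.maximum(t, 1e-300) / m) / s,
                             -np.inf)
            return ndtr(z)
        if self.family == "normal":
            p = self.params
            return ndtr((t - p["mu"]) / p["sigma"])
        return self._frozen.cdf(t)

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "point_mass":
            raise DistributionParameterError(
                "point_mass has no density; handle it analytically")
        if self.family == "lognormal":
            m, s = self.params["m"], self.params["s"]
            pos = t > 0
            z = np.where(pos, np.log(np.maximum(t, 1e-300) / m) / s, 0.0)
            return np.where(
                pos, np.exp(-0.5 * z * z) / (np.maximum(t, 1e-300) * s
                                             * _SQRT2PI), 0.0)
        if self.family == "normal":
            p = self.params
            z = (t - p["mu"]) / p["sigma"]
            return np.exp(-0.5 * z * z) / (p["sigma"] * _SQRT2PI)
        return self._frozen.pdf(t)

    def survival(self, t):
        """P(T > t), the strict-inequality tail probability."""
        return 1.0 - self.cdf(t)

    def quantile(self, q):
        q = np.asarray(q, dtype=float)
        if self.family == "point_mass":
            return np.full_like(q, self.params["t0"])
        return self._frozen.ppf(q)

    def sample(self, n: int, seed=None) -> np.ndarray:
        """Draw ``n`` values; ``seed`` may be an int or a Generator."""
        if n < 1:
            raise DistributionParameterError(f"need n >= 1, got {n}")
        rng = np.random.default_rng(seed) if not isinstance(
            seed, np.random.Generator) else seed
        if self.family == "point_mass":
            return np.full(n, self.params["t0"], dtype=float)
        return np.asarray(self._frozen.rvs(size=n, random_state=rng),
                          dtype=float)

    def mean(self) -> float:
        if self.family == "point_mass":
            return float(self.params["t0"])
        return float(self._frozen.mean())

    # -- serialization ---------------------------------------------------
    def to_config(self) -> dict:
        return {"family": self.family, "params": dict(self.params)}

    @staticmethod
    def from_config(block: Mapping) -> "TimerDistribution":
        return make_distribution(block["family"], **block["params"])


def _freeze(family: str, p: Mapping[str, float]):
    if family == "gamma":
        return stats.gamma(a=p["alpha_g"], scale=p["beta_g"])
    if family == "lognormal":
        return stats.lognorm(s=p["s"], scale=p["m"])
    if family == "normal":
        return stats.norm(loc=p["mu"], scale=p["sigma"])
    if family == "weibull":
        return stats.weibull_min(c=p["alpha_w"], scale=p["beta_w"])
    if family == "delayed_exponential":
        return stats.expon(loc=p["c"], scale=1.0 / p["lam"])
    if family == "delayed_lognormal":
        return stats.lognorm(s=p["s_d"], scale=p["m_d"], loc=p["c"])
    return None  # point_mass


def make_distribution(family: str, **params: float) -> TimerDistribution:
    """Construct a validated :class:`TimerDistribution`.

    Raises
    ------
    UnknownFamilyError
        if ``family`` is not one of the supported names.
    DistributionParameterError
        if parameters are missing, unexpected, or out of range.
    """
    if family not in FAMILIES:
        raise UnknownFamilyError(
            f"unknown family {family!r}; choose from {sorted(FAMILIES)}")
    required = FAMILIES[family]
    missing = [k for k in required if k not in params]
    if missing:
        raise DistributionParameterError(
            f"{family}: missing parameter(s) {missing}")
    extra = [k for k in params if k not in required]
    if extra:
        raise DistributionParameterError(
            f"{family}: unexpected parameter(s) {extra}")
    clean = {}
    for k in required:
        v = float(params[k])
        if not np.isfinite(v):
            raise DistributionParameterError(f"{family}: {k} must be finite")
        if k in _POSITIVE and v <= 0:
            raise DistributionParameterError(
                f"{family}: {k} must be > 0, got {v}")
        if k in _NON_NEGATIVE and v < 0:
            raise DistributionParameterError(
                f"{family}: {k} must be >= 0, got {v}")
        clean[k] = v
    return TimerDistribution(family=family, params=clean)
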