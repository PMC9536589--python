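"""Parametric laws for filament velocity, length and on/off durations.

Four families are supported: Dirac (deterministic), uniform, normal and
gamma.  Velocities are nonnegative and, for the normal and gamma families,
truncated so that no velocity exceeds 40 um/min; truncated laws are
renormalized on [lower, cap].  A uniform law specified by its mean alone
has support [0, 2*mean], the convention used throughout for the on/off
duration laws (whose means are tau_on and tau_off).

Gamma laws may be given either as (mean, sd) or as shape/scale (k, theta),
related by mean = k*theta and sd = sqrt(k)*theta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import integrate, stats

__all__ = [
    "AtomicDistributionError",
    "DistributionSpec",
    "make_distribution",
    "sample",
    "pdf",
    "cdf",
    "truncated_mean",
    "velocity_cap_default",
]

FAMILIES = ("dirac", "uniform", "normal", "gamma")

#: the truncation cap applied to normal/gamma *velocity* laws (um/min)
velocity_cap_default = 40.0

_MAX_REJECTION_ROUNDS = 1000


class AtomicDistributionError(ValueError):
    """Raised when a density is requested for an atomic (Dirac) law."""


@dataclass(frozen=True)
class DistributionSpec:
    """A validated 1-D parametric law with optional truncation.

    ``mean``/``sd`` always refer to the *untruncated* law; truncation to
    [``lower``, ``cap``] renormalizes the density.  For the uniform family
    ``a``/``b`` carry the support; for gamma, ``k``/``theta`` the
    shape/scale.
    """

    family: str
    mean: float
    sd: float = 0.0
    k: float | None = None
    theta: float | None = None
    a: float | None = None
    b: float | None = None
    lower: float = 0.0
    cap: float | None = None

    def with_cap(self, cap: float | None) -> "DistributionSpec":
        return replace(self, cap=cap)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {"family": self.family, "mean": self.mean}
        if self.family == "uniform":
            d["bounds"] = [self.a, self.b]
        elif self.family == "normal":
            d["sd"] = self.sd
        elif self.family == "gamma":
            d["k"] = self.k
            d["theta"] = self.theta
        if self.cap is not None:
            d["cap"] = self.cap
        if self.lower != 0.0:
            d["lower"] = self.lower
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        d = dict(d)
        family = d.pop("family")
        return make_distribution(family, **d)


def make_distribution(
    family: str,
    mean: float | None = None,
    sd: float | None = None,
    k: float | None = None,
    theta: float | None = None,
    bounds: tuple[float, float] | None = None,
    cap: float | None = None,
    lower: float = 0.0,
) -> DistributionSpec:
    """Build and validate a :class:`DistributionSpec`.

    dirac: ``mean`` only.  uniform: ``mean`` (support [0, 2*mean]) or
    explicit ``bounds=(a, b)``.  normal: ``mean`` and ``sd``.  gamma:
    ``(mean, sd)`` or ``(k, theta)``.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if cap is not None and cap <= lower:
        raise ValueError(f"cap {cap} must exceed lower bound {lower}")

    if family == "dirac":
        if mean is None:
            raise ValueError("dirac law needs a mean")
        if mean < lower or (cap is not None and mean > cap):
            raise ValueError("dirac atom lies outside [lower, cap]")
        return DistributionSpec("dirac", float(mean), 0.0, lower=lower, cap=cap)

    if family == "uniform":
        if bounds is not None:
            a, b = float(bounds[0]), float(bounds[1])
            if b <= a:
                raise ValueError(f"uniform bounds need a < b, got {bounds}")
        elif mean is not None:
            if mean <= 0:
                raise ValueError("mean-only uniform needs mean > 0")
            a, b = 0.0, 2.0 * float(mean)
        else:
            raise ValueError("uniform law needs mean or bounds")
        mu = 0.5 * (a + b)
        sigma = (b - a) / math.sqrt(12.0)
        return DistributionSpec("uniform", mu, sigma, a=a, b=b, lower=lower, cap=cap)

    if family == "normal":
        if mean is None or sd is None:
            raise ValueError("normal law needs mean and sd")
        if sd <= 0:
            raise ValueError("normal sd must be positive")
        return DistributionSpec("normal", float(mean), float(sd), lower=lower, cap=cap)

    # gamma
    if k is not None and theta is not None:
        if k <= 0 or theta <= 0:
            raise ValueError("gamma k and theta must be positive")
        mu = k * theta
        sigma = math.sqrt(k) * theta
    elif mean is not None and sd is not None:
        if mean <= 0 or sd <= 0:
            raise ValueError("gamma mean and sd must be positive")
        k = (mean / sd) ** 2
        theta = sd**2 / mean
        mu, sigma = float(mean), float(sd)
    else:
        raise ValueError("gamma law needs (mean, sd) or (k, theta)")
    return DistributionSpec(
        "gamma", mu, sigma, k=float(k), theta=float(theta), lower=lower, cap=cap
    )


@lru_cache(maxsize=256)
def _base(spec: DistributionSpec):
    """Frozen scipy distribution of the untruncated law (cached per spec)."""
    if spec.family == "uniform":
        return stats.uniform(spec.a, spec.b - spec.a)
    if spec.family == "normal":
        return stats.norm(spec.mean, spec.sd)
    if spec.family == "gamma":
        return stats.gamma(spec.k, scale=spec.theta)
    raise AtomicDistributionError("dirac law has no scipy counterpart")


@lru_cache(maxsize=256)
def _truncation_mass(spec: DistributionSpec) -> float:
    base = _base(spec)
    hi = np.inf if spec.cap is None else spec.cap
    mass = float(base.cdf(hi) - base.cdf(spec.lower))
    if mass <= 1e-300:
        raise ValueError(
            f"truncation window [{spec.lower}, {spec.cap}] has zero probability mass"
        )
    return mass


def sample(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. values from the truncated, renormalized law.

    Rejection sampling: redraw until every value lies in [lower, cap].  A
    window of vanishing mass raises instead of looping forever.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec.family == "dirac":
        return np.full(n, spec.mean)
    mass = _truncation_mass(spec)  # fails fast on an empty window
    if mass < 1e-6:
        raise ValueError(
            f"truncation window [{spec.lower}, {spec.cap}] keeps only a fraction "
            f"{mass:.2e} of the probability mass; refusing to rejection-sample"
        )
    base = _base(spec)
    hi = np.inf if spec.cap is None else spec.cap
    out = np.empty(n)
    filled = 0
    for _ in range(_MAX_REJECTION_ROUNDS):
        need = n - filled
        batch = min(int(need / mass * 1.2) + 16, 10_000_000)
        draws = base.rvs(size=batch, random_state=rng)
        good = draws[(draws >= spec.lower) & (draws <= hi)][:need]
        out[filled : filled + good.size] = good
        filled += good.size
        if filled == n:
            return out
    raise RuntimeError(
        f"rejection sampling did not fill {n} draws in "
        f"{_MAX_REJECTION_ROUNDS} rounds (acceptance region too small?)"
    )


def pdf(spec: DistributionSpec, x) -> np.ndarray | float:
    """Renormalized truncated density.  Dirac laws are atomic: no density."""
    if spec.family == "dirac":
        raise AtomicDistributionError(
            "dirac law is atomic; use cdf() or handle the point mass symbolically"
        )
    mass = _truncation_mass(spec)
    base = _base(spec)
    hi = np.inf if spec.cap is None else spec.cap
    x = np.asarray(x, dtype=float)
    inside = (x >= spec.lower) & (x <= hi)
    val = np.where(inside, base.pdf(x) / mass, 0.0)
    return val if val.ndim else float(val)


def cdf(spec: DistributionSpec, x) -> np.ndarray | float:
    """CDF of the truncated law (a step function for Dirac)."""
    x = np.asarray(x, dtype=float)
    if spec.family == "dirac":
        val = (x >= spec.mean).astype(float)
        return val if val.ndim else float(val)
    mass = _truncation_mass(spec)
    base = _base(spec)
    val = np.clip((base.cdf(x) - base.cdf(spec.lower)) / mass, 0.0, 1.0)
    return val if val.ndim else float(val)


def support(spec: DistributionSpec) -> tuple[float, float]:
    """Effective support [lo, hi] of the truncated law (hi may be inf)."""
    if spec.family == "dirac":
        return spec.mean, spec.mean
    if spec.family == "uniform":
        lo, hi = max(spec.a, spec.lower), spec.b
    elif spec.family == "normal":
        lo, hi = spec.lower, np.inf
    else:  # gamma
        lo, hi = max(0.0, spec.lower), np.inf
    if spec.cap is not None:
        hi = min(hi, spec.cap)
    return lo, hi


def truncated_mean(spec: DistributionSpec) -> float:
    """Mean of the truncated, renormalized law (numerical)."""
    if spec.family == "dirac":
        return spec.mean
    lo, hi = support(spec)
    # split at the bulk of the mass so sharply peaked laws are not missed
    pts = [spec.mean + c * spec.sd for c in (-8.0, -2.0, 0.0, 2.0, 8.0)]
    edges = [lo, *sorted(p for p in pts if lo < p < hi), hi]
    val = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        v, _ = integrate.quad(
            lambda x: x * pdf(spec, x), a, b, limit=200, epsabs=1e-10, epsrel=1e-10
        )
        val += v
    return float(val)
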