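"""Closed-form FRAP profile curves and their Monte-Carlo oracle.

Filaments lie parallel to the transport axis with right endpoints X0
uniform on [0, F], lengths L, and nonnegative velocities V; at time zero
the interval [y0, y1] is bleached.  The expected fluorescent coverage at
time t and position y is

    H(t, y) = P(some unbleached filament material is at y at time t).

For a *fixed* velocity v the problem collapses onto the traveling-wave
coordinate w = y - v*t and, integrating out X0, the per-(v, l) coverage is
the overlap of the interval (w, w + l) with [0, F], gated by w <= y0 (to
the right of the advancing bleach front nothing fluoresces):

    g(w; l) = max(0, min(w + l, F) - max(w, 0))   if w <= y0, else 0.

The two closed forms are expectations of g/F: over the length law at fixed
velocity (a rigid traveling wave), or over the velocity law at fixed
length (fronts that smear out over time).  Both are validated against a
brute-force Monte-Carlo evaluation of the defining triple integral, which
applies the unbleached/partially-bleached membership tests literally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .core import BleachGeometry, ProfileCurve
from .distributions import DistributionSpec, pdf, sample, support

__all__ = [
    "coverage_kernel",
    "profile_fixed_velocity",
    "profile_fixed_length",
    "evaluate_profile_grid",
    "MonteCarloOracle",
    "profile_monte_carlo_oracle",
    "recovery_curve",
    "initial_coverage_density",
]

_QUAD_OPTS = dict(epsabs=1e-10, epsrel=1e-9, limit=200)


def coverage_kernel(w, ell: float, F: float, y0: float):
    """Overlap of (w, w + ell) with [0, F], zero beyond the bleach front.

    ``w`` is the traveling-wave coordinate of the evaluation point relative
    to a filament moving at the fixed velocity; vectorized in ``w``.
    """
    w = np.asarray(w, dtype=float)
    overlap = np.minimum(w + ell, F) - np.maximum(w, 0.0)
    val = np.where(w <= y0, np.maximum(overlap, 0.0), 0.0)
    return val if val.ndim else float(val)


def _expect(spec: DistributionSpec, fn, breakpoints) -> float:
    """E[fn(X)] under the truncated law, splitting quadrature at breakpoints."""
    if spec.family == "dirac":
        return float(fn(spec.mean))
    lo, hi = support(spec)
    pts = sorted({float(p) for p in breakpoints if lo < p < hi})
    edges = [lo, *pts, hi]
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        val, _ = integrate.quad(lambda x: fn(x) * pdf(spec, x), a, b, **_QUAD_OPTS)
        total += val
    return total


def profile_fixed_velocity(
    v: float,
    length_law: DistributionSpec,
    geom: BleachGeometry,
    t: float,
    y: float,
) -> float:
    """H(t, y) when every filament moves at the same velocity ``v``.

    Depends on (t, y) only through w = y - v*t; the profile is a rigid
    traveling wave.  The length integral is symbolic for a Dirac length
    and adaptive quadrature otherwise (integrand piecewise linear in l
    with breakpoints at -w and F - w).
    """
    if v < 0 or t < 0:
        raise ValueError("need v >= 0 and t >= 0")
    w = y - v * t
    if w > geom.y0:
        return 0.0
    return _expect(
        length_law,
        lambda ell: coverage_kernel(w, ell, geom.F, geom.y0),
        (-w, geom.F - w),
    ) / geom.F


def profile_fixed_length(
    ell: float,
    velocity_law: DistributionSpec,
    geom: BleachGeometry,
    t: float,
    y: float,
) -> float:
    """H(t, y) when every filament has the same length ``ell``.

    The velocity integral runs over w(v) = y - v*t; quadrature is split at
    the velocities where w crosses the kernel's kinks (y0, F - ell, 0,
    -ell).  t = 0 is the bleach-time limit, evaluated directly from the
    kernel; a Dirac velocity delegates to the fixed-velocity form (the two
    closed forms coincide there).
    """
    if ell <= 0:
        raise ValueError("ell must be positive")
    if velocity_law.family == "dirac":
        from .distributions import make_distribution

        return profile_fixed_velocity(
            velocity_law.mean, make_distribution("dirac", mean=ell), geom, t, y
        )
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0.0:
        return coverage_kernel(y, ell, geom.F, geom.y0) / geom.F
    crossings = [(y - c) / t for c in (geom.y0, geom.F - ell, 0.0, -ell)]
    return _expect(
        velocity_law,
        lambda v: coverage_kernel(y - v * t, ell, geom.F, geom.y0),
        crossings,
    ) / geom.F


def evaluate_profile_grid(
    geom: BleachGeometry,
    times,
    positions,
    *,
    velocity_law: DistributionSpec | None = None,
    length_law: DistributionSpec | None = None,
) -> ProfileCurve:
    """Evaluate whichever closed form applies on a (times x positions) grid.

    Exactly one of the two laws may be non-Dirac: a genuinely random
    velocity *and* random length has no closed form (use the simulator).
    """
    if velocity_law is None or length_law is None:
        raise ValueError("both velocity_law and length_law are required")
    v_random = velocity_law.family != "dirac"
    l_random = length_law.family != "dirac"
    if v_random and l_random:
        raise ValueError(
            "no closed form exists when both velocity and length are random; "
            "use the stochastic simulator"
        )
    times = np.atleast_1d(np.asarray(times, dtype=float))
    positions = np.atleast_1d(np.asarray(positions, dtype=float))
    out = np.empty((times.size, positions.size))
    for i, t in enumerate(times):
        for j, y in enumerate(positions):
            if v_random:
                out[i, j] = profile_fixed_length(length_law.mean, velocity_law, geom, t, y)
            else:
                out[i, j] = profile_fixed_velocity(velocity_law.mean, length_law, geom, t, y)
    return ProfileCurve(times, positions, out, provenance="theory")


class MonteCarloOracle:
    """Brute-force estimate of H(t, y) from the defining triple integral.

    Draws (x0, v, l) once and evaluates, at any (t, y), the fraction of
    draws that are unbleached-and-covering (right endpoint past y, left
    endpoint before y, x0 left of the bleach) or partially bleached and
    covering with the truncated length l - (x0 - y0).  Serves as the
    independent check on both closed forms.
    """

    def __init__(
        self,
        velocity_law: DistributionSpec,
        length_law: DistributionSpec,
        geom: BleachGeometry,
        n_draws: int,
        rng: np.random.Generator,
    ) -> None:
        if n_draws < 10_000:
            raise ValueError("use at least 10^4 draws for a meaningful oracle")
        self.geom = geom
        self.n = int(n_draws)
        self.x0 = rng.uniform(0.0, geom.F, self.n)
        self.v = sample(velocity_law, self.n, rng)
        self.ell = sample(length_law, self.n, rng)

    def estimate(self, t: float, y: float) -> tuple[float, float]:
        """Return (H estimate, Monte-Carlo standard error) at (t, y)."""
        x0, v, ell, y0 = self.x0, self.v, self.ell, self.geom.y0
        right = x0 + v * t
        in_U = (right > y) & (right - ell < y) & (x0 < y0)
        right_b = y0 + v * t
        ell_b = ell - (x0 - y0)
        in_B = (right_b > y) & (right_b - ell_b < y) & (x0 > y0) & (x0 - ell < y0)
        hits = in_U | in_B
        p = float(hits.mean())
        se = math.sqrt(max(p * (1.0 - p), 0.0) / self.n)
        return p, se


def profile_monte_carlo_oracle(
    velocity_law: DistributionSpec,
    length_law: DistributionSpec,
    geom: BleachGeometry,
    t: float,
    y: float,
    n_draws: int,
    seed,
) -> tuple[float, float]:
    """One-shot oracle evaluation; returns (estimate, standard error)."""
    rng = np.random.default_rng(seed)
    return MonteCarloOracle(velocity_law, length_law, geom, n_draws, rng).estimate(t, y)


def recovery_curve(profile_fn, geom: BleachGeometry, times) -> np.ndarray:
    """Total fluorescence in the bleached window over time.

    ``profile_fn(t, y)`` is any profile evaluator; returns the integral of
    H(t, .) over [y0, y1] at each requested time.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    out = np.empty(times.size)
    for i, t in enumerate(times):
        val, _ = integrate.quad(
            lambda y: profile_fn(t, y), geom.y0, geom.y1, epsabs=1e-9, limit=200
        )
        out[i] = val
    return out


def binned_coverage(lefts: np.ndarray, rights: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Total interval length overlapping each bin, per unit bin width.

    Uses the cumulative covered length C(x) = sum_i clip(x - l_i, 0, r_i - l_i),
    evaluated at all bin edges in O((n + m) log n).
    """
    lefts = np.sort(np.asarray(lefts, dtype=float))
    order = np.argsort(rights)
    rights_sorted = np.asarray(rights, dtype=float)[order]
    cum_l = np.concatenate(([0.0], np.cumsum(lefts)))
    cum_r = np.concatenate(([0.0], np.cumsum(rights_sorted)))
    nl = np.searchsorted(lefts, edges, side="right")
    nr = np.searchsorted(rights_sorted, edges, side="right")
    C = (edges * nl - cum_l[nl]) - (edges * nr - cum_r[nr])
    return np.diff(C) / np.diff(edges)


def initial_coverage_density(
    length_law: DistributionSpec,
    geom: BleachGeometry,
    bin_width: float,
    n_filaments: int,
    seed,
    *,
    normalization: str = "nonzero_mean",
    plateau_window: tuple[float, float] | None = None,
) -> tuple[ProfileCurve, float]:
    """Pre-bleach filament density profile and its plateau variability.

    Places right endpoints uniformly on [0, F], bins the coverage density
    over the evaluation domain, normalizes, and reports the standard
    deviation of the bin values restricted to the plateau (the interior
    region unaffected by the [0, F] placement boundaries).  Short filaments
    produce a noisier plateau than long ones at equal filament count.
    """
    if n_filaments < 1:
        raise ValueError("need at least one filament")
    rng = np.random.default_rng(seed)
    x0 = rng.uniform(0.0, geom.F, n_filaments)
    ell = sample(length_law, n_filaments, rng)
    lo, hi = geom.domain
    edges = np.arange(lo, hi + bin_width, bin_width)
    density = binned_coverage(x0 - ell, x0, edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if plateau_window is None:
        margin = length_law.mean + 4.0 * length_law.sd
        plateau_window = (0.0, geom.F - margin)
    curve = ProfileCurve(
        np.array([0.0]), centers, density[None, :], provenance="simulation"
    ).normalized(normalization, plateau_window=plateau_window)
    mask = (centers >= plateau_window[0]) & (centers <= plateau_window[1])
    if not mask.any():
        raise ValueError("plateau window contains no bins")
    plateau_sd = float(np.std(curve.intensity[0, mask], ddof=1))
    return curve, plateau_sd
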