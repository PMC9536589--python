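"""Calibrating velocity and pause distributions against profile-curve data.

The objective is the mean absolute deviation between a simulated and an
observed profile on a common (time x position) grid, restricted to a fit
window around the bleached region:

    E = sum_ij |s(t_i, x_j) - d(t_i, x_j)| / (M N).

The simulator is stochastic, so each of ``n_realizations`` realizations is
optimized with its simulation seed held fixed (common random numbers make
E deterministic in the parameters for that realization); the reported fit
is the realization with the smallest optimized E.  Both curves are scaled
to plateau-mean one before comparison, so E is in normalized intensity
units.

The filament length law is held fixed during fitting (uniform with mean
5.025 um by default): profile curves carry essentially no length
information, so freeing it only inflates the search space.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .core import BleachGeometry, ProfileCurve
from .distributions import (
    DistributionSpec,
    make_distribution,
    truncated_mean,
    velocity_cap_default,
)
from .simulator import SimulationConfig, simulate_profile
from .theory import evaluate_profile_grid

__all__ = [
    "FitResult",
    "objective_E",
    "fit",
    "fit_theory",
    "summarize_dynamics",
    "default_fit_window",
    "default_plateau_window",
    "default_length_law",
]

#: length law held fixed during fitting (mean 5.025 um, shifted off zero)
def default_length_law() -> DistributionSpec:
    return make_distribution("uniform", bounds=(0.05, 10.0))


def default_fit_window(geom: BleachGeometry) -> tuple[float, float]:
    """Bleached region plus one bleach-width flank on each side."""
    w = geom.bleach_width
    return (geom.y0 - w, geom.y1 + w)


def default_plateau_window(geom: BleachGeometry) -> tuple[float, float]:
    """A window left of y0 where coverage stays at its plateau value."""
    w = geom.bleach_width
    return (geom.y0 - 2.0 * w, geom.y0 - 0.25 * w)


def objective_E(
    simulated: ProfileCurve,
    observed: ProfileCurve,
    fit_window: tuple[float, float] | None = None,
) -> float:
    """Mean absolute deviation over the shared grid inside ``fit_window``.

    The grids must already be aligned; resampling is an explicit, separate
    step, never done silently here.
    """
    if simulated.times.size != observed.times.size or not np.allclose(
        simulated.times, observed.times, atol=1e-9
    ):
        raise ValueError("time grids differ between simulated and observed curves")
    if simulated.positions.size != observed.positions.size or not np.allclose(
        simulated.positions, observed.positions, atol=1e-9
    ):
        raise ValueError("position grids differ between simulated and observed curves")
    if fit_window is None:
        mask = np.ones(observed.positions.size, dtype=bool)
    else:
        lo, hi = fit_window
        mask = (observed.positions >= lo) & (observed.positions <= hi)
        if not mask.any():
            raise ValueError(f"fit window {fit_window} contains no grid positions")
    return float(np.mean(np.abs(simulated.intensity[:, mask] - observed.intensity[:, mask])))


# -- parameter vector <-> distribution plumbing --------------------------

_VEL_BOUNDS = {"mean": (0.01, velocity_cap_default), "sd": (0.01, 20.0)}
_TAU_BOUNDS = (0.05, 30.0)


def _param_names(velocity_family: str, sim_type: int) -> list[str]:
    names = ["mean"] if velocity_family in ("dirac", "uniform") else ["mean", "sd"]
    if sim_type == 3:
        names += ["tau_on", "tau_off"]
    return names


def _bounds(names: list[str]) -> list[tuple[float, float]]:
    return [_VEL_BOUNDS.get(n, _TAU_BOUNDS) for n in names]


def _velocity_law(family: str, params: dict) -> DistributionSpec:
    if family == "dirac":
        return make_distribution("dirac", mean=params["mean"])
    if family == "uniform":
        return make_distribution("uniform", mean=params["mean"])
    return make_distribution(
        family, mean=params["mean"], sd=params["sd"], cap=velocity_cap_default
    )


def _config_for(
    template: SimulationConfig, family: str, params: dict
) -> SimulationConfig:
    kwargs: dict = {"velocity_law": _velocity_law(family, params)}
    if template.sim_type == 3:
        kwargs["on_law"] = make_distribution("uniform", mean=params["tau_on"])
        kwargs["off_law"] = make_distribution("uniform", mean=params["tau_off"])
    return replace(template, **kwargs)


@dataclass
class FitResult:
    """Best-fit parameters plus the dynamics summaries they imply."""

    velocity_family: str
    sim_type: int
    params: dict
    E_min: float
    E_values: list[float]
    per_realization_params: list[dict]
    n_failed: int
    seed: int | None
    derived: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.derived:
            law = _velocity_law(self.velocity_family, self.params)
            v_on = truncated_mean(law)
            if self.sim_type == 3:
                tau_on = self.params["tau_on"]
                tau_off = self.params["tau_off"]
                frac_moving = tau_on / (tau_on + tau_off)
            else:
                tau_on, tau_off, frac_moving = np.inf, 0.0, 1.0
            self.derived = {
                "v_on_um_min": v_on,
                "v_mean_um_min": v_on * frac_moving,
                "v_on_um_s": v_on / 60.0,
                "v_mean_um_s": v_on * frac_moving / 60.0,
                "stationary_pct": 100.0 * (1.0 - frac_moving),
                "paused_time_pct": 100.0 * (1.0 - frac_moving),
            }

    def to_dict(self) -> dict:
        return {
            "velocity_family": self.velocity_family,
            "sim_type": self.sim_type,
            "params": self.params,
            "E_min": self.E_min,
            "E_values": self.E_values,
            "per_realization_params": self.per_realization_params,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "derived": self.derived,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _multistart_minimize(fun, bounds, n_starts, rng_seed, maxfev):
    """Bounded derivative-free search in log-parameter space.

    Parameters span orders of magnitude (velocities 0.01-40 um/min), so the
    search runs on z = log(x).  A Latin-hypercube batch of candidate points
    is scored first and Nelder-Mead polishes the ``n_starts`` best of them;
    returns (best objective, best x) or None if nothing evaluated finite.
    """
    dim = len(bounds)
    z_lo = np.log([b[0] for b in bounds])
    z_hi = np.log([b[1] for b in bounds])
    sampler = qmc.LatinHypercube(d=dim, seed=rng_seed)
    cand = z_lo + sampler.random(max(8 * dim, 2 * n_starts)) * (z_hi - z_lo)
    scores = np.array([fun(np.exp(z)) for z in cand])
    if not np.isfinite(scores).any():
        return None
    best_fun, best_x = np.inf, None
    for idx in np.argsort(scores)[:n_starts]:
        res = optimize.minimize(
            lambda z: fun(np.exp(z)),
            cand[idx],
            method="Nelder-Mead",
            bounds=list(zip(z_lo, z_hi)),
            options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-6},
        )
        if np.isfinite(res.fun) and res.fun < best_fun:
            best_fun, best_x = float(res.fun), np.exp(res.x)
    if best_x is None:
        return None
    return best_fun, best_x


def fit(
    observed: ProfileCurve,
    template: SimulationConfig,
    velocity_family: str,
    n_realizations: int = 30,
    seed: int = 0,
    *,
    n_starts: int = 3,
    fit_window: tuple[float, float] | None = None,
    plateau_window: tuple[float, float] | None = None,
    maxfev: int = 200,
) -> FitResult:
    """Calibrate the velocity (and, for type 3, on/off) laws to ``observed``.

    ``template`` fixes everything the optimizer does not touch: geometry,
    filament count, output times, bin width, window and the length law.
    ``observed`` and each simulated curve are rescaled to plateau-mean one
    before computing E.
    """
    geom = template.geom
    if fit_window is None:
        fit_window = default_fit_window(geom)
    if plateau_window is None:
        plateau_window = default_plateau_window(geom)
    names = _param_names(velocity_family, template.sim_type)
    bounds = _bounds(names)
    obs = observed.normalized("plateau_mean", plateau_window=plateau_window)
    template = replace(
        template, output_times=tuple(obs.times), n_realizations=1, window=template.window
    )

    records: list[tuple[float, dict]] = []
    n_failed = 0
    for r in range(n_realizations):
        sim_seed = np.random.SeedSequence([seed, 7919 + r])

        def E_of(x: np.ndarray) -> float:
            params = dict(zip(names, x))
            try:
                cfg = _config_for(template, velocity_family, params)
                sim = simulate_profile(cfg, sim_seed).normalized(
                    "plateau_mean", plateau_window=plateau_window
                )
                return objective_E(sim, obs, fit_window)
            except (ValueError, RuntimeError):
                return np.inf

        res = _multistart_minimize(E_of, bounds, n_starts, seed * 1000 + r, maxfev)
        if res is None:
            n_failed += 1
            warnings.warn(f"realization {r}: optimizer failed to produce a finite E")
            continue
        best_E, best_x = res
        records.append((best_E, dict(zip(names, best_x))))

    if not records:
        raise RuntimeError("every realization failed to optimize")
    E_values = [e for e, _ in records]
    best_idx = int(np.argmin(E_values))
    return FitResult(
        velocity_family,
        template.sim_type,
        records[best_idx][1],
        E_values[best_idx],
        E_values,
        [p for _, p in records],
        n_failed,
        seed,
    )


def fit_theory(
    observed: ProfileCurve,
    velocity_family: str,
    geom: BleachGeometry,
    ell: float,
    seed: int = 0,
    *,
    n_starts: int = 3,
    fit_window: tuple[float, float] | None = None,
    plateau_window: tuple[float, float] | None = None,
    maxfev: int = 400,
) -> FitResult:
    """Deterministic fit of the fixed-length closed form (no realizations)."""
    if fit_window is None:
        fit_window = default_fit_window(geom)
    if plateau_window is None:
        plateau_window = default_plateau_window(geom)
    names = _param_names(velocity_family, sim_type=1)
    bounds = _bounds(names)
    obs = observed.normalized("plateau_mean", plateau_window=plateau_window)
    length_law = make_distribution("dirac", mean=ell)

    def E_of(x: np.ndarray) -> float:
        params = dict(zip(names, x))
        try:
            law = _velocity_law(velocity_family, params)
            theo = evaluate_profile_grid(
                geom, obs.times, obs.positions, velocity_law=law, length_law=length_law
            ).normalized("plateau_mean", plateau_window=plateau_window)
            return objective_E(theo, obs, fit_window)
        except (ValueError, RuntimeError):
            return np.inf

    res = _multistart_minimize(E_of, bounds, n_starts, seed, maxfev)
    if res is None:
        raise RuntimeError("theory fit failed to produce a finite objective")
    best_E, best_x = res
    params = dict(zip(names, best_x))
    return FitResult(velocity_family, 1, params, best_E, [best_E], [params], 0, seed)


def summarize_dynamics(fits: list[FitResult], labels: list[str] | None = None) -> pd.DataFrame:
    """Tabulate per-dataset and aggregate transport summaries.

    Velocities are reported in both um/min (the working unit) and um/s;
    the stationary percentage is 100 * tau_off / (tau_on + tau_off).
    """
    if not fits:
        raise ValueError("no fits to summarize")
    rows = []
    for i, f in enumerate(fits):
        rows.append(
            {
                "dataset": labels[i] if labels else f"dataset_{i}",
                "velocity_family": f.velocity_family,
                "sim_type": f.sim_type,
                "E_min": f.E_min,
                "tau_on_min": f.params.get("tau_on", np.inf),
                "tau_off_min": f.params.get("tau_off", 0.0),
                **f.derived,
            }
        )
    df = pd.DataFrame(rows)
    agg = df.drop(columns=["dataset", "velocity_family", "sim_type"]).mean(numeric_only=True)
    agg["dataset"] = "aggregate_mean"
    return pd.concat([df, agg.to_frame().T], ignore_index=True)
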