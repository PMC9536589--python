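"""Shared containers: bleach geometry and fluorescence profile curves.

A FRAP experiment on anterogradely transported filaments is summarised by a
*profile curve*: fluorescence intensity sampled on a (time x position) grid
across and around the bleached interval [y0, y1].  Filament right endpoints
are initially placed uniformly on [0, F]; everything downstream (closed-form
theory, stochastic simulation, experimental data) produces the same
container so that curves can be compared on a common grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["BleachGeometry", "ProfileCurve"]


@dataclass(frozen=True)
class BleachGeometry:
    """Domain and bleach-window geometry (all lengths in micrometres).

    Parameters
    ----------
    F
        Right edge of the interval [0, F] on which filament right endpoints
        are placed uniformly at time zero.
    y0, y1
        Left and right edges of the bleached interval, ``y0 < y1``.
    domain
        Evaluation/binning interval; defaults to ``(0, F)``.
    allow_y0_beyond_F
        Permit ``y0 > F``.  Used only for the pre-bleach density analysis
        where the "bleach" is pushed past the placement interval so that no
        material is actually bleached.
    """

    F: float
    y0: float
    y1: float
    domain: tuple[float, float] | None = None
    allow_y0_beyond_F: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.y0 < self.y1):
            raise ValueError(f"need 0 <= y0 < y1, got y0={self.y0}, y1={self.y1}")
        if self.F <= 0:
            raise ValueError("F must be positive")
        if self.y0 > self.F and not self.allow_y0_beyond_F:
            raise ValueError(
                "y0 > F leaves the bleached region empty of filaments; "
                "set allow_y0_beyond_F=True if this is intentional"
            )
        if self.domain is None:
            object.__setattr__(self, "domain", (0.0, float(self.F)))

    @property
    def bleach_width(self) -> float:
        return self.y1 - self.y0


_NORMALIZATIONS = ("none", "sup_one", "plateau_mean", "nonzero_mean")


@dataclass
class ProfileCurve:
    """Fluorescence intensity on a (time x position) grid.

    ``intensity[i, j]`` is the intensity at ``times[i]`` (minutes) and
    ``positions[j]`` (micrometres), in arbitrary units, nonnegative.
    """

    times: np.ndarray
    positions: np.ndarray
    intensity: np.ndarray
    normalization: str = "none"
    provenance: str = "theory"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.times.size, self.positions.size):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match "
                f"(n_times={self.times.size}, n_positions={self.positions.size})"
            )
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def normalized(
        self, mode: str = "sup_one", plateau_window: tuple[float, float] | None = None
    ) -> "ProfileCurve":
        """Return a rescaled copy.

        ``sup_one`` divides by the grid maximum (the theory papers'
        convention, sup-norm one); ``plateau_mean`` divides by the mean
        intensity over ``plateau_window`` (all times pooled), the convention
        used to put simulation and data on a common scale; ``nonzero_mean``
        divides by the mean of strictly positive entries.
        """
        if mode == "none":
            return replace(self, intensity=self.intensity.copy())
        if mode == "sup_one":
            scale = float(np.max(self.intensity))
        elif mode == "plateau_mean":
            if plateau_window is None:
                raise ValueError("plateau_mean normalization needs plateau_window")
            lo, hi = plateau_window
            mask = (self.positions >= lo) & (self.positions <= hi)
            if not mask.any():
                raise ValueError(f"no positions inside plateau window {plateau_window}")
            scale = float(np.mean(self.intensity[:, mask]))
        elif mode == "nonzero_mean":
            pos = self.intensity[self.intensity > 0]
            scale = float(np.mean(pos)) if pos.size else 0.0
        else:
            raise ValueError(f"unknown normalization mode {mode!r}")
        if scale <= 0:
            raise ValueError("cannot normalize an all-zero profile")
        return replace(self, intensity=self.intensity / scale, normalization=mode)

    # -- long-format CSV round trip --------------------------------------

    def to_frame(self) -> pd.DataFrame:
        tt, pp = np.meshgrid(self.times, self.positions, indexing="ij")
        return pd.DataFrame(
            {
                "time_min": tt.ravel(),
                "position_um": pp.ravel(),
                "intensity_au": self.intensity.ravel(),
                "source": self.provenance,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ProfileCurve":
        df = pd.read_csv(path)
        times = np.unique(df["time_min"].to_numpy())
        positions = np.unique(df["position_um"].to_numpy())
        wide = df.pivot_table(
            index="time_min", columns="position_um", values="intensity_au"
        )
        wide = wide.reindex(index=times, columns=positions)
        provenance = str(df["source"].iloc[0]) if "source" in df else "experiment"
        return cls(times, positions, wide.to_numpy(), provenance=provenance)
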