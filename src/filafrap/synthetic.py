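"""Ground-truth FRAP datasets and the experimental-spreadsheet reader.

A synthetic dataset is a simulated profile curve from a known parameter
set (the ground truth travels with the data), degraded by a simple
measurement-noise model: additive Gaussian noise on the plateau-normalized
intensity, optionally with a per-time multiplicative gain jitter.  The
noise model is a package choice — it emulates detector noise on a
normalized profile, not microscope optics.

Experimental spreadsheets are read sheet-by-sheet.  The canonical dialect
written by this package is one sheet per dataset: column one holds
position (um), each further column one post-bleach time with the time (in
minutes) in the header.  Long-format sheets (time/position/intensity
columns) are also accepted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ProfileCurve
from .distributions import DistributionSpec
from .fitting import default_plateau_window
from .simulator import SimulationConfig, simulate_profile

__all__ = [
    "SyntheticDatasetSpec",
    "generate_dataset",
    "generate_batch",
    "write_dataset_xlsx",
    "read_experimental_xlsx",
    "XlsxValidationError",
]


class XlsxValidationError(ValueError):
    """Raised with an itemized report when a spreadsheet cannot be parsed."""


@dataclass
class SyntheticDatasetSpec:
    """Generating configuration plus the measurement-noise model.

    ``config`` holds the ground-truth motion parameters; the truth record
    returned by :func:`generate_dataset` is built from it.  Noise sd is on
    the plateau-normalized intensity scale (plateau = 1).
    """

    config: SimulationConfig
    sigma_noise: float = 0.02
    gain_jitter_sd: float = 0.0
    name: str = "synthetic"
    plateau_window: tuple[float, float] | None = None

    def truth_record(self, seed) -> dict:
        cfg = self.config

        def law(d: DistributionSpec | None):
            return None if d is None else d.to_dict()

        return {
            "name": self.name,
            "sim_type": cfg.sim_type,
            "n_filaments": cfg.n_filaments,
            "velocity_law": law(cfg.velocity_law),
            "length_law": law(cfg.length_law),
            "on_law": law(cfg.on_law),
            "off_law": law(cfg.off_law),
            "geometry": {"F": cfg.geom.F, "y0": cfg.geom.y0, "y1": cfg.geom.y1},
            "sigma_noise": self.sigma_noise,
            "gain_jitter_sd": self.gain_jitter_sd,
            "seed": str(seed),
        }


def generate_dataset(
    spec: SyntheticDatasetSpec, seed=None
) -> tuple[ProfileCurve, dict]:
    """Simulate a ground-truth curve, normalize, and add measurement noise.

    Returns the noisy curve (provenance "experiment", plateau-mean one
    before noise) and the ground-truth record including the seed.
    """
    base = seed if seed is not None else spec.config.seed
    ss = base if isinstance(base, np.random.SeedSequence) else np.random.SeedSequence(base)
    sim_ss, noise_ss = ss.spawn(2)
    plateau = spec.plateau_window or default_plateau_window(spec.config.geom)
    truth = simulate_profile(spec.config, sim_ss).normalized(
        "plateau_mean", plateau_window=plateau
    )
    rng = np.random.default_rng(noise_ss)
    intensity = truth.intensity.copy()
    if spec.gain_jitter_sd > 0:
        gains = 1.0 + rng.normal(0.0, spec.gain_jitter_sd, size=truth.times.size)
        intensity *= gains[:, None]
    if spec.sigma_noise > 0:
        intensity += rng.normal(0.0, spec.sigma_noise, size=intensity.shape)
    np.clip(intensity, 0.0, None, out=intensity)
    curve = replace(truth, intensity=intensity, provenance="experiment")
    return curve, spec.truth_record(base)


def generate_batch(
    specs: list[SyntheticDatasetSpec], seed: int = 0
) -> list[tuple[ProfileCurve, dict]]:
    """Generate several datasets from one master seed (one child each)."""
    children = np.random.SeedSequence(seed).spawn(len(specs))
    return [generate_dataset(s, c) for s, c in zip(specs, children)]


# -- spreadsheet I/O ------------------------------------------------------


def write_dataset_xlsx(
    curves: list[ProfileCurve],
    path: str | Path,
    names: list[str] | None = None,
    truths: list[dict] | None = None,
) -> None:
    """Write curves in the canonical wide layout, one sheet per dataset.

    If ground-truth records are supplied they are written to a JSON sidecar
    next to the spreadsheet.
    """
    path = Path(path)
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        for i, curve in enumerate(curves):
            name = names[i] if names else f"dataset_{i + 1}"
            df = pd.DataFrame({"position_um": curve.positions})
            for j, t in enumerate(curve.times):
                df[float(t)] = curve.intensity[j]
            df.to_excel(xl, sheet_name=name, index=False)
    if truths is not None:
        sidecar = path.with_suffix(".truth.json")
        sidecar.write_text(json.dumps(truths, indent=2))


def _parse_wide(df: pd.DataFrame) -> ProfileCurve:
    times = []
    for c in df.columns[1:]:
        times.append(float(str(c).lstrip("tT= ").rstrip("mins ")))
    positions = df.iloc[:, 0].to_numpy(dtype=float)
    intensity = df.iloc[:, 1:].to_numpy(dtype=float).T
    return ProfileCurve(np.array(times), positions, intensity, provenance="experiment")


def _parse_long(df: pd.DataFrame) -> ProfileCurve:
    cols = {str(c).lower(): c for c in df.columns}

    def find(prefix):
        for k, c in cols.items():
            if k.startswith(prefix):
                return c
        raise KeyError(prefix)

    t_col, p_col, i_col = find("time"), find("pos"), find("intens")
    wide = df.pivot_table(index=t_col, columns=p_col, values=i_col)
    return ProfileCurve(
        wide.index.to_numpy(dtype=float),
        wide.columns.to_numpy(dtype=float),
        wide.to_numpy(dtype=float),
        provenance="experiment",
    )


def read_experimental_xlsx(path: str | Path) -> dict[str, ProfileCurve]:
    """Parse a spreadsheet of profile-curve datasets, one sheet each.

    Tries the wide layout first (position column + one column per time),
    then long format.  Header rows are auto-detected by searching for the
    first row whose leading cell parses as a number.  All failing sheets
    are reported together.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    book = pd.read_excel(path, sheet_name=None, header=None)
    curves: dict[str, ProfileCurve] = {}
    errors: list[str] = []
    for sheet, raw in book.items():
        raw = raw.dropna(axis=1, how="all").dropna(axis=0, how="all")
        if raw.empty:
            errors.append(f"sheet {sheet!r}: empty")
            continue
        header_row = None
        for r in range(min(len(raw), 20)):
            try:
                float(raw.iloc[r, 0])
            except (TypeError, ValueError):
                continue
            header_row = r - 1
            break
        if header_row is None or header_row < 0:
            errors.append(f"sheet {sheet!r}: no numeric data row found")
            continue
        df = raw.iloc[header_row + 1 :].copy()
        df.columns = raw.iloc[header_row]
        df = df.reset_index(drop=True)
        try:
            try:
                curves[sheet] = _parse_long(df)
            except KeyError:
                curves[sheet] = _parse_wide(df)
        except Exception as exc:  # report, do not crash on one bad sheet
            errors.append(f"sheet {sheet!r}: {exc}")
    if errors:
        raise XlsxValidationError(
            "could not parse spreadsheet:\n  " + "\n  ".join(errors)
        )
    return curves
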