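# filafrap

Analysis of FRAP (Fluorescence Recovery After Photobleaching) intensity
profile curves for elongated structures under directed transport —
intermediate filaments carried anterogradely along microtubules being the
motivating case.  Classical FRAP models assume diffusing point-like
molecules; when the fluorescent objects are micron-long filaments moving
unidirectionally, recovery is governed by transport geometry instead, and a
different model is needed.  This package is for quantitative cell biologists
and modelers who want to turn profile-curve data into estimates of the
filament velocity distribution and pause statistics.

## Model

Filaments lie along the transport axis with right endpoints `X0 ~ U[0, F]`,
fixed lengths `L`, and nonnegative velocities `V`; the right endpoint moves
as `x(t) = v t + x0`.  At `t = 0` the interval `[y0, y1]` is bleached;
bleached material keeps moving but is invisible, and a filament straddling
`y0` keeps only its tail left of `y0` (new right endpoint `y0`, new length
`y0 − (x0 − ℓ)`).  The expected fluorescent coverage ("profile curve") is

    H(t, y) = P(some unbleached filament material is at y at time t)
            = (1/F) · E[ g(y − V t; L) ],
    g(w; ℓ) = max(0, min(w + ℓ, F) − max(w, 0))   for w ≤ y0, else 0.

Two closed forms follow: fixed velocity + random length (a rigid traveling
wave in `w = y − v t`) and fixed length + random velocity (fronts that smear
over time; the shape is set by the velocity law — piecewise linear for
uniform, sigmoidal for normal/gamma).  Both are validated against a
brute-force Monte-Carlo evaluation of the defining triple integral.

Three stochastic simulators produce profile curves when no closed form
exists: **type 1** (one velocity per filament, forever), **type 2**
(velocity redrawn after each moving period `T_on`), **type 3** (stop-and-go:
pauses `T_off` between moving periods).  At steady state a fraction
`τ_on / (τ_on + τ_off)` of filaments is moving.  Fitting minimizes the mean
absolute deviation

    E = Σ_ij |s(t_i, x_j) − d(t_i, x_j)| / (M N)

between simulated and observed curves over several common-random-number
realizations; derived summaries include the moving-filament mean velocity
`v_on`, the overall mean velocity `v = v_on · τ_on/(τ_on + τ_off)`, and the
stationary percentage `100 · τ_off/(τ_on + τ_off)`.

## Worked example

```python
import numpy as np
from filafrap import *

geom = BleachGeometry(F=470, y0=200, y1=210)          # micrometres
velocity = make_distribution("gamma", mean=1.0, sd=0.25, cap=40.0)
length = make_distribution("dirac", mean=10.0)

# closed-form profile at the centre of the bleach zone
for t in (0.5, 1.0, 3.0, 5.0):
    H = profile_fixed_length(10.0, velocity, geom, t, 205.0)
    print(f"t = {t:3.1f} min   H(t, 205 um) / plateau = {H / (10.0/470.0):.3f}")

# stop-and-go simulation and its steady-state moving fraction
config = SimulationConfig(
    sim_type=3, n_filaments=20_000, velocity_law=velocity, length_law=length,
    geom=geom, output_times=(30.0,),
    on_law=make_distribution("uniform", mean=1.0),
    off_law=make_distribution("uniform", mean=0.5),
)
ensemble = initialize_ensemble(config, seed=0)
print(f"moving fraction at t = 20 min: {moving_fraction(ensemble, 20.0):.3f}")
```

prints

```
t = 0.5 min   H(t, 205 um) / plateau = 0.000
t = 1.0 min   H(t, 205 um) / plateau = 0.000
t = 3.0 min   H(t, 205 um) / plateau = 0.010
t = 5.0 min   H(t, 205 um) / plateau = 0.467
moving fraction at t = 20 min: 0.664
```

Five micrometres into a 10-µm bleach zone, fluorescence is still absent at
1 min (few filaments move 5 µm that fast when the mean velocity is
1 µm/min), reaches 1% of the plateau at 3 min, and recovers to roughly half
the plateau by 5 min — an asymmetric, left-fed recovery.  The simulated
moving fraction sits at the renewal-theory value
τ_on/(τ_on + τ_off) = 1/1.5 ≈ 0.667.

There is also a CLI for reproducible runs:
`filafrap theory|simulate|fit|synth --config cfg.yml --out out/ --seed 1`.

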