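# Methods

## Model and assumptions

Filaments are 1-D segments on the transport axis, independent of each
other, with right endpoints placed uniformly on `[0, F]` and lengths fixed
for the whole observation window (no assembly, disassembly, severing,
fusion or subunit exchange on the minutes time scale modeled here).
Transport is unidirectional (anterograde, velocities ≥ 0); density is
assumed uniform in the direction perpendicular to transport, which reduces
the geometry to one dimension.  Bleaching at `t = 0` darkens `[y0, y1]`
irreversibly without changing motion; only unbleached material fluoresces.

The central quantity is the coverage probability `H(t, y)` that unbleached
filament material overlaps position `y` at time `t`.  Working conditional
on velocity and length and integrating the uniform placement out yields a
single kernel,

    g(w; ℓ) = max(0, min(w + ℓ, F) − max(w, 0)),  applied when w ≤ y0,

with `w = y − v t`, and `H = (1/F) E[g]`.  This one expression contains
both unbleached filaments (right endpoint still left of `y0`) and the
surviving tails of partially bleached filaments; the case splits usually
written out (`w ≤ 0`, `0 < w ≤ y0`, `w > y0`) are the regions where the
min/max resolve differently.  The expectation runs over the length law at
fixed velocity or over the velocity law at fixed length; when both are
random no closed form exists and the simulator is the tool of choice.  The
boundary convention is `H > 0` at `w = y0` exactly (the case boundary
belongs to the fluorescent side); for continuous velocity laws `H` is
continuous in `y` for `t > 0` anyway.

A Monte-Carlo oracle evaluates the defining triple integral directly: draw
`(x0, v, ℓ)`, apply the unbleached and partially-bleached membership tests
literally, and average the indicator.  Every closed-form path is tested
against it; this guards the integral-limit algebra, which is where
transcription errors would hide.

## Distributions

Four families: Dirac (deterministic), uniform, normal, gamma.  Gamma is
parameterized interchangeably by (mean, sd) or shape/scale with
`μ = kθ`, `σ = √k·θ`.  A uniform law given only a mean `μ` has support
`[0, 2μ]`; this convention is also applied to the on/off duration laws,
which are specified only through their means `τ_on`, `τ_off`.  Velocity
laws of the normal and gamma families are truncated to `[0, 40]` µm/min
(40 µm/min being far above any plausible motor-driven filament speed);
truncated densities are renormalized, sampling is by rejection with the
batch size chosen from the analytic window mass, and windows keeping less
than 1e-6 of the mass are refused rather than ground through.

## Simulation

Types 1/2/3 share one representation: per-filament arrays of moving
segments (velocity, duration) separated by pauses.  Positions are exact
piecewise-linear functions of time — there is no time step and hence no
integration-error knob.  Type 1 is a single infinite segment; type 2 has
zero-length pauses; type 3 starts each filament moving with probability
`τ_on/(τ_on + τ_off)` (its stationary value) and otherwise begins with a
freshly drawn pause.  Fresh draws rather than residual-life (stationary
renewal) durations were chosen because only the initial moving fraction is
constrained by the model; the distinction decays within one on/off cycle.

Every stochastic ingredient (placement, lengths, velocities, on-durations,
off-durations, initial phase) uses its own child stream of one seed.
Segment velocities are drawn column-by-column (first segment for all
filaments, then second, ...), which makes the limiting cases collapse
bit-exactly: a zero pause law turns type 3 into type 2, and on-durations
longer than the horizon turn type 2 into type 1, at equal seeds.

Measured intensity is overlap coverage: total unbleached filament length
per spatial bin divided by the bin width (fluorescence is proportional to
visible material, matching the "some part of the filament is at y"
semantics of `H`), computed from cumulative covered length in
`O((n + bins) log n)`.  Default bin width 0.1 µm; 0.5 µm is used on the
fitting grids.  Bleaching applies the endpoint rule exactly and removes
filaments entirely right of `y0`, which can never fluoresce under
rightward motion.

The intrinsic measurement noise of a simulated profile is binomial: the
plateau coverage count is `n ℓ̄ / F` filaments, so the relative plateau
noise is `≈ sqrt(F / (n ℓ̄))` — about 5% at n = 20,000, ℓ = 10 µm,
F = 470 µm.  Sup-norm comparisons between a single simulation and theory
are noise-limited at roughly twice to three times that level; mean-absolute
comparisons sit near 0.8× the average pointwise noise.

## Fitting

The objective is the mean absolute deviation `E` between simulated and
observed profiles on a shared grid, restricted to a fit window (default:
bleach zone plus one bleach width on each flank); both curves are first
rescaled to plateau-mean one over a window left of `y0` (default
`[y0 − 2w, y0 − w/4]`, `w` the bleach width), where coverage remains at its
plateau value throughout the experiment.  Grids must match exactly;
resampling is deliberately not implicit.

The simulator is stochastic, so each of `n_realizations` (default 30)
realizations holds its simulation seed fixed while a bounded derivative-free
search runs over the free parameters — common random numbers make `E`
deterministic per realization.  The search operates on log-parameters
(velocities span 0.01–40 µm/min), scores a Latin-hypercube batch of
8×dim candidates, and polishes the best `n_starts` with Nelder–Mead under
box bounds (velocity mean ≤ 40 µm/min, σ ≤ 20, τ ∈ [0.05, 30] min).  The
reported fit is the minimum-E realization; the full E distribution and all
per-realization optima are kept.  The filament length law is held fixed
(uniform on [0.05, 10] µm, mean 5.025) because profile curves carry
essentially no length information.  A deterministic variant fits the
fixed-length closed form instead of simulations and recovers
self-generated noise-free parameters to quadrature accuracy.

Derived summaries: `v_on` is the truncated-law mean velocity of moving
filaments; the overall mean velocity is `v_on · τ_on/(τ_on + τ_off)`; the
stationary percentage and the per-filament paused-time percentage both
equal `100 · τ_off/(τ_on + τ_off)` under the renewal model.

Known limitation: profile curves constrain the overall mean velocity much
more strongly than the split between moving speed and pausing.  At reduced
problem sizes (10,000 filaments per objective evaluation, 5 realizations)
the expected-E separation between the generating parameters and the
`v_on × moving-fraction` ridge is smaller than the per-realization noise
the optimizer can fit, so the recovered stationary fraction scatters widely
even when the overall mean velocity lands within ±20%.  The
parameter-recovery harness in the test suite and acceptance script
quantifies exactly this.

## Synthetic data

A synthetic dataset is a high-count simulation (default 100,000 filaments)
at known parameters, plateau-normalized, with additive Gaussian noise
(sd 0.02 on the normalized scale by default) and optional per-time gain
jitter, clipped at zero.  The noise model emulates detector noise on a
normalized profile; it does not model the microscope PSF, photobleaching
chemistry, or shot-noise physics, and real data may additionally show
normalization drift and window misalignment that the generator does not
produce — passing the recovery tests therefore demonstrates correctness of
the inference machinery under the model's own assumptions, not robustness
to instrument systematics.  The ground truth (all laws, geometry, seeds)
travels with the dataset as a JSON record.  Spreadsheet I/O uses one sheet
per dataset, a position column plus one column per time point (long-format
sheets are also accepted), with itemized per-sheet validation errors.

## Reference conditions and problem sizes

Unless stated otherwise, examples and tests use: placement interval
F = 470 µm, bleach [200, 210] µm, observation times {0.5, 1, 3, 5} min,
mean velocity 1 µm/min with σ = 0.25 for the random families, filament
length 10 µm (theory comparisons) or uniform mean 5.025 µm (fitting),
τ_on = 1 min, τ_off = 0.5 min, 20,000 filaments per simulation (200,000
for fixed-velocity wave demonstrations), 50 realizations for averaged
profiles, and a reduced recovery protocol of 5 realizations at 10,000
filaments per evaluation with 10 replicate datasets.  Quadrature is
adaptive with absolute tolerance 1e-10 per segment, split at every kink of
the coverage kernel; Dirac laws are handled symbolically, and the `t = 0`
limit of the fixed-length form is a dedicated branch (the velocity
integral's limits contain 1/t).
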