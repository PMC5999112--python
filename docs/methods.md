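# Methods

This note documents the model equations, the tunable parameters and their
defaults, the calibration of the free plume constants, the numerical
conventions, and the known limitations of the simulated regime.  Nothing here
is an empirical claim beyond what the test suite and `scripts/acceptance.py`
compute.

## Wind model

The wind is a two-component, two-dimensional field assembled from processes
separated by time scale:

| term | meaning | model |
|------|---------|-------|
| `U` | streamwise mean | constant within a run (default 1 m/s); cross-stream mean is zero |
| `U_g(t)` | gusts | piecewise-constant steps; Poisson arrivals (`rate_per_run`, default 3), uniform amplitude in ±`amplitude_frac·U` (≤ 0.5), fixed hold (default 10 s); off by default |
| `V_m(t)` | meandering | `a·U·sin(2πt/P)`, identical everywhere; default amplitude 0.2, period 100 s; off by default |
| `u', v'` | turbulence | zero-mean i.i.d. Gaussian draws, redrawn at every evaluation, rms `TI·U` in both components |

Only the ratio `TI = u'_rms/U` matters for the fluctuations; they are
deliberately independent of the instantaneous local wind, so gusts and
meandering shift the mean terms without altering the fluctuation statistics
(this is asserted by a matched-seed test).  Gaussianity is a modeling choice:
only the rms enters anywhere downstream.

Because fluctuations are redrawn independently every step, a tracked particle
performs a random walk whose variance grows as `(TI·U·dt)²` per step, i.e. the
effective eddy diffusivity is `dt`-dependent.  This is inherent to the
"redraw each step" construction (there is no Langevin correlation time); `dt`
is therefore part of the study conditions, not a pure discretization knob,
and is fixed at 0.05 s throughout.

## Puff plume

The source at the origin releases an instantaneous puff of mass `m` every `T`
seconds.  Centers advect with the full instantaneous wind sampled
independently per puff and per step.  Sizes grow with age `a` as

    σ_{h,z}(a) = max(A_{h,z} · a^{B_{h,z}}, σ₀),      B_{h,z} = 1,

and each puff contributes a normalized trivariate Gaussian; on the flight
plane (the release height, `z0 = 0`):

    C(r, t) = Σ_i m / ((2π)^{3/2} σ_h² σ_z) · exp(−|r − r_p,i|²/(2σ_h²)).

The 3-D integral of one puff is exactly `m` (verified by quadrature), and the
peak decays as `a^{−3}` once past the size floor, so a puff that has become
undetectable never becomes detectable again — this justifies pruning dead
puffs.  A config switch (`plume.vertical_term = "printed"`) replaces the
vertical factor with `exp(−z0²/σ_z²)` for fidelity experiments with the
alternative published form; with `z0 = 0` the two coincide.

The growth coefficient couples to the flow as `A = c · TI · U`
(`plume.growth_coupling`, default `c = 0.07`), making the patch spread rate
proportional to the fluctuation rms.  `σ₀` (`plume.sigma_floor_m`, default
0.125 m) is the initial patch size at release: a fresh pulse is a
centimeters-to-decimeters filament, not a point, and the floor also guards
the age-zero singularity of the prefactor.

### Calibration of the free constants

`T`, `m`, `C*`, `c` and `σ₀` are free constants of the scenario.  They were
fixed once, from geometric considerations, and are not adjusted per
condition:

- `T = 1 s`, `m = 1` — pulse cadence and mass scale; with `U = 1 m/s` the
  inter-puff spacing is 1 m.
- `C*` — computed by `calibrate_threshold` such that a puff arriving at the
  reference distance `x_ref = 10 m` has a detectable radius `ρ_ref = 0.3 m`,
  evaluated at the reference turbulence intensity `ti_ref = 0.15` and then
  held fixed for the whole sweep (one sensor, one threshold).  With the
  defaults this gives `C* ≈ 1.82`.
- The trio (`c`, `σ₀`, `ρ_ref`) controls the regime of the navigation
  problem.  Three regime conditions guided the choice: (i) patch radii must
  stay below the puff spacing so detection is intermittent rather than a
  continuous ribbon; (ii) they must exceed `U·T/4 ≈ 0.25 m` over most of the
  corridor so that a surge of one crossing time can bridge the gap to the
  next puff (otherwise every encounter ends in a long cast and search time
  dominates the flight); (iii) the detectable plume must span most of the
  6–20 m start band at every turbulence level, which the size floor
  guarantees at low `TI` (where `A` is small) while the `a^{−3}` peak decay
  truncates the range near ~14 m at `TI = 0.30`.  The detectable half-width
  that results (≈ 0.3–0.45 m) matches the ±0.4 m transverse start band.

Higher turbulence then produces genuinely larger patches at a given distance
(larger `A`, same `C*`), more scattered puff tracks, a noisier upwind
reference, and a shorter detectable range — the four effects whose balance
drives all condition-dependent results.

## Navigator

A point agent at constant ground speed 0.3 m/s; headings are set relative to
the instantaneous wind vector at the agent's own position (optomotor
anemotaxis), including its fluctuation part, so brief downwind motion can
occur in rough wind.  State machine:

- `WAITING` — stationary; first detection starts the flight.
- `IN_PUFF` — fly at 180° to the wind; a stopwatch accumulates the contiguous
  detection time.  At signal loss the stopwatch value is the puff crossing
  time `t_c` (strictly contiguous at `dt` resolution; no gap tolerance).
- `SURGE` — continue upwind for `t_c`, counted from patch exit.  A new
  detection returns to `IN_PUFF` and restarts the measurement.
- `CAST` — counter-turning: legs of duration `t_c` at ± a fixed angle from
  the instantaneous upwind direction, alternating sides; the angle is drawn
  uniformly in [30°, 120°] once per casting cycle, the first side is a fair
  coin flip.  Any detection returns to `IN_PUFF`.

Design points that were genuinely open, and the choices made:

- **Surge timer origin.**  Whether the timed upwind period starts at patch
  entry or exit is ambiguous; the default counts from exit (time inside the
  puff is not part of the surge budget).  The `entry` variant is implemented
  behind `navigator.surge_timer_origin`; since the crossing itself consumes
  exactly `t_c`, that variant degenerates to casting immediately at exit.
- **Re-detection mid-leg** immediately returns to upwind flight and later
  redraws the cast angle (the angle is constant only *within* a cycle).
- Headings change instantaneously (point agent, no turn radius); the
  ground-speed contract `|Δr| = 0.3·dt` holds exactly in every moving mode
  and is asserted per step in the tests.
- The internal-counter baseline replaces `t_c` with a constant τ in both the
  surge and the cast legs, and is otherwise identical, so paired-seed
  comparisons isolate the timing rule.

## Monte-Carlo experiment

Per condition: 10 plume realizations ("fields") × 100 flights (the field is
shared across its flights; every field and every flight has a named
`SeedSequence` stream derived from the master seed by counter-based keys, so
adding conditions or flights never perturbs existing draws).  Fliers start at
rest, uniform in x ∈ [6, 20] m and y ∈ ±0.4 m (±1 m for strong-meander runs,
matching the wider plume envelope).  The field runs for a spin-up of
`1.5 · 20 m / U = 30 s` before fliers are placed, so the puff train spans the
start band.

A flight ends at the first crossing of `x = 0` (the crossing point is
interpolated within the step); success means `|y| ≤ R` there, with
R ∈ {0.15, 0.20, 0.25} m.  Censoring: flights that pass 25 m downstream or
exceed 600 s are failures; fliers that never detect anything are excluded
from all statistics.  Success probability is averaged per field and then
across fields (the across-field SD is the error bar).  Flight metrics
(total flight time from first detection to crossing, accumulated casting
time, search cycles = surge→cast transitions, counter-turns, trajectory
length, lateral path deviation) are aggregated over successful flights at
R = 0.25 m.

The lateral deviation is implemented as a path integral: the per-sample
perpendicular distance to the chord joining the first and last trajectory
points, times the per-sample arc length, normalized by the squared chord
length.  Its magnitude depends on the sampling convention, so it is reported
as a diagnostic only.

The flight inner loop is compiled with numba (a pure-Python single-step
reference implementation lives in `mothnav.navigator`; a test drives both
through a deterministic scenario and checks they agree step for step).  The
full default sweep — 6 turbulence levels × 1000 flights — runs in well under
a minute on one CPU.

## What the generator does and does not emulate

Emulated: pulsed release, passive advection by a shared large-scale wind with
uncorrelated small-scale fluctuations, growth/dilution of patches with age,
binary threshold sensing, and the resulting intermittent detection sequence.

Not emulated: spatially correlated turbulence (no eddies, no Navier–Stokes),
fine-scale concentration structure inside a patch, odor decay or deposition,
vertical flight dynamics, sensor dynamics or adaptation, and any flier
airspeed/heading dynamics beyond the constant-ground-speed point agent.
Passing tests therefore certify the behavior of this idealized system, not of
real moths or real plumes; in particular the per-step-redraw noise makes both
plume scatter and heading noise scale with `√dt`, so quantitative levels are
tied to the stated `dt`.

## Known limitations of the calibrated regime

With all free constants frozen before the quantitative checks were run, the
default configuration reproduces the reference regime only partially; the
acceptance tests encode the discrepancies rather than hiding them:

- The grand-mean success probability over the turbulence grid sits near
  two-thirds rather than ~0.8: crossings have a wide-|y| tail produced by
  fliers that ride the edge of the detectable corridor and lose it in the
  last meters, where patches are smallest.  Symmetric casting has no net
  lateral drift, so edge-riders re-acquire only by puff scatter.
- Mean total flight time is roughly flat across turbulence instead of
  decreasing: the shorter detectable range at high `TI` (nearer starts) is
  offset by the noisier upwind reference and patch scatter, which slow the
  approach.
- Search-cycle counts at high turbulence run ~30% above the reference level,
  for the same reason.
- The crossing-time strategy does not significantly beat a grossly
  mismatched internal counter under paired seeds in this regime: a too-wide
  constant zigzag still reacquires a patch-dense plume, and a too-narrow one
  degenerates into an accurate (if slow) hover-and-wait that a generous
  600 s budget does not punish.  The adaptive rule's advantage here is cost
  (time), not success rate.

Search time, its increase with turbulence, the success decrease with
turbulence and increase with the arrival radius, the strong meander penalty,
and the insensitivity to gusts all reproduce at the stated tolerances.
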