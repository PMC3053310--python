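# Methods

## The movement and interaction model

`N` animals occupy integer sites of a periodic lattice (ring in 1D,
torus in 2D) and move in discrete time.  Each step:

1. Animals are updated once each, in a fresh uniformly random order
   (randomized sequential updating).  Sequential updating avoids
   having to resolve two animals choosing the same site in the same
   instant; the update order is drawn from the same seeded generator
   as the moves, so a `(config, seed)` pair fixes the trajectory
   bit-for-bit.
2. An animal standing on a site carrying *active foreign scent*
   retreats: its admissible moves are the von-Neumann neighbours (2 in
   1D, 4 in 2D) free of active foreign scent.  Otherwise all
   neighbours are admissible.  A mark deposited by animal `j` at time
   `t0` is active at time `t` iff `t − t0 < tas` (strict inequality:
   a mark of age exactly `tas` has just expired).  `tas = 0` disables
   avoidance; `tas = inf` makes marks permanent.
3. The chosen destination (uniform among admissible moves in the
   `plain` variant) is stamped with the mover's scent at the new time.
   An animal with no admissible move stays put and re-stamps its own
   site.  Two animals may transiently occupy the same site: exclusion
   acts through scent, not through bodies.

A counter `n` per animal records steps since it last stood on foreign
scent; it resets to 0 on the encounter step.  The
`correlated_retreat` variant adds short-lived directional persistence
after a retreat: on the retreat step itself the direction is uniform
among admissible moves, and on subsequent steps the previous heading
is preferred with probability `q0·2^−(n−1)` (1D) or through a
discrete two-sided exponential turning kernel of concentration
`lam0·2^−(n−1)` over turn angles {0°, ±90°, 180°} (2D).  The halving
decay and the defaults `q0 = 0.5`, `lam0 = 2.0` are package choices —
no external source fixes them — and both are exposed in the config.

*Snooping* models deliberate border patrol: with `snoop_p > 0`, an
animal arriving at one of its territory-boundary sites refreshes the
time-stamps of a contiguous fraction `snoop_p` of the boundary loop
(`ceil(snoop_p·B)` of `B` sites, starting at the arrival site, in a
random direction; 2D boundary sites are ordered by polar angle about
the territory centroid).  Snooping runs only through the pure-Python
stepper; the compiled kernel covers the plain and correlated variants.

Initial conditions: animals on a regular sublattice (`placement:
grid`; two animals on a ring start diametrically opposed) or on
uniformly random distinct sites (`random`), each stamping its start
site at `t = 0` with no other scent present.

## Engines and determinism

The inner loop is compiled with numba.  Both the compiled kernel and
the reference Python stepper consume exactly three uniforms per animal
and step (order rank, move choice, persistence decision) from the same
`numpy` generator stream, so the two engines produce identical
trajectories — the test suite asserts bit-equality on 1D/2D, plain and
correlated runs.  Replicate `r` of an ensemble uses `seed + r`.

## Observables

A **territory** at time `t` is the set of sites where an animal's own
scent is active; its **boundary** are member sites with at least one
von-Neumann neighbour outside.  The centroid uses per-axis circular
means (the standard unambiguous choice on a torus); the radius `ρ` is
the mean minimal-image distance from centroid to boundary.

In the two-animal 1D system the two scent arcs meet at two interfaces,
each an unscented gap or doubly-scented overlap; the **boundary
coordinate** is the circular midpoint of that interval (the site-
valued variant rounds halves down).  The two interfaces are labelled
by which animal owns their counter-clockwise flank, so per-boundary
time series need no matching step.  Snapshots whose interface
structure is not the clean two-interface one (early transient, expired
scent) are excluded from ensemble averages and counted, never imputed.

**MSDs** use unwrapped (minimal-image accumulated) displacements, so
values may exceed `(L/2)²`.  Animal MSD averages squared displacement
from each replicate's baseline over replicates and animals.  Boundary
MSD in 1D averages the two labelled interfaces; in 2D it is the
centroid MSD plus the variance of the directional radius measured
along a fixed reference direction (north-east by default, other
directions behind a flag).  Both accept a baseline time `t0`; measured
from a baseline *after* the formation transient (we use `32·L²` steps)
the series isolates the settled, asymptotic-regime boundary motion.

Power-law fits `MSD = K·t^α` are least squares in log-log space; a
constrained mode fixes `α` (1/2 for the 1D boundary law) and estimates
`K` as the geometric-mean residual.  Fits require ≥ 5 positive points.

## First-passage theory

With `tas → 0` two walkers interact only on meeting.  Both move every
step, so their separation changes by ±2 sites w.p. 1/4 each or stays
put w.p. 1/2; on the ring this two-site-step walk relabels to a *lazy
unit-step walk on an L-node cycle*.  Meeting states carry walker 1's
arrival direction: the entry copy ("walker 1 just moved left")
deterministically re-separates (reflection), the exit copy ("walker 1
just moved right") absorbs.  `L` must be even (≥ 4): on odd rings the
±2 steps alias the whole lattice and the scaling changes by a factor
4 — a parity artefact with no biological meaning.  Solving
`(I − Q)τ = 1` gives the MFPT exactly; the recurrence solves in closed
form to `2M² − M` with `M = L/2`, which the tests use as an
independent oracle.  Hence

    T_R = 2·MFPT = L² − L,     T_R/(L/N)² = 4·(1 − 1/L) → 4,

with the coefficient normalized by the squared per-animal span
`ℓ = L/N` (`N = 2`); the ladder L = 16…128 extrapolates linearly in
`1/L` to exactly 4.  With `tas = inf` territories freeze where the
scents first meet; each resident then traverses its `s`-site segment
in `s²` steps (reflecting→absorbing edge), so per replicate
`T_R = (2s₁² + 2s₂²)/2`.  Frozen sizes are measured from the interface
midpoints (overlap split at its midpoint) after every site is scented;
from uniformly random starts the sizes concentrate near `L/2` with
~9% fluctuation, giving a coefficient `2 + 8·Var(s₁/L) ≈ 2.07–2.1` —
the fluctuation excess above the even-split value 2.

## Calibration constants

Three constants are measured by simulation and stored with provenance;
each has a regeneration function.

* **MCP↔MSD constant** `c_A = 3.28`: the 90% MCP width of the
  stationary animal distribution in units of `sqrt(animal MSD)`
  (`calibrate_mcp_constant`; L=64, `tas = 0.25·T_R`, 400 replicates,
  batch spread 7%).  It lies between the uniform-distribution value
  3.12 and the Gaussian 3.29, as expected for a flat-topped
  distribution with exponential tails.  The crossing-time adjustment
  `(4·1.645/c_A)² ≈ 4.0` rescales the boundary-point MSD so the curves
  cross where summed overlap equals home-range size.
* **Universal curve**: for each `(Z, L)` on the grid
  `Z ∈ {0.2, 0.28, 0.4, 0.57, 0.8}`, `L ∈ {32, 48}`, a two-animal
  ensemble (default 300 replicates) is run for `32·L²` burn-in plus
  `2·L²` observation steps; `K` is fitted with `α = 1/2` over the
  elapsed window `[L²/8, 2·L²]`.  The collapsed amplitude `K/ℓ`
  agrees across box sizes within ~12% rms over this range (`K/ℓ^0.5`
  and `K/ℓ^1.5` do not collapse).  It decays roughly exponentially in
  `Z`, which bounds the invertible range: below `Z ≈ 0.15` the
  overlap saturates at the home-range size (territories effectively
  unresolvable), above `Z ≈ 1` the boundary displacement falls below
  one lattice site at desk-scale replicate counts.  Queries outside
  the calibrated hull are refused, never extrapolated.
* **Window-spread factor** `6.3`: the overlap of *one* realization's
  MCP intervals over a finite window underestimates the ensemble
  boundary MSD (time-average spread plus the 10% MCP trim); the
  estimator multiplies `σ_b²` by this simulation-calibrated ratio
  (`calibrate_window_factor`).  Because the curve is steep in `Z`,
  residual bias in this factor moves the inferred `T_AS` far less than
  the factor-two acceptance band.

## The inference chain

1D chain (`infer_tas_1d`), per neighbour pair: project fixes onto the
line through the two home-range centroids (`project_fixes_1d`); convert
metres to sites via the resolution `a` and seconds to steps via
`Δt = a²/(2·dims·D)` with `D` estimated from the first 25 minutes of
movement excursions (an excursion starts at the first fix displaced
more than `a` from its predecessor; the rule is a config knob).
Overlap `O` and home-range width `H` are measured on consecutive
sub-windows of halving length and the longest *unsaturated* window
(`0 < O < 0.8·H`) is used — the single fixed `T_obs` of the classic
recipe is the special case where the full record qualifies.  Then
`σ_b = O/(2·1.645)`, `K = 6.3·σ_b²/√τ`, `Z` from the universal curve
at `K/ℓ` (with `ℓ` the per-animal span implied by the population
density), `T_AS = Z·(L² − L)` and steps→days via `Δt` and the active
hours per day (8 by default, the fox convention).  `O = 0` everywhere
returns a *lower-bound* flag at the hull's upper edge; saturation
everywhere returns a *saturated* flag at the lower edge.

2D mode (`infer_tas_2d`) skips the universal curve: it simulates a
`tas` ladder at the matched density, measures the settled boundary MSD
at the observation window, and monotonically inverts the empirical
relation at the observed value (the 90% bivariate containment radius
2.146 converts a 2D overlap extent into `σ_b`).

End-to-end validation (in the test suite): synthetic two-animal
telemetry at known `tas` over `Z_true ∈ {0.22, 0.35, 0.5, 0.75}`,
20 datasets per level, recovers `T_AS` with median relative error
0.18–0.37 — within a factor of two throughout the calibrated range.

## What the synthetic telemetry does and does not emulate

`generate_synthetic_fixes` reproduces the field protocol: fixes every
5 minutes during contiguous 8-hour nightly activity blocks, 5–11
nights per animal (optionally randomized per animal), several
neighbouring residents, isotropic Gaussian position jitter, with the
true `tas` carried in a metadata sidecar.  It does *not* emulate
heterogeneous habitat, attraction to dens, variable activity schedules,
missed fixes, or non-Gaussian GPS error — passing recovery tests
therefore demonstrates the estimator's self-consistency under the
model's own assumptions, not robustness to those field realities.

## Numerical choices and problem sizes

* Scent ages are float64; "never visited" is `−inf`, so `tas = inf`
  and `tas = 0` fall out of the same strict inequality.
* Ensembles in the tests use boxes of 32–128 sites, 10²–10³
  replicates and up to `2¹⁸` steps per run — sizes at which every
  measured exponent and coefficient above is stable at the tolerances
  the tests assert; the calibration defaults are the study conditions,
  not tuning knobs.
* Degenerate inputs fail loudly: empty territories are flagged, MCPs
  require enough fixes after peeling, curve queries outside the hull
  raise, recording plans that would exceed ~2 GB are refused.
* `extrapolate_coefficient` fits `c(L) = c_∞ + b/L`, exact for the
  master-equation ladder (`c(L) = 4 − 4/L`).

## Known limitations

* The correlated-retreat parameterization is a plausible family, not a
  field-fixed law; conclusions drawn from that variant depend on
  `q0`/`lam0`.
* The universal curve is calibrated (and hence invertible) only for
  `Z ∈ [0.2, 0.8]`; the estimator reports bounds outside it.  Weakly
  territorial systems (`Z ≲ 0.15`) are intrinsically unresolvable by
  the overlap method at realistic observation windows.
* The 2D boundary MSD uses a single reference direction for the radius
  term; strongly anisotropic territories would need the multi-direction
  flag.
* Snooping has no compiled path and is therefore slow for large
  lattices; its effect on the inferred `T_AS` is exposed as a
  sensitivity knob without a packaged empirical anchor.
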