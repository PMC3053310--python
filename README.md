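# scentmark

Scent-mediated territorial emergence in animals: a stochastic lattice
model, its first-passage theory, and an inference chain that recovers
the *active scent time* from radio-telemetry fixes.

## The science

Many territorial mammals (the urban red fox is the prototype here) are
*hinterland markers*: they deposit scent throughout their range and
retreat when they hit a neighbour's fresh mark.  A mark only works for
a finite **active scent time** `T_AS`; afterwards intruders ignore it.
Territory maintenance is therefore a race between two clocks:

* the **boundary return time** `T_R` — how long the resident takes to
  revisit its borders and refresh them, and
* `T_AS` — how long the old marks keep working in its absence.

Their ratio `Z = T_AS / T_R` controls everything.  The model is an
agent-based exclusion process: `N` random walkers on a periodic lattice
stamp every site they visit; a walker standing on a site with *active
foreign* scent may only move to neighbours free of it.  Emergent
territories (the sites carrying an animal's own active scent) behave
like deformable elastic objects: the animals diffuse (`MSD ∝ t`) while
the territory *boundaries* creep subdiffusively (`MSD_b = K t^α`,
`α ≈ 1/2` in 1D), with `K` a decreasing function of `Z`.

Three quantitative pillars, all implemented and tested here:

1. **Exact first-passage theory.**  For two walkers with vanishing
   `T_AS` the relative separation obeys a master equation on the ring
   (a lazy unit-step cycle walk with meeting/reflection bookkeeping).
   Solving `(I − Q)τ = 1` gives the meeting-to-meeting mean
   first-passage time exactly; `T_R = 2·MFPT = L² − L`, so the
   coefficient `T_R/(L/N)² → 4`.  In the opposite, permanent-scent
   limit territories freeze where the scents first meet and the
   segment law (`MFPT = s²` across `s` sites) averaged over the frozen
   size distribution gives a coefficient just above 2.
2. **Home-range statistics.**  Field data see home ranges, not
   territories: A% minimum convex polygons (MCP), their overlap `O`,
   and the Gaussian containment factors (half-width `1.645` in 1D,
   radius `2.146` in 2D at 90%) that convert between MCP extents and
   mean square displacements.  The crossing time `t_c` — when summed
   overlaps reach the home-range size — marks the end of detectable
   exclusivity.
3. **Inference.**  From the observed overlap of two neighbours,
   `σ_b = O/(2·1.645)` estimates the boundary spread, hence the
   amplitude `K`; the simulation-calibrated *universal curve*
   `K/(L/N)` vs `Z` is inverted to get `Z`, and `T_AS = Z·T_R`
   converts to days through the lattice spacing `a`, the time-step
   `Δt = a²/(2·dims·D)` (with `D` the early-excursion diffusion
   constant) and the 8-active-hours-per-day convention.

## Worked example

```python
import numpy as np
from scentmark import (SimConfig, run_ensemble, animal_msd, boundary_msd,
                       fit_power_law)
from scentmark.fpt import boundary_return_time_limit
from scentmark.sim import log_times

est = boundary_return_time_limit(64, "small_tas")
print(f"T_R(L=64) = {est.T_R:.0f} steps; T_R/(L/2)^2 = {est.coefficient:.4f}")

cfg = SimConfig(dims=1, L=64, N=2, tas=512.0, T_max=2**19, seed=1)
snaps = log_times(cfg.T_max, n=30, t_min=256)
arch = run_ensemble(cfg, 200, rec_stride=8, snap_times=snaps)
K_b, a_b = fit_power_law(boundary_msd(arch), window=(2e4, 2e5))
K_a, a_a = fit_power_law(animal_msd(arch), window=(8, 48))
print(f"animal exponent (early) = {a_a:.2f}; "
      f"boundary exponent (asymptotic) = {a_b:.2f}")
```

prints

```
T_R(L=64) = 4032 steps; T_R/(L/2)^2 = 3.9375
animal exponent (early) = 0.91; boundary exponent (asymptotic) = 0.41
```

i.e. the exact return-time coefficient is already within 2% of its
large-box limit 4 at `L = 64`, and the same simulation shows the
two-time-scale structure: near-diffusive animals (`α ≈ 0.9`) inside
slowly creeping territories (`α ≈ 0.4`, consistent with the `√t` law
at this box size and window).

A command-line surface wraps the library for shell use:

```bash
scentmark synth --tas 500 --seed 1 --out fixes.csv      # synthetic telemetry
scentmark fpt --L 64 --regime small_tas                 # return-time theory
scentmark calibrate --out curve.json --replicates 300   # universal curve (slow)
scentmark infer-tas --fixes fixes.csv --density 0.0341 \
    --resolution 25 --dt 19 --curve curve.json          # T_AS from fixes
```

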