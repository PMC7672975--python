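# capsim

**Antibody transport simulation in encapsulated 3-D tumor-microenvironment
models.**

Alginate capsules co-culturing cancer-cell spheroids and fibroblasts are a
standard 3-D in-vitro platform for studying how therapeutic antibodies
penetrate the tumor microenvironment (TME). Light-sheet fluorescence
microscopy can record where a fluorescent antibody goes over a few hours —
but interpreting those movies needs a transport model. `capsim` is that
model: a 2-D in-silico capsule cross-section in which antibody diffusion,
cellular binding-site saturation and extracellular-matrix barriers can be
composed, simulated and calibrated against measured fluorescence profiles.

It is aimed at researchers running encapsulated TME cultures (or any
spheroid-on-a-chip variant) who want to ask *what-if* questions —
where do collagen fibers block antibody delivery, how fast does a buried
cluster see drug, which saturation kinetics explain an observed uptake
curve — without new wet-lab rounds.

## The model

**Transport.** Antibody concentration `C(x, y, t)` obeys Fick's second law,
`∂C/∂t = ∇·(D ∇C)`, on a square mesh of 200 × 200 nodes spanning 1000 µm
(node spacing 5 µm). The capsule is a 350 µm-radius disc; everything outside
it is a Dirichlet bath held at the injection concentration
`C_inj = 13 µg/mL` (the medium volume dwarfs the capsule, so depletion is
negligible). The solver is an explicit flux-conservative 5-point stencil
with per-face interface diffusivities (harmonic mean by default), run at the
CFL-stable timestep `Δt ≤ Δx²/(4 D_max)`.

**Heterogeneous diffusivity.** Medium nodes carry
`D_medium = 0.15 µm²/s`; cells carry `D_cell = D_medium/100 = 0.0015 µm²/s`;
collagen fibers are total barriers (`D = 0`). Inside a cancer spheroid of
radius `r_sph`, diffusivity is graded linearly with distance `d` from the
center: `D(d) = D_cell · d / r_sph`.

**Binding-site saturation.** As antibody accumulates at a cell node its
surface binding sites fill up, modeled as a multiplicative decay of the
local cellular diffusivity

    D ← D · exp( −(Δt/Δt_ref) · a · C_norm^n / (1 − C_norm)^p ),
    C_norm = C / (0.01 · C_inj),

with adjustable parameters `(a, n, p)` and saturating concentration 1% of
`C_inj`. The `Δt/Δt_ref` factor (Δt_ref = 120 s, the acquisition cadence)
makes the cumulative decay timestep-independent.

**Profiles and fitting.** Mean-concentration traces over circular ROIs are
the computational analogue of cluster fluorescence profiles. They can be
summarized by delay time (first crossing of 5% of the maximum) and log-phase
slope (OLS slope between 15% and 85% of the maximum), or fitted with the
Richards sigmoid family

    P(t) = M / [1 + α·exp(−Mβt)]^γ .

**Calibration.** `SaturationCalibration` fits `(a, n, p)` to an observed
trace by minimizing the RMSE between min-max-normalized predicted and
observed profiles with BFGS in log-parameter space, one full forward
simulation per objective evaluation (memoized).

## Worked example

```python
import capsim as cs

grid = cs.GridSpec()                      # 200x200 nodes, 1000 um, R = 350 um
placement = cs.PlacementConfig(seed=1, n_fibers=25)
transport = cs.TransportConfig()
domain = cs.place_elements(cs.build_domain(grid), placement)
domain = cs.init_diffusivity(domain, transport)

result = cs.run_simulation(domain, cs.SimulationConfig(),
                           cs.SaturationParams(a=1, n=1, p=1), transport)
center, radius = domain.spheroids[0]
roi = cs.ROISpec("spheroid", center, radius)
profile = cs.extract_profile(result, roi)

print(f"depth {cs.distance_to_periphery(domain, center):.1f} um")
print(f"delay time: {cs.delay_time(profile):.1f} min")
fit = cs.select_best(cs.normalize_profile(profile))
print(fit.summary())
```

prints

```
depth 135.4 um
delay time: 46.8 min
Growth-curve fit (richards), n = 91
  M (asymptote)     : 0.970242
  beta (growth)     : 0.0408196
  gamma (asymmetry) : 3.72246
  alpha             : 5.39616
  P0 @ t0=0  : 0.000970242
  R^2               : 0.995449
```

The seeded capsule put its cancer spheroid 135 µm below the capsule surface;
antibody needs ~47 min to exceed 5% of the final cluster signal, and the
normalized uptake curve is well described by an asymmetric Richards sigmoid
(R² ≈ 0.995). Calibrating the saturation parameters against a measured
trace is one more call:

```python
res = cs.fit_saturation(domain, roi, observed_profile, init=(1, 1, 1))
print(res.summary())       # fitted a, n, p with normalized-profile RMSE
```

A command-line workbench wraps the same library for shell use:
`capsim build-capsule | digitize | simulate | fit-profiles | calibrate |
make-fixture`, all driven by a YAML config (see `examples/run.yaml`).

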