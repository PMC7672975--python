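# Methods

This note documents the model, its numerical treatment, the synthetic-data
conditions the test suite runs under, and the design choices that were
genuinely open.

## Transport model

Antibody motion inside the capsule is purely diffusive: convection is
negligible in a static bath, and over the 3 h horizon we assume no antibody
degradation, no cell growth, death or movement, and no matrix remodeling —
the label field is frozen for the whole run. The governing equation is
Fick's second law with spatially varying diffusivity. Because the printed
form `∂C/∂t = D ∇²C` is only valid for constant `D`, the solver discretizes
the conservative form `∂C/∂t = ∇·(D ∇C)` with per-face interface
diffusivities:

* **harmonic mean** (default): `D_face = 2 D_i D_j / (D_i + D_j)`, defined
  as 0 when either side is 0. This is the physically consistent choice for
  serial resistances and makes zero-diffusivity fibers *exact* barriers — a
  closed fiber loop holds machine-zero concentration indefinitely;
* **arithmetic mean**: available for comparison; it leaks flux through
  zero-D faces and is not used by default.

The exterior of the capsule disc is a Dirichlet bath at
`C_inj = 13 µg/mL`, re-pinned after every step. Because every node outside
the disc is pinned, the mesh-edge condition is irrelevant. Note a
discretization consequence used by the verification tests: the bath value
lives at exterior *node centers*, so the effective Dirichlet radius of the
scheme is `R + Δx/2`, half a spacing beyond the last interior ring. A
radially symmetric reference solution must impose its boundary there, not
at `R`, or the comparison measures geometry offset instead of solver error.

**Stability.** Explicit 5-point diffusion requires
`Δt ≤ Δx²/(4 D_max)`; with the defaults (Δx = 5 µm, D_max = 0.15 µm²/s)
the bound is 41.7 s. The automatic timestep applies a safety factor of 0.5
and is then rounded down so an integer number of steps fits in each 2-min
frame interval (Δt = 20 s, 6 steps/frame, 540 steps per 3 h run). A
user-supplied Δt above the bound is rejected unless explicitly overridden;
NaNs or negative concentrations raise an instability error naming the
timestep.

## Saturation law

Cellular binding sites fill up as antibody arrives; rather than mechanistic
k_on/k_off kinetics (deliberately out of scope), occupancy is folded into a
multiplicative decay of cell-node diffusivity per step:

    D ← D · exp( −(Δt/Δt_ref) · a · C_norm^n / (1 − C_norm)^p ),
    C_norm = clamp( C / (0.01 · C_inj), 0, 1 − ε ),  ε = 1e−6.

Parameters, all dimensionless: `a` scales the decay rate, `n` the
sensitivity at low occupancy, `p` the blow-up approaching full saturation;
defaults (1, 1, 1). The saturating concentration is 1% of the injection
concentration. Two numerical choices:

* **Timestep scaling.** Written as a bare per-step multiplier the cumulative
  decay would depend on the step count; the exponent therefore carries
  `Δt/Δt_ref` with `Δt_ref = 120 s` (the 2-min observation cadence), making
  results converge under timestep refinement — halving Δt changes the final
  frame by ~1.6e−4 relative L2 — and reproducing a per-frame application
  when Δt = Δt_ref.
* **Clamping.** `C_norm` is capped at `1 − 1e−6` to regularize the singular
  denominator; at or above the saturating concentration the multiplier
  underflows toward zero, i.e. full saturation.

The law applies to every cancer and fibroblast node each step (after the
diffusion sub-step; at the stable Δt the splitting error is far below frame
resolution). Spatial localization of saturation to the exposed cluster
surface is emergent from the concentration field, not imposed by a mask.

**A caveat on monotonicity.** With time-constant coefficients the discrete
scheme obeys a comparison principle: from a zero initial condition with a
fixed boundary source, concentration is non-decreasing at every node (the
suite asserts this exactly). With saturation enabled the coefficients decay
over time and the principle no longer holds as a theorem; small genuine
local decreases (~1e−5 µg/mL) occur where collapsing diffusivity reroutes
flux. Monotonicity checks therefore run on the diffusion-only
configuration.

## Capsule geometry

Nodes are cell-centered: node `(i, j)` sits at `((i+0.5)Δx, (j+0.5)Δx)`;
a node belongs to a disc element iff its center is inside the element
radius, and to the capsule iff its center is within `R` of the capsule
center. The stochastic placer draws elements largest-first (spheroids,
fibroblast clusters, single fibroblasts, fibers) by rejection sampling —
a candidate is accepted only if all its nodes are strictly inside the
capsule and still unoccupied, with 1000 attempts per element before a
placement error. Placement is a pure function of the seed.

Fibroblasts prefer the outer ring (outermost 20% of the capsule radius):
each center is drawn from that annulus with probability `outer_ring_prob`
(default 0.7 — the underlying reports state a preference without a number,
so this is a package choice, exposed in config), otherwise uniformly over
the disc; both draws are area-uniform and confined to centers admitting the
element (`radius ≤ R − r_elem`).

Fibers are straight 30 µm segments at 0/45/90/135°, one node thick: the
center snaps to the nearest node and the segment is rasterized as
`⌈L/Δx⌉` axial or `⌈L/(Δx√2)⌉` diagonal nodes (6 and 5 nodes at the
default spacing).

Spheroid diffusivity grading (`D = D_cell · d/r_sph`) applies to registered
cancer spheroids only; fibroblast clusters keep uniform `D_cell` unless
`grade_clusters=True`.

**Digitization.** A labeled raster (0 background/medium, 2 cancer,
3 fibroblast, 4 fiber; or binary 0/1 with 1 read as fibroblast tissue) at
an integer multiple of the mesh resolution is downsampled by per-node
majority vote (ties break toward the smaller label). Manually specified
spheroids override node labels to cancer and are registered for the radial
grade. Rendering a domain at any integer upscale and digitizing it back is
an exact inverse at 1×, and ≥ 99% label-accurate at 4×.

## Profiles, metrics, growth curves

A cluster profile is the arithmetic mean of `C` over the ROI's member nodes
per frame; area is member count × Δx². "Total achieved signal" is read as
the profile maximum (equal to the final value for monotone profiles).
Delay time interpolates linearly between the bracketing frames of the 5%
crossing; log-phase slope is the OLS slope through points between 15% and
85% of the maximum (≥ 3 points required).

Richards fits fix `t0` to the first sample and
`P0 = max(first value, 1e−3·M)` so the curve is defined when the first
observation is exactly zero (the simulator's initial condition; real
fluorescence data has a background floor instead). Fitting is bounded
least squares — `M ∈ [max/2, 2·max]`, `β` and `γ` positive via log
transform — from an 8-point multi-start grid over growth rate and
asymmetry; unweighted residuals. `β` is weakly identified jointly with `M`
(they enter the exponent as a product); `M`, `γ` and the product `Mβ` are
recovered to < 5% median error under 1% noise. The logistic (γ = 1) and
Gompertz (γ → ∞ limit, reparametrized through `P0`) families are fitted
with the same machinery, and `select_best` returns the highest-R² family.

## Calibration

The objective for candidate `(a, n, p)` runs one full forward simulation,
extracts the target ROI's profile, restricts both series to their shared
frame times, min-max normalizes each, and returns the RMSE
`√(Σ(ŷᵢ−yᵢ)²/n)`. Normalization happens after alignment so both series are
scaled over the same support. Minimization is BFGS over
`(log a, log n, log p)` — positivity without explicit bounds — with
central-difference gradients (relative step 1e−3) on a memoized objective,
so repeated evaluations at one point never rerun the solver. The returned
result keeps the best point ever visited, reports the per-cluster RMSE
table with the single fitted parameter set applied capsule-wide, and flags
non-convergence rather than raising.

A coarse-mesh mode (default 100×100, via the element registry re-rasterized
on the coarser grid) accelerates objective evaluations ~6×, but the coarse
optimum is measurably biased with respect to the full mesh (full-mesh RMSE
~8% from a coarse-fitted optimum vs ~1% from a full-mesh fit in the
recovery benchmark); the final report is always evaluated on the full mesh,
and the package's own benchmark runs the whole optimization there
(~150 simulations, ~90 s).

Weak identifiability is expected and observed: distinct `(a, n, p)` can fit
one cluster equally well, so recovery is asserted on the profile RMSE, not
on the parameter values.

## Synthetic study conditions

No experimental light-sheet series are publicly deposited, so the suite
manufactures its own inputs with known ground truth:

* **Noisy sigmoids**: Richards curves times `(1 + ε)`, ε ~ N(0, σ),
  clipped at zero; σ defaults to 0.02 (0.03 for the fit-quality check) —
  an engineering stand-in for fluorescence fluctuation, sample drift and
  cell movement. The noise is independent per timepoint; real fluorescence
  noise is partially correlated in time, so passing recovery tests bounds
  behavior under idealized noise only.
* **Pseudo-experiments**: a seeded stochastic capsule (defaults: 1 cancer
  spheroid of 50 µm — the reference setup allocates cancer cells to a
  single randomly placed cluster — 30 single fibroblasts, 8 clusters, no
  fibers unless requested), simulated with known `(a, n, p)`, ROI profiles
  perturbed multiplicatively. The hidden truth lives only in the manifest,
  never in the emitted CSV, and every fixture regenerates byte-identically
  from (manifest, seed).
* **Fiber scenario**: a constructed pair of capsules identical except for
  fibers — a peripheral cluster, a cluster at 0.75 R enclosed by a closed
  fiber loop, and a partially shielded cluster behind a single
  perpendicular fiber. Positions scale with the capsule radius; the exact
  capsule center is avoided because the 3 h diffusion penetration depth
  (~100 µm) cannot reach it even without fibers.

Problem sizes in the tests: most units run on a 60×60 mesh (300 µm side)
at the production node spacing; solver-verification and end-to-end checks
run the full 200×200 geometry. These sizes are the package's own choice of
a compact but representative benchmark; the physics is spacing-dependent,
not domain-size-dependent, so the small meshes keep Δx at 5 µm.

## Known limitations

* 2-D cross-section only; transport through adjacent planes is absent,
  which the underlying study flags as a likely source of per-cluster
  parameter inconsistency.
* No mechanistic binding kinetics; the saturation law is phenomenological
  and its parameters are weakly identified per cluster.
* Fibers are 1-node-thick straight segments at four orientations; no
  curvature or thickness.
* The digitizer consumes prepared label masks, not raw micrographs —
  segmentation is upstream of this package.
* Richards `β` alone should not be interpreted quantitatively; report `Mβ`.
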