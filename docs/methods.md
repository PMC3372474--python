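# Methods

`coraltherm` models the thermal microenvironment of a single idealised coral
in a laboratory flow chamber: laminar seawater flow past (and through) a
porous tissue/skeleton body, shortwave heating of the tissue surface, and
conjugate heat transport in the coral and the surrounding water.  This note
records the governing model, the numerical choices, and the judgement calls
made where the physical configuration was ambiguous — together with what the
desk-scale implementation can and cannot reproduce.

## Physical model

**Domain.** A rectangular chamber, 25 cm long x 5 cm wide x 10 cm tall,
with a single coral on the floor: a hemisphere (radius r) for massive
growth forms or a vertical cylinder (radius r, length z) for a branch.
Water enters at the inlet at 26 °C with a uniform speed (0.002 m/s in the
validation scenarios, 0.013 m/s for the high-flow comparison).

**Flow.** Steady, incompressible, laminar Navier–Stokes with a
Darcy–Forchheimer sink in the coral zones:

    div(U) = 0
    div(U U) = -grad(p) + nu laplace(U) - (nu D U + (F/2)|U| U)

where `U` is the superficial velocity.  The viscous resistance follows
Blake–Kozeny, `D = 150 (1-phi)^2 / (phi^3 d^2)`, and the inertial
resistance Burke–Plummer, `F = 3.5 (1-phi) / (phi^3 d)`, with `d` the coral
sample diameter and `phi` the zone porosity.  At millimetre-per-second
chamber speeds the quadratic term is negligible and is disabled by default.
Buoyancy is neglected (density differences across ~0.5 K are tiny), which
decouples the flow from the temperature field.

**Zones.** The skeleton porosity comes from bulk and true density,
`phi = 1 - rho_b / rho_t` with aragonite `rho_t = 2.94 g/cm^3`; species
values are 0.475 (P. lobata), 0.431 (S. pistillata), 0.405 (S. hystrix),
and 0.500 assumed for the unavailable massive corals (C. serailia, Favia
sp.).  The living tissue is a nominally 1 mm shell with percolation
porosity 0.05 (configurable 0.05–0.10): nearly impermeable, so the external
flow sees an effectively no-slip coral surface through the porous drag.

**Heat.** Local thermal equilibrium between pore water and matrix, with
volume-weighted effective properties
`(rho Cp)_eff = phi (rho Cp)_f + (1-phi)(rho Cp)_s`,
`k_eff = phi k_f + (1-phi) k_s` (arithmetic mean; harmonic optional), and
`alpha_eff = k_eff / (rho Cp)_eff`.  Constituents: seawater at 26 °C
(`rho = 996.8, Cp = 4179, k = 0.61, mu = 8.7e-4` SI) and aragonite
(`rho = 2940` from the mineral literature; `Cp = 880`, `k = 2.2` from
standard mineral tables — coral-specific values are tabulated nowhere).
The conservative energy equation

    (rho Cp)_eff dT/dt + div(rho_f Cp_f U T) = div(k_eff grad T) + q

is driven by the irradiance source `q` (below).  The Prandtl number
`Pr = nu/alpha ~ 6` sets the thermal-to-momentum boundary-layer ratio.

**Boundary conditions.**  Inlet: fixed velocity and 26 °C.  Outlet: fixed
reference pressure, zero-normal-gradient velocity, advective outflow for
heat.  Top and sides: slip, adiabatic.  Bottom: fixed 26 °C; the velocity
condition is a fixed 0.001 m/s whose direction is configurable.  The
default is a *tangential* (along-flow) sand-bed drift: the alternative
upward-percolation reading injects cold water over the whole floor with an
advective conductance `rho Cp w ~ 4200 W/(m^2 K)` that caps coral warming
near 0.03 K for every species and flow rate — irreconcilable with the
species- and flow-dependent reference observations — so it is selectable
but not the default.

**Irradiance.**  The source deposits `alpha I sin(theta)` per unit exposed
tissue surface area (`theta` = beam elevation; overhead in all validation
runs), spread over the water-contacting coral cells in proportion to their
exposed face area and normalised to the analytic exposed area (hemisphere
`2 pi r^2`, standing cylinder `2 pi r z + pi r^2`) so the absorbed power is
mesh-independent.  This mirrors a source term that carries only the global
beam angle, with no local-orientation factor: flanks absorb as much per
area as the crest.  A collimated alternative ("projected": `alpha I` per
horizontally projected area into the topmost coral cell of each column) is
available; it deposits 2x (hemisphere) to 5x (branch) less power and
produces a branch/hemisphere warming ratio of ~0.29 versus the reference
model's 0.60, which is why the surface convention is the default.
In-depth (volumetric) absorption is not modelled.

## Lumped heat-balance theory

For a well-mixed coral, absorbed power `alpha I A_p` balances Newton
cooling `h A dT` at steady state, giving `dT_ss = alpha I A_p / (h A)`, and
the dark-light warm-up is exponential with

    tau = (rho Cp)_eff / (h S),   S = A/V.

Areas use the convention A = curved surface + basal disc (hemisphere:
`3 pi r^2`, so `S = 4.5/r`; cylinder: `2 pi r z + 2 pi r^2`, so
`S = 2/r + 2/z`).  The hemisphere values reproduce the reference ratios
exactly (257 per m at d = 35 mm, 180 per m at d = 50 mm).  The reference
prints 1,666 and 3,000 for the two branch geometries, which no standard
cylinder convention reproduces from the stated dimensions (they correspond
to half the stated radii); the standard convention is used and the
discrepancy simply noted.  The convective coefficient, never stated in the
reference, is closed with the Whitaker sphere correlation (hemispheres) or
Churchill–Bernstein (cylinders in cross-flow), both behind one interface.

## Numerics

* Collocated, graded Cartesian grid; uniform fine cells in a window around
  the coral (stair-step zone tagging: a cell is coral iff its centre is
  inside the shape; the outermost coral layer is always tissue), geometric
  stretching (ratio <= 1.2) to the far field.  Meshes are rejected if the
  near-coral spacing exceeds d/8 or twice the tissue thickness.
* SIMPLE pressure-velocity iteration with Rhie–Chow face fluxes and
  SIMPLEC-consistent correction coefficients; under-relaxation 0.95 (U) /
  0.9 (p).  First-order upwind momentum convection.  The
  pressure-correction operator is frozen and factorised once (exact sparse
  LU, refreshed every 60 iterations); momentum systems use BiCGStab with a
  diagonal fast path and a cached-LU preconditioner.  Convergence: global
  mass imbalance below 1e-5 of the inflow (measured: tightening to 5.7e-6
  moves surface warming < 1%); the uniform-flow oracle converges to machine
  zero.
* Energy: implicit matrices with first-order upwind advection plus a van
  Leer TVD deferred correction (default) — at desk-grid cell Peclet numbers
  (~25 at low flow) pure upwind's false diffusion visibly thins the thermal
  boundary layer.  Steady solves iterate the correction to a fixed point on
  a cached LU; transients use implicit Euler (dt = 1 s in the validation
  scenarios) with one correction sweep per step.  Harmonic-mean face
  conductivities across zone boundaries.
* Transients exploit the buoyancy-free decoupling: one steady flow solve,
  then energy stepping with frozen face fluxes and a single factorisation
  (each step is a back-substitution).  The dark phase is analytically
  isothermal and recorded without stepping.  Runs stop at a horizon cap or
  once the surface warming is within 1% of plateau.
* Deterministic end to end: no random number is drawn anywhere in the
  solver; reruns are bit-identical.

**Problem sizes.**  Default meshes: P. lobata / Favia 50k cells
(1.75 mm near-coral), S. pistillata 81k (0.56 mm), C. serailia 50k
(1.73 mm), S. hystrix 103k (0.36 mm) — the branch meshes are pinned by the
eight-cells-across-the-diameter requirement, and the S. pistillata
high-flow case is grid-limited enough that the finest affordable grid is
used (its warming still rises ~13% per refinement notch).  The test suite runs one notch
coarser.  A grid-independence study (`coraltherm grid-study`) documents the
residual discretisation error; between the two finest grids the steady
warming changes by a few per cent, still rising slowly with refinement
(the thermal boundary layer over the crest spans only 1–2 cells).

## Surface-warming statistics and calibration

Two statistics are always computed over the exposed coral surface cells:
the area-weighted mean and the maximum ("point probe") warming.  The
reference warming values were measured with thermocouples or microsensors
at the illuminated spot, so the flow-comparison calibration matches the
*maximum* by default: tissue absorptivity is chosen once per species so the
low-flow (0.002 m/s, 600 W/m^2) solve reproduces the species' reference
low-flow value, clipped to the plausible range [0.13, 0.28] (calibrated:
~0.27 for P. lobata; S. pistillata clips at 0.28), then frozen, making the
high-flow result a genuine prediction.  Calibrating the surface *mean*
would require absorptivities of 0.5–0.6, far outside the plausible range.

## What the desk-scale model does and does not reproduce

Reproduced: the analytic A/V ratios; exact linearity of steady warming in
irradiance (R^2 = 1 to roundoff — the model is linear by construction once
buoyancy is dropped, the physical content of the observed R^2 = 0.99); the
qualitative orderings (branch cooler than hemisphere, high flow cooler than
low flow for every species, hemisphere slower to equilibrate than branch);
mass conservation to solver tolerance; steady energy closure to < 1%;
Poiseuille and transient-conduction oracles to <= 2% / <= 1%; the
hemisphere-sensitive / branch-insensitive response to skeletal bulk
density (steady spreads of -16% vs +0.06% for a +-10% bulk-volume
perturbation).  The *sign* of the hemisphere's response is opposite to the
reference (denser runs warmer here): Blake–Kozeny with the coral sample
diameter as characteristic length gives gravel-scale permeability, so
interior percolation cooling dominates, and densifying the skeleton
throttles it; with a realistic pore-scale length the coral would be
near-impermeable and the conduction route (denser, more conductive,
cooler) would set the reference's sign.

Not reproduced, by a wide margin: the reference transient time constants
(340 s hemisphere, 180 s branch — this model: ~20 s and shorter) and the
hemisphere's near-flow-independent warming (reference model ratio 0.90
between 0.013 and 0.002 m/s; this model ~0.17).  The gap is structural,
not a resolution artefact one can buy back at desk scale: a time constant
of 340 s at the observed plateau implies an effective charged heat
capacity 2–3x the entire coral's and an effective `h ~ 55–80 W/(m^2 K)`,
below even the unbounded-stream sphere correlation at Re = 100, whereas
any resolved forced-convection solution of the equations above cools
several times faster (this solver: effective h inflated further, roughly
2x, by residual false diffusion at the surface kink where the TVD limiter
reverts to upwind).  Physically, slow near-bath warming and
mixed-convection plumes (Richardson number ~ 10 at 0.002 m/s and 0.5 K)
plausibly governed the laboratory transients; both lie outside the stated
forced-convection, fixed-ambient model.  The package reports what the
written equations produce.

## Known limitations

* Stair-step surfaces: geometric surface error up to one local cell width;
  exposed-area normalisation removes the systematic stair-area inflation
  from the absorbed power but not from the local flux distribution.
* The thermal boundary layer over the crest is under-resolved at desk
  grids (1–2 cells); steady warming still rises a few per cent per
  refinement step at the defaults.
* No buoyancy, turbulence, waves, salinity, in-depth light penetration, or
  mass/nutrient transfer; single coral per chamber; isotropic homogeneous
  permeability per zone.
* Tissue and skeleton share the aragonite constituent properties,
  differing only in porosity; living tissue is thermally closer to water,
  so tissue-layer conduction is likely overestimated.
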