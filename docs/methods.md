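# Methods

## The model

`ecsrd` simulates chemical dynamics in the extracellular space (ECS) of
brain tissue at the macroscopic, volume-averaged scale (voxels of order
10 um).  Explicit cell geometry is replaced by two per-voxel tissue fields:

* **free volume fraction** `alpha` — the proportion of tissue volume
  accessible to diffusing species.  Concentrations are expressed relative
  to free volume: the amount in a voxel is `c * alpha * dx*dy*dz`.
* **tortuosity** `lambda` — the mean multiplicative path-length increase
  due to obstacles.  The effective diffusion coefficient is
  `D* = D / lambda^2`, optionally per axis for anisotropic tissue.

Each extracellular species obeys

    alpha * dc/dt = div( g grad c ) + alpha * R(c) + S,
    g = alpha * D / lambda^2,

with `R` the reaction right-hand side (mM/ms) and `S` point sources from
membrane currents.  Units are fixed throughout: um, ms, mM, mV, mA/cm^2;
amounts are reported in mM·um^3 (= 1e-15 mmol).

Typical gray-matter values `alpha = 0.2`, `lambda = 1.6` are the defaults;
both accept scalars, per-voxel arrays, or functions of position sampled at
voxel centers.  (Sampling at centers rather than voxel-averaging the field
is a deliberate choice: tissue-parameter fields are smooth at the 10-um
scale, and center sampling keeps user functions cheap and exact for the
piecewise definitions used in the edema scenario.)

## Diffusion: finite-volume Douglas-Gunn ADI

Diffusion is discretized in flux form on the voxel grid.  The conductance
of the face between two voxels is the **harmonic mean** of the adjacent
`alpha * D*` values — the standard flux-continuous choice for layered
media, which reduces to `alpha*D*` in homogeneous tissue and gives exactly
zero flux into inaccessible (`alpha*D = 0`) regions.  Because every face
flux is computed once and enters its two voxels with opposite signs, total
mass telescopes to round-off under zero-flux boundaries.

Time stepping uses the Douglas-Gunn alternating-direction-implicit scheme
with trapezoidal (theta = 1/2) weights.  With `A_i` the directional
operators and `gamma = dt/2`:

    (I - gamma L1) u*   = c + gamma A1 c + gamma s1 + dt (A2 + A3) c
    (I - gamma L2) u**  = u*  - gamma L2 c
    (I - gamma L3) c'   = u** - gamma L3 c

(`L_i`/`s_i` are the linear/affine parts; `s_i` is nonzero only for
Dirichlet boundaries, implemented as ghost voxels held at the boundary
concentration at the ghost-cell center).  Each sub-step solves independent
tridiagonal systems along grid lines by the Thomas algorithm with
precomputed factorizations, so a step costs O(N) in the voxel count.  The
scheme is unconditionally stable and second-order in space and time.
Applying the alpha-weighted sum to the three sub-step identities shows the
scheme inherits exact mass conservation from the operators themselves; the
measured drift is at the 1e-15 level over thousands of steps.

Two numerical caveats are documented rather than hidden:

* On **discontinuous** initial data with very large time steps (tens of
  times the explicit limit), the trapezoidal weights produce a bounded,
  decaying transient (under ~10% of the jump) rather than a monotone
  profile — the usual Crank-Nicolson behavior.  Solutions remain bounded
  and relax to the conserved mean.
* The spatial error of the 7-point stencil on the sharp cube-in-box
  verification problem peaks at ~1.9% of the local value at `dx = 1 um`
  (transiently, while the central voxel decays fastest) and falls
  second-order under refinement; see "Verification" below.

## Reactions

Reactions are declared as stoichiometry plus symbolic rate expressions
over species names; expressions are parsed with sympy and compiled to
vectorized numpy callables evaluated over all voxels at once.  With
mass-action kinetics the net rate of `K + A <-> AK` is
`kf*[K][A] - kb*[AK]`; rate "constants" may themselves be expressions of
the concentrations, as in the astrocyte buffer below.  Each reaction's
rate is computed once and added with opposite signs to both sides, so
linear invariants (e.g. `[K] + [AK]`) cancel exactly in floating point.

Reaction integration is operator-split from diffusion (Lie splitting:
sources, then reactions, then diffusion; Strang splitting is available as
a flag).  The per-voxel update is a linearized backward Euler step,

    (I - dt J) dc = dt R(c),    c <- c + dc,

with `J` the **numerically approximated Jacobian** (forward differences,
step `max(1e-8, 1e-6 |c_j|)`); the batched small systems are solved in
closed form for up to three participating species.  The update is exact
for linear kinetics, unconditionally stable for the stiff uptake rates
used here, and preserves linear conservation sums to round-off because the
difference columns of `J` inherit the exact sign cancellation of the
right-hand side.  A singular matrix triggers internal halving of dt (at
most 20 times).  Transient negative concentrations inside a solve are
tolerated and clamped only at output; a persistent excursion below
-1e-9 mM logs a diagnostic.

## The astrocyte buffer

Excess extracellular K+ is cleared phenomenologically by immobile glial
binding sites:

    K + A <-> AK,   kf = kb / (1 + exp(-([K] - 15)/1.15)),   kb = 8e-4 /ms,

with total capacity `Amax = [A](0)` in mM.  The sigmoidal forward rate
switches uptake on above ~15 mM.  The printed formula is implemented
exactly as given (its units are nominally 1/ms although it multiplies
[K][A] in the mass-action law; the original source does not reconcile
this, and we follow the printed form).

## Neuron-field coupling

Embedded cells are two-compartment (soma, dendrite) Hodgkin-Huxley
neurons: fast sodium `naf` (m^3 h), delayed-rectifier `kdr` (n^4),
instantaneous persistent sodium `nap`, a potassium leak and a non-specific
leak; Traub-style rate functions at body temperature.  The Na/K-ATPase is
deliberately omitted; clearance is the field buffer's job.  Reversal
potentials are recomputed each membrane sub-step from the local field via
the Nernst equation (fixed intracellular 125 mM K+, 15 mM Na+), and the
net K+/Na+ membrane currents are converted to molar fluxes
(`I·area / F`) deposited into the cell's voxel:
`d(conc) = flux * dt / (alpha * voxel volume)`.

Membranes sub-step at 0.05 ms (exponential-Euler updates for gates and
voltage) inside each 1-ms field step, with reversal potentials frozen over
the field step; fluxes accumulate and deposit once per field step.  An
optional numba kernel accelerates the sub-stepping; the vectorized numpy
path is the reference implementation and the two agree to ~1e-9.

The cited conductance set for this cell is not published, so the package
ships a named default (`traub2c`) chosen by calibration, in this order:

1. rest is stable at the 3.5 mM K+ baseline (settles near -74 mV, no
   drift over 1 s);
2. sustained depolarization sets in for extracellular K+ around
   12-20 mM, the range that lets elevated K+ recruit neighbors;
3. with 1 and 2 fixed, the delayed-rectifier density was set so the
   desk-scale slab scenario (below) propagates near the published
   1.69 mm/min.

The calibrated values are `gnaf 30, gkdr 30, gnap 0.15 (half-activation
-52.5 mV), gkleak 0.06, gleak 0.3 mS/cm^2`, soma/dendrite areas
1000/2000 um^2.  All are plain dataclass fields and swappable per run.
Wave speeds depend on this set; the package reports them as its own
calibrated reproduction, not as parameter-free predictions.

By default cells are "open books": intracellular concentrations are fixed
boundary-condition-like reservoirs.  Closed-books mode additionally debits
every deposited flux from a per-population intracellular ledger so that
total substance (ECS + bound buffer + cell interiors) is exactly
conserved — this is the configuration the conservation audit uses.

## Spreading depression scenario

The full-scale conditions are 1 mm^3 of ECS (`dx = 10 um`, alpha 0.2,
lambda 1.6), 90,000 cells/mm^3 placed uniformly at random from a recorded
seed, K+ (D = 2.62 um^2/ms) and Na+ (D = 1.78 um^2/ms) fields at
3.5/144 mM baselines, and a 40 mM K+ bolus of radius 100 um.  The wave
front is the maximum distance from the bolus center where [K+] exceeds
15 mM; wave speed is the least-squares slope of front radius vs time over
the first 10 s, in mm/min.

Computations in this repository run the **desk-scale thin slab**:
1000 x 200 x 200 um with the bolus centered on one end face, the same
densities, kinetics and voxel size, zero-flux boundaries, 1-ms field
steps, 10 simulated seconds (a few minutes on one CPU; the problem sizes
here are the package's standard desk-scale choices).  Constant-
concentration boundaries are supported but not used for the slab: with
walls only 100 um from the wave axis they drain the front entirely,
unlike the full cube where the wave stays 500 um from the walls.

Measured desk-scale results (seeded placement, defaults above):

* `Amax = 0`: the front propagates at ~1.6 mm/min (published full-scale
  value: 1.69 mm/min).
* `Amax = 500 mM`: uptake removes the bolus within tens of ms; no front
  ever passes the bolus radius by more than one voxel.
* `Amax = 10 mM`: the wave propagates ~38% slower than `Amax = 0`.  The
  published full-scale reduction is 70%.  On this slab the reduction is
  structurally capped near ~45% for this model family: the buffered wave
  must supply roughly `(K_recruit - 3.5) + Amax` mM per voxel against
  `(K_recruit - 3.5)` unbuffered, and the printed 15 mM uptake threshold
  prevents lowering the recruitment threshold enough to amplify the
  ratio (recruitment below 15 mM makes the buffer miss the
  pre-recruitment zone and *weakens* the effect — measured ~30%).
  Across ~20 calibration runs varying nap half-activation (-56..-48 mV),
  gkdr (15-80 mS/cm^2) and membrane areas (1-3x), no parameter set
  exceeded 41% while keeping the absolute speed in range.
* Cytotoxic edema (alpha ramping 0.07 -> 0.2 and tortuosity 1.8 -> 1.6
  from the core radius 100 um outward over the half-domain): the wave
  runs ~27% faster than uniform tissue at equal Amax — the reduced free
  volume outweighs the tortuosity penalty.

## Verification

Three independent routes check the solver:

1. **Analytic cube-in-box** — a 9-um cube of unit concentration centered
   in a closed 21-um box (c0 = 0 outside; this normalization is ours, the
   geometry is fixed).  The exact solution is the heat kernel integrated
   over the initial data with zero-flux walls satisfied by the method of
   images; the box and cube factorize per axis, so the voxel average is a
   product of three 1D series with closed-form erf antiderivative terms.
   Image pairs are added until a pair contributes less than 1e-14 relative
   (at least 3 pairs); halving the tolerance moves results by < 1e-12.
   The solver's central-voxel trace at dx = 1 um, dt = 0.1 ms tracks the
   series with a peak transient error of ~1.9% (see above), and the error
   falls strictly under refinement with fitted order ~2.0.  For the
   refinement study each run is compared against the exact evolution of
   its *own* voxel-averaged initial data, so grids incommensurate with the
   cube faces (dx = 1.4 um) measure scheme error, not representation
   error.
2. **Brute-force oracle** — a deliberately simple forward-Euler explicit
   solver (flux form, harmonic faces, same boundary semantics, no shared
   code) run below its stability bound.  The two discretizations agree to
   ~1e-2 mM on heterogeneous grids with point sources and converge to
   each other under joint step refinement; the oracle itself is anchored
   to the analytic series at 1%.
3. **Conservation audit** — per-step books of
   `mass - injected - boundary exchange` (plus coupler-held intracellular
   amounts) per species.  Dirichlet boundary exchange is accumulated from
   the sub-step boundary fluxes, making the discrete divergence identity
   hold to ~1e-14; closed runs drift < 1e-14 relative over 10^3-10^4
   steps, including the 50^3 heterogeneous run with 125 closed-books
   neurons and the buffer reaction.

## Reproducibility

All randomness (cell placement) flows from a single integer seed; a fixed
seed reproduces front-radius series bit-for-bit on one machine.  The CLI
logs the fully resolved configuration next to every run's outputs.
`scripts/acceptance.py --seed N --out results/acceptance.json` re-runs the
two slab scenarios from scratch and writes the unbuffered wave speed and
the Amax = 10 percent reduction.

## Known limitations

* The membrane parameter set is a calibrated stand-in for an unpublished
  one; absolute wave speeds inherit that calibration.
* The slab's Neumann walls and quasi-planar front are not the full-scale
  spherical geometry; the buffered-speed *reduction* is the quantity most
  affected (see above), the unbuffered speed the least.
* Synthetic scenarios place point neurons uniformly; real tissue is
  neither homogeneous nor uniformly seeded, and the model omits pumps,
  Ca2+/glutamate/Cl- dynamics, cell swelling feedback, and the silencing
  phase that follows the depolarization wave.
* Electrodiffusion (field-driven ion drift) is not modeled; species carry
  charge labels only for current-to-flux conversion.
* One field step couples neurons explicitly (reversal potentials frozen
  over 1 ms); stiff membrane transients faster than the field step are
  resolved within the sub-stepper but their field feedback is first-order
  in the field dt.
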