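# Methods

## Model and assumptions

The package implements a three-species generalized Lotka–Volterra system
for tumor (`T`), pro-tumor immune (`P`, PTI), and anti-tumor immune
(`A`, ATI) cell densities, all dimensionless and non-negative. Tumor and
ATI cells grow logistically (rates `r_T`, `r_A`; capacities `K_T`,
`K_A`, with self-limitation coefficients written `r_T/K_T`, `r_A/K_A`);
PTI cells have no intrinsic birth term — they arise from tumor contact
(`α_PT T P`) and, centrally, from tumor-catalyzed conversion of ATI
cells at rate `ω A T`, which appears as an influx in the P equation and
an equal outflux in the A equation. Pairwise interactions are
mass-action (`α_XY` = effect of `Y` on the per-capita growth of `X`).
The model is well-mixed and deterministic: no space, no saturating
(Holling-type) functional responses, no stochasticity, and parameters
constant in time. These are modeling choices aimed at mechanism, not
quantitative prediction.

Three binary structural switches generate eight variants from one
implementation of the right-hand side and Jacobian:

* `pti_self_limitation`: `−d_P P²` (quadratic) or `−d_P P` (linear);
* `pti_tumor_growth`: `α_PT T P` present or absent;
* `ati_dynamics`: logistic `r_A A − (r_A/K_A) A²`, or constant
  recruitment with linear death `r_A − (r_A/K_A) A`. In the source
  variant only the birth/self-limitation pair is replaced; the
  interaction and conversion terms keep their multiplicative-in-`A`
  form, and `r_A/K_A` is read as a plain linear decay coefficient
  (no carrying-capacity interpretation is implied there).

The baseline is {quadratic, on, logistic}.

## Parameters

All eleven parameters are non-negative; `r_T, K_T, d_P, r_A, K_A` must
be strictly positive (they appear in denominators of the closed forms).
The shipped fixtures set every rate and capacity to 1 with
`α_TP = 0.95`, `α_PT = 0.15`, `α_AT = 0.05`, `α_AP = 0.5`, and vary
`α_TA` (ATI tumor-killing rate) and `ω` (conversion rate) — the two
parameters whose interplay organizes the dynamics. Interval-valued
entries of a fixture (the swept parameters) are recorded under
`options.ranges` with a documented representative scalar in
`parameters`; config files must spell out all eleven parameters so that
no rate can silently fall back to a default.

## Steady states

Boundary states have closed forms: extinction `(0,0,0)`, tumor-only
`(K_T, 0, 0)`, cancer-free `(0, 0, K_A)`, the tumor-ATI state (which
exists only at `ω = 0`, since `dP/dt = ωAT > 0` otherwise), and the
tumor-PTI state `T = r_T/Γ_{T→T;TP}`, `P = (α_PT/d_P) T`, feasible iff
`Γ_{T→T;TP} = r_T/K_T − α_TP α_PT/d_P > 0`. The coexistence (TPA) state
has a closed form only at `ω = 0`; for `ω > 0` it is computed
numerically: `A` is eliminated with the interior tumor nullcline
(requires `α_TA > 0`; a full 3-D fallback covers `α_TA = 0`), leaving a
polynomial system in `(T, P)` solved by dense multistart root-finding
over a 20×20 hybrid log/linear grid on `(0, 3·max(K_T, 1)]²`, with
duplicate roots merged within `1e-7` (max-norm) and every root verified
against the full vector field to a residual below `1e-10`. Feasibility
uses strict positivity with tolerance `1e-9`.

Two refinement steps make numeric roots agree with closed forms to
`1e-8`:

* **boundary snapping** — residual-based convergence leaves position
  errors up to ~`sqrt(tol)` in directions where the field is
  quadratically flat (the PTI direction at the cancer-free state, where
  the only restoring term is `−d_P P²`), so components below `1e-6` are
  snapped to zero, jointly first (small components can balance each
  other through `ωAT`), accepted only if the residual bound still holds;
* **subspace Newton polish** — the remaining nonzero coordinates are
  polished with Newton steps on the corresponding subsystem, whose
  Jacobian is nonsingular even when the full Jacobian is marginal.

The generic variant-agnostic finder (`find_equilibria`) multistarts the
full 3-D system and additionally sweeps each invariant axis and the
T–P / T–A coordinate planes in their own dimension, where boundary roots
are found far more reliably; the full-system residual check discards
subspace roots that are not equilibria of the full model (e.g. `A = 0`
states under source-recruitment ATI dynamics). Search boxes are scaled
per axis: the tumor scale includes `r_T/Γ_{T→T;TP}` (the TP tumor
density, which grows without bound as the feasibility margin shrinks)
and the PTI scale follows `P ~ (α_PT/d_P) T`.

Interior states of the baseline model also satisfy an exact scalar
quadratic (eliminating `A` and then `P`); the test suite uses that
reduction as an independent oracle against the multistart solver, which
remains the shipped implementation.

## Stability

States are classified by the eigenvalues of the analytic Jacobian:
stable if all real parts are below `−1e-8`, unstable if any exceeds
`+1e-8`. Otherwise the state is marginal and linearization is
inconclusive — the generic case here, not an edge case: the cancer-free
state always has a structurally zero eigenvalue in the PTI direction
(the conversion influx `ωAT` is second order in the perturbation). The
verdict is then settled numerically: 26 perturbations (every nonzero
sign pattern on the three axes, max-norm `1e-3`, clipped to the
non-negative orthant), each integrated forward; the state is
`marginal_numerically_stable` iff every trajectory returns within
`1e-4` (max-norm). Recapture along the flat direction is algebraic,
`P(t) ~ 1/(d_P t)`, so the trials use a long horizon (`1e7` time units
— cheap, as adaptive steps grow geometrically); the capture event fires
at a tenth of the recapture radius to avoid pass-through false
positives.

Integration uses LSODA (stiff-capable, adaptive) with `rtol = 1e-10`,
`atol = 1e-12`, terminal events for convergence (vector-field max-norm
below `1e-10`) and divergence (any density above `1e6 · max(K_T, K_A)`;
the unbounded regime grows without bound, so any large cutoff serves).
The integrator's tolerances and horizons are package choices — nothing
in the model fixes them.

## Bifurcation analysis

`sweep_omega` computes all steady states and verdicts on an ω grid
(default 401 points over the fixture's range), matching branches between
consecutive grid points by nearest neighbor in the full `(T, P, A)`
space with label continuity as tie-break — per-density projections of a
diagram can cross without the branches intersecting. Detection on the
baseline model:

* **transcritical** — the TP state's leading eigenvalue equals the ATI
  reinvasion rate `r_A + (α_AT − ω) T_TP − α_AP P_TP` (the A-row of its
  Jacobian decouples), so a sign change between grid points is refined
  by `brentq` on that rate; the closed form
  `ω_TC = Γ_{T→T;TP} r_A/r_T + α_AT − α_AP α_PT/d_P` is exposed
  separately and the two agree to machine precision.
* **saddle-node** — the feasible coexistence-root count jumps between 0
  and 2 across the fold; bisection on the count refines it to `1e-6` in
  ω. Eigenvalue tests are avoided here because the fold lies on the
  numeric branch. Beyond the pitchfork the fold survives only on a
  branch with `A < 0`; `feasible_only=False` counts those roots too.
* **pitchfork** — defined by the fold meeting the transcritical point.
  Direct bisection on feasible-fold existence degrades near the
  degeneracy (the colliding pair separates like `~1e-3·Δα²` in ω,
  beneath what root counting resolves), so the locator uses the
  equivalent characterization that the TP point becomes a *double* root
  of the reduced interior system at `ω_TC`: `brentq` on the reduced
  Jacobian determinant there, a smooth sign change in `α_TA`. The test
  suite cross-validates against coarse fold-existence bisection.

`phase_diagram` labels an `(α_TA, ω)` grid by its stable-state set
(cancer-free only, coexistence only, cancer-free/coexistence bistable,
cancer-free/TP bistable, or no stable tumor-free state). For grid
throughput the cancer-free state is classified by the sign of
`Ω_{T→A}` — the equivalence with the perturbation-trial verdict is
itself a tested property — and all other states linearly.

## Basins of attraction

`compute_basins` integrates every point of an initial-condition grid to
convergence and matches the terminal state to the nearest known
equilibrium within `1e-4` (stable attractors take precedence; unstable
boundary equilibria are still matched so that invariant sets label
themselves, e.g. the origin). Unmatched or non-convergent points get
explicit `unresolved` / `diverged` labels. The default grid is 15³ over
`[0, 1.2·max(K_T, K_A)]³`; the tests use strictly interior grids,
because the coordinate planes are invariant sets whose limit sets are
boundary states (with no initial ATI density a tumor simply grows to
carrying capacity), and statements about the cancer-free basin concern
the interior. Basin fractions are label counts over the grid;
"cancer" aggregates the TP and TPA outcomes. The optional basin-boundary
estimate fits a support-vector machine with a degree-3 polynomial
kernel to the cancer-free/cancer dichotomy; it is visualization-only and
feeds no quantitative result.

## Problem sizes

The test suite uses the sizes a single-CPU run completes comfortably:
200 random parameter draws (log-uniform on `[0.05, 5]`, TP feasibility
enforced so growth stays bounded) for the stability-theorem and
closed-form/numeric agreement suites, 100 random trajectories for
orthant invariance, a 26-point ω grid per variant for the eight-model
comparison, and an 8³ interior grid at five conversion rates for the
basin-shrinkage check. The acceptance script's sweep cross-check uses 26
ω points around the transcritical value. Larger grids only sharpen
locations already refined by root-finding.

## What the random-draw suites do and do not show

The draw distribution exercises the model across two orders of
magnitude per parameter but enforces the bounded-growth condition, so
the suites validate the steady-state theorems *within* the biologically
sensible regime; they say nothing about measure-zero degeneracies
(exact `Ω_{T→A} = 0`, `ω = ω_TC`), which the bifurcation locators
handle explicitly instead. All draws are mass-action gLV by
construction — agreement of solver routes here does not validate the
model against data, only the implementation against itself and against
independent algebra.

## Known limitations

* `solve_tpa`'s elimination requires `α_TA > 0`; the `α_TA = 0` fallback
  relies on the generic 3-D multistart, which offers no completeness
  guarantee (roots are residual-verified but could in principle be
  missed).
* Stability verdicts for marginal states are numerical evidence, not
  proof; no center-manifold or Lyapunov analysis is attempted.
* Branch matching is nearest-neighbor continuation, not arc-length
  continuation; it assumes the grid resolves branch spacing.
* Basin fractions are grid-point counts, not integrated volumes.
* Near-threshold initial conditions can exhaust the integration horizon
  and label `unresolved`; refining the grid near the boundary is the
  intended workaround.
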