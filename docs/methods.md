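# Methods

## Model

States are the extracellular concentrations plus biomass,
`x = [c_ext; c_bio]` (mmol/L, biomass gDW/L).  Specific fluxes (mmol/gDW/h)
satisfy the pseudo steady-state constraint `S_int v = 0`, hence `v = K u`
with `K` an (n × d) null-space basis and `u` the d free fluxes.  Batch
dynamics are `dx/dt = S_e K u(t) (q_bioᵀ x)`; continuous cultures add
`D(t)(x_in − x)` with a right-continuous piecewise-constant dilution profile
aligned with the measurement grid.  Outputs are linear selections of states
and of fluxes; off-gas rates carry a sign in the selection row so measured
uptake/production values are nonnegative.  Intracellular concentration
dynamics are deliberately out of scope: the pseudo steady-state step replaces
them with the algebraic constraint.

## Flux parameterization

Each free flux is a clamped B-spline of degree k = 2 (continuous first
derivative; other degrees are available in the library but the pipeline fixes
two).  A spline with g internal knots has q = g + k + 1 control points and a
total knot vector with k+1 copies of each horizon end.  Three structural
operations drive the incremental algorithm:

* **knot insertion** (single-knot convex-combination update) refines the knot
  vector *without changing the profile* — the warm-start property the
  algorithm depends on; implemented against `scipy.interpolate` and verified
  to ≤ 1e-12 relative profile change;
* **prolongation** moves the end knot outward keeping the control points
  (the profile changes slightly through basis stretching but remains close);
* **knot windowing** pins an accepted knot to the measurement interval it
  optimized into, as box bounds for all later solves.

Evaluation is right-continuous at interior knots and inclusive at the horizon
end; no extrapolation.

## Discretization

Direct collocation on finite elements: element borders at the measurement
times (n_time − 1 elements), cubic Lagrange state polynomials with 3-point
right-Radau collocation (nodes (4±√6)/10 and 1).  Differential and algebraic
states get 4 coefficients per element per state — the value at the element
start plus the three Radau points.  The collocation block enforces the ODE at
the 3 interior points per element and the algebraic definition
`z = I_irr K u` at those points plus the global initial time (the extra
initial-point constraint is a convention choice; it reproduces the intended
constraint counts).  Continuity equates element end states with the next
element's start coefficient.  Positivity `x ≥ 0, z ≥ 0` is imposed on the
coefficients, not continuously — the standard relaxation.  A dimension
report documents every variable/constraint count and is checked against the
assembled blocks.

## Solving the NLP subproblems

For fixed spline parameters the discretized dynamics are *linear* in the
state coefficients: the right-hand side is a flux vector times the scalar
biomass concentration (plus an affine dilution term), so each element's
collocation equations are one small linear solve and elements chain through
continuity.  The solver exploits this: `p_x` and `p_z` are eliminated exactly
(they satisfy the collocation and continuity blocks to linear-algebra
precision by construction) and the reduced problem over
`(p_u, t_knot, x_0[, K])` — a few dozen variables — is solved with SLSQP
(scipy).  Gradients are finite-difference with a single-point cache so each
sweep costs one state elimination.  Because SLSQP's ftol is absolute, the
objective is normalized by its current magnitude and re-polished (up to 4
rounds) whenever it drops by more than 10×; this keeps the effective
tolerance (default 1e-8) relative across the large dynamic range between
cold starts and near-perfect warm starts.  Subproblems are capped at 300
major iterations; with the warm-start mechanism they typically converge in
far fewer.  Knot windows and the horizon interior are box bounds; knot
ordering within a spline is an inequality block; state/algebraic positivity
is imposed on the eliminated coefficients as inequality constraints.
Finite-difference gradients bound the achievable precision: parameter
recovery on noiseless data is reliable to ~1e-5 (exact-derivative solvers
would reach 1e-6 and below).

In optimal-basis mode the entries of K join the variable set with
`S_int K = 0` and the lower triangle of `KᵀK − I = 0` as equality
constraints (d(d+1)/2 independent rows by symmetry), adding d(d−1)/2 net
degrees of freedom.  Free fluxes under an optimized K are only defined up to
rotation, so comparisons and reported profiles use the full flux space
`v = K u`.

## Incremental estimation

The start horizon is the smallest l with `l·n_out ≥ 3d + m_ext + 3`
(strictly positive AICc denominator for the knotless model; in optimal-basis
mode l additionally covers the d(d−1)/2 basis parameters).  The cold start
sets x₀ from the first measurement row and each spline to a constant at the
median of finite-difference slope estimates mapped through `pinv(S_e K)` and
divided by the interval-midpoint biomass — the median rather than an
interpolating fit, because at small biomass the noise dominates the slopes.
Irreversible free fluxes are clipped nonnegative.

At each horizon: while a knot is insertable under `n_meas ≥ n_p + 4`
(one knot adds two continuous parameters and AICc needs
`n_meas ≥ n_p + 2`), solve d trial subproblems, one knot inserted per free
flux at the midpoint of the latest measurement interval past that spline's
last window (bounded below by that window's upper edge during its first
optimization).  Accept the minimum-AICc trial only if it is *strictly* below
the incumbent (ties never grow the model; equal-AICc trials break toward the
lowest flux index), window the new knot to its measurement interval, and try
again; otherwise stop inserting.  Then append the next measurement time,
prolongate, re-solve the base problem, and repeat.  Windowed knots stay
movable inside their windows in all later solves.  Failed subproblems count
as AICc = +∞; insertion rounds are uncapped.  The per-iteration history
(n_time, n_p, incumbent AICc, best insertion AICc, action) is recorded and
printed by the CLI.  The final fit is accepted if the weighted SSE is below
the 95% χ² quantile at `n_meas − n_p` degrees of freedom.

## Uncertainty

Monte-Carlo bootstrap: each of 1000 replicates redraws every measurement
from Normal(m_ij, σ_ij²) and re-estimates the *continuous* parameters at the
point estimate's frozen structure (knot counts and windows; knots still move
within windows).  Re-running the full knot-selection search per replicate
would multiply cost a thousandfold for little band movement, but freezing the
structure does understate structural uncertainty — a documented deviation
risk.  Bands are the 2.5/97.5 percentiles (linear interpolation between
order statistics) per flux per grid point; failed replicates are dropped and
counted, with a warning above 20%.  Fisher-information intervals are
deliberately not offered: the problem is constrained and strongly nonlinear
in the knots.

## Synthetic experiments

The generator provides the two study conditions the estimator is designed
around, plus arbitrary user protocols.

**Batch (small)** — 7 fluxes, 4 internal metabolites, extracellular
A_ext/E_ext/F_ext + biomass, d = 3.  Free-flux reference kinetics:
`u₁ = c_Aext/(1.5 + c_Aext)`, `u₄ = 0.2 c_Eext/(3 + c_Eext)`,
`u₅ = 1/(1 + c_Fext)`; x(0) = (10, 15, 0, 0.1); 21 equidistant samples of
all 4 states on [0, 20] h → 84 measurements.  Noise: variance 1e-8
(near-noiseless) or the "realistic" model below.  The network itself is a
reconstruction: it satisfies every published structural constraint (counts,
valid free-flux sets {1,4,5} and {3,6,7}, fluxes 3 and 6 the only reversible
ones, kinetic bindings), but its stoichiometric entries are this package's
own, chosen so that `S_e K` has full column rank (all free fluxes observable
from the states) and all states remain nonnegative over the horizon
(verified by simulation).

**Continuous (medium)** — a synthetic 68-flux stand-in network with 62
internal metabolites, 9 extracellular metabolites + biomass, d = 6, 44
irreversible fluxes; exchange reactions 59–68 with free fluxes
{62 glycerol, 63 glucose, 65 ammonia, 66 citrate, 67 acetate, 68 oxygen};
Monod-type kinetics with the stated constants (u₆₂ = 0.0995 constant, etc.);
x(0) = (100, 53.15, 38.45, 62.61, 0, 0, 0, 6.78, 100, 2.14); glucose-only
feed at 20 mmol/L; 31 samples on [0, 10] h of 8 concentrations plus O₂
uptake and CO₂ production → 310 measurements.  Flux 67's rate law
(0.8834/(10 + c_Ac) with c_Ac(0) = 0) is implemented as acetate *excretion*
inhibited by accumulating acetate — the only direction in which it is
physically consistent.  The dilution schedule is a documented stand-in
(0 → 0.5 → 0.2 → 0.8 at quarter-horizon marks, configurable); the original
profile is only available graphically.

**Noise.** The "realistic" per-measurement model is σ_ij = max(a·|m_ij|, b)
with defaults a = b = 0.05 in each output's units — the standard
relative-plus-floor model of analytical chemistry.  The original
per-measurement variance tables are third-party supplementary data and are
not bundled; consequently, fits to specific published SSE/AIC values for the
realistic-noise runs are only reproducible when those tables are supplied
(see `tests/test_acceptance.py::test_reference_measurement_set_reproduction`).

**What passing tests show.** Simulated data share the model family, complete
measurement grids, exactly known Gaussian noise, and exact stoichiometry.
They do not probe model mismatch (unmodeled intracellular dynamics,
volume changes, drifting variances), missing measurements, or wrong network
annotations — all of which affect real experiments.

## Problem sizes used in the test suite

The session-scoped recovery run uses the low-noise batch protocol sampled at
11 equidistant points on [0, 20] (the protocol default is 21) so the full
suite completes in a few minutes on one CPU; all generator noise and kinetic
settings are the defaults.  At this size the incremental run inserts ~7
knots and every one of the 7 flux profiles is recovered within 5% integrated
absolute deviation.  At the full 21-point grid recovery is 0.1–2% for six
fluxes while flux 6 — the smallest-magnitude flux, a difference of three
free fluxes — sits near the 5–6% boundary, limited by the finite-difference
SLSQP stack rather than by the method.

## Known limitations

* Early-horizon identifiability: with relative noise and a small inoculum,
  fluxes are weakly constrained while biomass is tiny (the state derivative
  scales with c_bio), so realistic-noise estimates can deviate strongly near
  t = 0 while still passing the χ² test.
* Local optimality only: the incremental warm-start scheme finds good local
  minima but there is no global search; no multistart is provided.
* Initial values of states that do not influence any output (e.g. dissolved
  O₂ when only its uptake flux is measured) are structurally unidentifiable
  and should be read as arbitrary.
* One knot insertion candidate per free flux per round, placed at the end of
  the horizon; profiles needing mid-horizon refinement rely on later windowed
  re-optimization.
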