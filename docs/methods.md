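# Methods

## Model

`ecostrat` simulates a minimal spatial ecosystem on a one-dimensional
domain x ∈ [0, L] (depth in a mat, sediment, or water column).  S consumer
species with densities N_i(x, t) deplete M chemical resources with
concentrations R_α(x, t):

    ∂N_i/∂t = N_i ( γ g_i(R) − Σ_{j≠i} A_ij N_j ) + D_N ∂²N_i/∂x²
    ∂R_α/∂t = − Σ_i f_iα(N, R) + D_R ∂²R_α/∂x²

with per-capita growth g_i = Σ_α Y_α k_iα R_α − m_i and bilinear
consumption f_iα = k_iα R_α N_i.  Y_α is the usable energy yield of
resource α, k the consumption-rate matrix (identity in the default
specialist configuration: species i consumes only resource i), m the
maintenance cost, and A the pairwise antagonism matrix (contact inhibition
or competition for space; zero diagonal).  Two global knobs define the
phase plane of interest: γ ≥ 0 scales self-replication (γ = 0 is abiotic
catalysis), and ρ ∈ [0, 1] is the fraction of nonzero off-diagonal entries
of A (ρ = 0 is no ecology).

Resources are supplied only at x = 0 at constant flux K_α; species obey
no-flux conditions at both ends.  The supply boundary condition is imposed
on the bare gradient,

    −∂R_α/∂x(0, t) = K_α − Σ_i f_iα(0, t),

i.e. the prescribed inward gradient is the supply flux minus boundary-layer
consumption.  A variant that divides the right-hand side by D_R (prescribing
the diffusive flux instead of the gradient) is available as
`flux_scaled_by_diffusion=True`; since K is in arbitrary units the two
differ only by a rescaling of the effective supply.

### Right boundary

The right boundary is closed by default (`right_boundary="closed"`:
∂R/∂x(L) = 0 — nothing enters or leaves the far end, and bulk consumption
at the boundary node is already accounted for by the reaction term).  An
alternative form that prescribes −∂R/∂x(L) = −Σ_i f_iα(L) is provided as
`right_boundary="literal"`.  That form makes boundary consumption act as a
resource *source* at x = L (the injected flux D_R·Σf grows with the local
consumption it feeds, a positive feedback with gain ~2 D_R/dx per unit
consumption), so in any regime with growing consumers the state diverges;
`integrate` then stops with a blow-up diagnostic, and a test pins this
behavior.  The closed form is the one consistent with a system that
exchanges mass with its surroundings only through the supply face, and is
used for all shipped results.

## Random communities

`sample_community(S, M, ρ, seed)` draws the community for one replicate:

- Y_α ~ Uniform(0, 2) i.i.d. — energy yields span a factor ~25 of the
  survival threshold range (see below);
- k = the S×M specialist delta matrix;
- m_i = 0.1 for all species;
- exactly round(ρ·S·(S−1)) ordered off-diagonal entries of A, chosen
  uniformly without replacement, each ~ Normal(0.4, 0.1), truncated at 0
  (the interactions model antagonism, never facilitation; a negative draw
  has probability ≈ 3×10⁻⁵).  A is not assumed symmetric: "fraction of
  interactions" is counted per ordered pair.

The draw order (Y, then slot choice, then strengths) is fixed, so a seed
identifies a community bit-for-bit.  Sweep replicates derive their seeds by
`SeedSequence([base_seed, gamma_index, rho_index, replicate])`, so any cell
can be rerun in isolation and a sweep is a pure function of its spec.

Supply fluxes default to K_α = 1 for all resources (configurable; all units
are arbitrary).  Scans over K ∈ {0.01 … 1} leave the order-parameter
phenomenology unchanged, so the choice is not load-bearing.

## Discretization and integration

Method of lines on a uniform grid (default 256 nodes over L = 100) with
second-order central differences; boundary conditions are imposed through
ghost nodes that force the centered gradient at the boundary to its
prescribed value.  Doubling the grid to 512 nodes changes saturated-regime
order parameters by < 10⁻⁴ (a test asserts < 10⁻²).

Time integration uses `scipy.integrate.solve_ivp(method="BDF")` with a
finite-difference Jacobian on the known sparsity pattern (node-local dense
blocks plus diffusion tridiagonals).  Steady state is declared when the
max-norm of the full right-hand side drops below `steady_tol = 10⁻⁶`
(absolute, arbitrary units), checked every 10 time units; the horizon is
`t_max = 10⁴`.  Runs that never reach steady state (see the knockout
regimes below) return `converged=False` rather than raising.  Solver
tolerances default to rtol = 10⁻⁶, atol = 10⁻⁹; tightening rtol tenfold
moves saturated-regime order parameters by < 10⁻⁷.

Reaction terms are evaluated on the nonnegative part of the state, so
solver undershoots below zero decay instead of amplifying.  At every
checkpoint, entries in (−clip_eps, 0) are clipped to zero and anything
below −clip_eps aborts with a diagnostic.  `clip_eps` defaults to 10⁻⁸,
one decade above atol: undershoot up to the local-error scale is expected
solver behavior, anything larger indicates a genuine failure.  A magnitude
guard at 10¹² converts runaway states into a blow-up diagnostic.

Initial conditions: species homogeneous at n0 = 0.1 (the value is
immaterial — perturbing n0 by ±50% moves the converged order parameter by
< 10⁻²; a test asserts this), resources at the decaying quadratic
R_α(x) = K_α (L − x)²/(2L), the unique quadratic with R(L) = R′(L) = 0
whose inward source gradient matches the supply flux when boundary
consumption is neglected (the consumption correction at t = 0 would make
the profile depend on n0; the transient forgets either choice).

### Mass ledger

With the ghost-node construction the trapezoid-quadrature resource mass
obeys an exact semi-discrete balance: d/dt ∫R_α dx = D_R (K_α − F_α(0)) −
∫Σ_i f_iα dx, with F the boundary-node consumption.  The integrator
accumulates both right-hand-side terms by composite Simpson quadrature on
the solver's own accepted steps (fixed-interval sampling misses the fast
initial transient and degrades closure to ~10⁻³).  The reported closure
error divides by the largest of |supplied|, |Δmass|, |consumed|: cumulative
supply alone can be near zero or negative early in abiotic runs, when
boundary-layer consumption exceeds K and the literal supply condition
reverses the boundary gradient.  Typical closure across regimes is ~10⁻⁷;
tests require < 10⁻³.

## Stratification metrics

Penetration depth of a profile: trapezoid area divided by the
concentration at the source, i.e. the width of the rectangle of height
R(0) with the profile's area.  Undefined (flagged, not raised) when
R(0) ≤ 10⁻⁹.  The order parameter of a run is −corr(Y, depths) over
resources with defined depths — Pearson by default (the relationship at
steady state is close to linear in the stratified regime; Spearman is a
configuration option), undefined when fewer than two valid resources
remain or either vector is constant.  Undefined order parameters are
excluded from ensemble means, never zero-imputed; summaries report the
number excluded.

The displacement diagnostic ranks surviving species (peak density ≥ 10⁻⁹)
by the grid position of their density maximum, ties broken by species
index.  At the standard parameters the saturated steady state is a
coexistence: antagonism at strength ~0.4 suppresses but does not exclude
subordinate species at the source, so several species typically share an
arg-max at exactly x = 0 while the lowest-yield species form interior
bumps.  The energy-ordering test therefore checks the claim as a weak
ordering — peak positions non-decreasing when species are sorted by
descending Y — rather than demanding that an arbitrary tie-break
reproduce the Y-sort.

## Regimes and what the tests show

- Saturated regime (γ = 1, ρ = 1): converges in a few hundred time units;
  order parameters ~0.90–0.99, ensemble mean ≈ 0.95 over 20 seeds.
- Self-replication knockout (γ = 0, ρ = 1): antagonism alone makes the
  catalysts annihilate each other algebraically (N ~ 1/t), so resources
  accumulate at rate ~D_R K/L indefinitely and no steady state exists;
  runs stop at t_max with `converged=False` and the order parameter is
  measured on the final state.  Depths are set by each catalyst's decay
  history, which is independent of Y, so the ensemble is null-centered.
- Ecology knockout (ρ = 0, γ = 1): each specialist–resource pair decouples
  and converges to a localized steady state near the source (species
  extent ~ sqrt(D_N/m) = 10 ≪ L).  Because both the survival threshold
  R* = m/(γY_α) and the equilibrium biomass are monotone in Y_α, resource
  boundary layers order by energy *without any ecology*: the measured mean
  order parameter is ≈ +0.9, not 0.  The package reports this regime as
  the model produces it; the corresponding null-control test codifies the
  published expectation and fails against it.  The effect is robust to
  the supply flux (K ∈ {0.01…1}), the maintenance rate (m ∈ {0, 0.01,
  0.1}), and both supply-flux conventions, and sets in by t ≈ 80 with no
  transient null-centered plateau — so it is a property of the dynamics,
  not of measurement timing.
- Degenerate corner (γ = 0, ρ = 0): with identical consumption constants,
  supply and initial density, all M resource profiles are identical, the
  depth vector has zero variance, and the order parameter is undefined;
  such runs are excluded from means and counted.

## Synthetic data and scope

All inputs are generated by the package itself (random communities,
closed-form initial profiles, hand-crafted metric fixtures); no empirical
profiles ship with it.  The generator emulates the study conditions —
specialist consumers, uncorrelated uniform energy yields, dense Gaussian
antagonism — and none of the complications of real stratified systems:
cross-feeding and byproduct chains, generalist diets, light/temperature
dependence, advection, 2-D or 3-D geometry, or measurement noise in
profiles.  Passing tests therefore demonstrate properties of this model
class, not of field data; the metrics module, however, accepts external
profile tables (CSV) so the same statistic can be applied to measured
concentration profiles.

## Problem sizes

Shipped ensembles use 20 replicates per regime at 256 nodes, which resolves
every reported quantity to well inside its tolerance (grid doubling moves
order parameters by < 10⁻⁴).  The full phase-plane sweep API supports
arbitrary γ×ρ grids and replicate counts; the bundled defaults
(5×5 cells × 10 replicates) are a scaled-down rendering of the phase
diagram, chosen to keep a desktop run in minutes.
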