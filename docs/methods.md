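# Methods

This note documents the models, algorithms and numerical choices behind
`pkident`, and what the shipped synthetic studies do and do not demonstrate.

## Model abstraction

A model is `dx/dt = g(t, x, θ)`, `x(t0) = x0(θ)`, with a scalar observed
response obtained by mapping the state trajectory (by default the first
state, typically a plasma concentration) and multiplying by
`response_unit_scale`. Parameters carry integer dimension vectors over three
base dimensions — amount, volume, time — which cover all units appearing in
PK compartment models of this kind (litres, hours, molar concentrations and
unitless fractions); mass and length are deliberately not represented, and
the unit parser is not a general units engine.

Numerics: the generic path integrates with a stiff-capable solver (LSODA,
relative tolerance 1e-8). The absolute tolerance defaults to
`1e-12 / response_unit_scale`: states are integrated on the *unconverted*
scale, so when the raw response is of order `1/response_unit_scale` (e.g.
1e-9 M with a 1e9 M→nM conversion) the tolerance tightens proportionally and
the noise floor stays far below the signal. Solver failures and non-finite
states raise errors naming the offending parameter vector; inside a
likelihood they are treated as zero-probability proposals and logged.

The one- and two-compartment fixtures also carry exact closed-form solutions
(a single exponential; the eigendecomposition of the 2×2 rate matrix, with a
numeric fallback at repeated eigenvalues). `solve_model` uses the closed form
unless `force_numeric=True`; the test suite requires numeric/analytic
agreement to 1e-6 relative and solver self-convergence under tolerance
halving. The closed forms are what make the shipped simulation studies
(hundreds of MCMC runs) cheap, and they give the integrator an independent
oracle.

The one-compartment fixture is *deliberately* rank-deficient from plasma
data alone: `C(t) = (F·D/V)·exp(-(CL/V)t)` depends on (F, V, CL) only
through F/V and CL/V. Its fixture constants (F = 0.7, V = 3 L,
CL = 0.2 L/h, dose D = 1, priors U(0,1), U(0.5,10), U(0.01,2)) are chosen
near physiological magnitudes for plasma volume and antibody clearance; they
are package constants, not literature claims. The same applies to the
two-compartment fixture (V1 = 3, V2 = 11, CL = 0.25, Q = 0.5), whose four
parameters are generically identifiable from the biexponential profile.

The 16-state mPBPK brain scaffold registers the compartment list and the ten
candidate parameters with their literature nominal values and uniform priors
(e.g. VP = 3.12 L with U(0,100), LT = 0.32 L/h with U(0.289, 0.353), the
switch fractions σ with U(0,1)). The rate equations of that model are
published elsewhere and are not guessed here: the scaffold refuses to
integrate until the user supplies `dynamics`, `initial_condition` and the
remaining parameters. Consequently the package's quantitative studies run on
the fixtures, not on the full brain model.

## Sensitivities

Sensitivities are `∂(response)/∂log θ_j` at nominal values, computed on the
unit-converted response so entries are well-scaled. Default scheme: central
differences in log-parameter space with absolute step 1e-4 in log units —
second-order accurate and requiring nothing from the model. A complex-step
scheme (exact to roundoff) is available for models with analytic solutions
and is used in tests as the reference; the two agree to 1e-5 on the
fixtures. The differentiation scheme and step are package choices; steps
below 1e-12 are rejected as underflow, and non-positive nominal values are
rejected because the log transform is undefined there.

## Parameter subset selection

Greedy elimination: compute the SVD of the current sensitivity matrix,
record `r = (σ_min/σ_max)²`, and remove the column with the
largest-magnitude component in the right singular vector of σ_min, until one
column remains. The threshold never enters the elimination itself, so one
trace serves every ladder; subsets are therefore exactly nested and larger
thresholds are stricter (keep fewer parameters). The stopping rule declares
all current parameters identifiable when `r ≥ η`, evaluated on the ratios of
the matrices *before* each elimination (sizes p…2, with the single-column
endpoint assigned ratio 1). Near-ties in the singular-vector components
(within 1e-9 relative) resolve to the highest column index, which makes the
order deterministic including at exact rank deficiencies, where the
components are equal in exact arithmetic. Singular-vector sign ambiguity is
irrelevant since only magnitudes are used.

The verification error norm R̄ of a subset perturbs every excluded parameter
by +20% of nominal, refits the subset by bounded least squares against the
nominal-parameter response, and averages |fit − nominal|/max|nominal| over
the grid. Both the perturbation size and the refit are configurable choices.
One caveat discovered with the one-compartment fixture: perturbing *all*
excluded parameters by a common factor can be an exact model symmetry (there,
scaling F, V, CL together leaves the response invariant), in which case
R̄ = 0 even for a genuinely insufficient subset. The tests exercise the
positive case on the two-compartment model, where no such symmetry exists.

## Dimensional analysis

All linear algebra is exact over the rationals (sympy): floating null spaces
produce spurious small exponents. Writing the response as a monomial in the
dimensioned quantities gives one linear equation per base dimension; the
particular solution is the reduced-echelon solution with free exponents set
to zero, and the null-space basis — the new dimensionless products — is
canonicalized to coprime integer exponents with positive leading entry, in
reduced echelon over the free variables in input order. Unitless quantities
pass through as their own products. Alternate quantity orderings give
different bases spanning the same lattice (verified by mutual rational
expressibility in tests). The product count always equals
(# dimensioned quantities) − rank(dimension matrix).

Pair relations: a bounded search over integer combinations of the basis
products (|exponent| ≤ 3, restricted to products mentioning the pair) looks
for a dimensionless monomial containing both pair members; among hits the
simplest wins (fewest distinct quantities, then smallest total degree,
preferring a positive exponent on the first member). Same-sign exponents on
the pair mean their *product* is pinned along the unidentifiable direction —
an inverse relation; opposite signs pin the ratio — a proportional relation.

## DRAM sampler

Likelihood: `y_i = f(t_i, θ) + ε_i`, `ε_i ~ iid N(0, σ²)`, independent
uniform priors, response compared on the converted unit scale (σ² lives on
that scale; posterior parameter means are unit-invariant, which the tests
check across a 1e9 scale change). First-stage proposal: Gaussian random walk
with covariance C; on rejection a second-stage proposal with covariance
`γ²C` (γ = 1/5) is attempted, accepted with the standard two-stage
delayed-rejection probability that preserves detailed balance. C starts at
`diag((0.05·prior width)²)` and is re-estimated every 100 draws from the full
chain history (running moments, O(d²) per iteration), scaled by `2.38²/d`
with a 1e-10 ridge; a non-positive-definite adapted covariance is
re-regularized, never fatal. σ² is redrawn each iteration from its conjugate
inverse-gamma full conditional, `InvGamma((n0+n)/2, (n0·s0² + SS)/2)`, with
a weakly informative default (n0 = 1, s0² set from the initial residual
scale). Burn-in defaults to the first 60% of the chain. All randomness flows
through one seeded generator per run; identical seeds give bitwise-identical
chains.

ESS uses the initial-positive-sequence truncation: `M/(−1 + 2Σ_m Γ_m)` with
`Γ_m = ρ_{2m} + ρ_{2m+1}` summed while positive, autocovariances via FFT.
A constant chain returns 0 with a degeneracy warning. The estimator is
validated against the AR(1) closed form `M(1−ρ)/(1+ρ)` and cross-checked
against an independent library implementation in the tests.

Posterior-predictive bands: pointwise quantiles of `f(t, θ̃)` over
post-burn-in draws (credible band) and of `f(t, θ̃) + σ̃Z` with the paired σ²
draw (prediction band), with several noise replicates per draw to stabilize
the outer quantiles. Requesting more draws than available samples falls back
to sampling with replacement, with a warning.

## Refinement criteria and loop

The three criteria are quantitative operationalizations of what is usually
judged from trace and pairwise scatter plots, and their thresholds are
package defaults validated on the fixtures, not universal constants:

* **C1** — a pair is "nearly single-valued" when |Pearson correlation| on
  raw samples, or on log samples for positive parameters, reaches 0.995.
  Posterior ridges produced by multiplicative non-identifiabilities are
  straight lines in log space, which is why the log check matters.
  Zero-variance marginals are reported separately. The member to fix is the
  user's override if given, else the pair member eliminated earlier in the
  PSS trace (less identifiable; a parameter never eliminated counts as most
  identifiable), else the later-listed member. The dimensional-analysis
  relation, when available, is attached as justification.
* **C2** — a marginal is uninformed when its Kolmogorov–Smirnov distance to
  the uniform prior is strictly below 0.1 (the boundary case resolves to
  "informed"). All uninformed parameters are fixed in one step: under a
  nested ladder each threshold adds one parameter, so this coincides with
  fixing them one at a time but saves reruns.
* **C3** — every per-parameter ESS must reach 1000. A failing row escalates
  the chain length once (×4) — lengthening the chain being the first
  standard remedy — before being marked unresolved.

The loop walks thresholds from largest to smallest, starting each row from
the ladder subset minus everything excluded earlier (monotone exclusion: a
fixed parameter never re-enters), and reports per-row verdicts plus the
largest refined subset over all rows (ties resolve to the smaller
threshold). An empty resolvable subset everywhere raises an explicit "no
subset consistent with successful inference" error, signalling that the
initial screening should be revisited. Per-row, per-attempt seeds derive
from one seed sequence, so reports are reproducible.

## Synthetic data

`generate_synthetic` solves the model at the true (nominal) parameters on
the grid (default 0–1000 h, 1001 points) and adds i.i.d. Gaussian noise.
Default noise scale: sd = fraction·max|response| with fraction 0.02; 0.01,
0.05 and 0.10 are the other levels used in the studies. The literal
variance reading (σ² = fraction·max) is available as `variance-of-max` but
is unit-dependent — at molar magnitudes it produces noise larger than the
signal — hence not the default.

What the generator emulates: dense, uniformly sampled single-response data
with homoscedastic Gaussian error and a known true parameter vector. What it
does not: sparse/irregular clinical sampling, proportional or combined error
models, inter-individual variability, model misspecification. Passing tests
therefore demonstrate correctness of the machinery under the stated error
model, not robustness of any particular PK conclusion to real-data
pathologies.

## Study sizes and tolerances

The shipped studies use: recovery fits with 5e4 draws (60% burn-in),
injected-target checks with 1e5 draws, and a coverage study of 200
replicates at 2e4 draws each with 95% bands scored against a fresh noise
realization — sizes chosen so the full suite runs at desk scale in minutes
while keeping Monte-Carlo error well inside the asserted bounds (posterior
means within 3 posterior sd; ESS ≥ 1000; coverage within [0.90, 0.99];
sampler moments within 0.05–0.1 of truth at ESS ≥ ~1e4).

## Known limitations

* No forward/adjoint sensitivity ODE augmentation — finite differences cost
  2p solves per matrix, fine at desk scale.
* Single-chain diagnostics only (ESS); no Gelman–Rubin/Geweke multi-chain
  statistics, no Hamiltonian or tempering samplers, and the marginal
  likelihood is never computed.
* The C1 detector is pairwise and correlation-based; a curved three-way
  dependence that is not pairwise-linear in raw or log space could escape
  it (the dimensional-analysis report is the backstop for monomial
  relations).
* Prior re-specification (e.g. tightening a physiologically implausible
  prior) is deliberately manual, via the configuration, not automated.
* The full 16-state mPBPK model's equations must be supplied by the user;
  nothing in this package reproduces results that depend on them.
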