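# pkident

Identifiability-informed Bayesian calibration of ODE models, built for
pharmacokinetic (PK / minimal PBPK) compartment models: which parameters can
plasma-concentration data actually determine, and what are their posterior
uncertainties?

Compartmental PK models routinely carry more parameters than a single
measured response can pin down. Calibrating all of them at once produces
poorly mixing MCMC chains, posterior ridges and biased estimates. `pkident`
implements a screening-then-refinement workflow:

1. **Local sensitivity analysis** — the n×p matrix
   `s_j(t_i) = ∂y(t_i)/∂log θ_j` of the observed response with respect to
   log-transformed parameters, evaluated at nominal values θ\*.
2. **Parameter subset selection (PSS)** — greedy SVD elimination: while the
   squared singular-value ratio `(σ_min/σ_max)²` of the current sensitivity
   matrix is below a threshold η, drop the column dominating the right
   singular vector of σ_min (the least identifiable parameter). One
   elimination trace yields nested candidate subsets `A_1 ⊂ … ⊂ A_k` for a
   decreasing ladder of thresholds.
3. **Exact dimensional analysis** — Buckingham-Pi reduction over the
   rationals: write `y = C0^a · Π θ_j^{e_j} · H(π_1, …, π_q)` and solve the
   dimension equations exactly, enumerating the dimensionless products π and
   candidate algebraic relations between parameter pairs.
4. **DRAM sampling** — delayed-rejection adaptive-Metropolis MCMC for the
   posterior `π(θ|y) ∝ p(y|θ) π0(θ)` under `y_i = f(t_i, θ) + ε_i`,
   `ε_i ~ N(0, σ²)`, with conjugate inverse-gamma updates for σ², Geyer
   effective-sample-size (ESS) diagnostics and posterior-predictive credible
   and prediction bands.
5. **Iterative refinement** — for each ladder subset, sample and test three
   criteria: **C1** no near single-valued pairwise posteriors (algebraic
   dependence, cross-checked against the dimensional analysis), **C2** every
   marginal differs from its prior (the data inform the parameter), **C3**
   ESS ≥ 1000 for every chain. Offending parameters are fixed at their
   nominal values; the largest refined subset across thresholds is reported.

Fully specified one- and two-compartment fixture models ship with the
package, together with a configuration scaffold for a 16-state minimal PBPK
model of antibody disposition in the brain (compartments and the ten
candidate parameters with units, nominal values and uniform priors are
pre-registered; the rate equations are user-supplied).

## Worked example

```python
import numpy as np
import pkident as pk
from pkident.pss import SubsetLadder
from pkident.refine import run_refinement

model = pk.fixture_onecomp()          # C(t) = (F·D/V)·exp(-CL·t/V), D = 1
grid = pk.TimeGrid()                  # 0-1000 h, 1001 points

# synthetic data: 2% of the response maximum as the noise sd
data = pk.generate_synthetic(model, grid=grid, noise_fraction=0.02, seed=11)

# sensitivity + subset selection
S = pk.sensitivity_matrix(model, grid)
trace = pk.eliminate_order(S)
print(trace.order)
# [('CL', 1.381781227923363e-18), ('V', 0.13735437623410054)]
#   ^ exact rank deficiency: F, V, CL enter only through F/V and CL/V

# calibrate the 2-parameter subset (V fixed at nominal)
calib = pk.BayesianCalibration(data.values, data.times, model, ["F", "CL"],
                               grid=grid)
res = calib.fit(draws=50_000, seed=0)
print(res.summary())
```

```
parameter        mean          sd         ESS
----------------------------------------------
F                0.7081    0.008603        2356
CL               0.2039    0.003756        2261
sigma2        2.188e-05
draws=50000  post-burn-in=20000  acceptance=0.58
```

The posterior means sit within one posterior standard deviation of the truth
(F = 0.7, CL = 0.2) and both chains mix well (ESS ≳ 2000). Running the full
refinement over the ladder `{F,CL} ⊂ {F,CL,V}` flags the posterior ridge of
the rank-deficient 3-parameter subset (pairwise correlations ≥ 0.995), fixes
one ridge member at its nominal value, and reports a final refined subset of
two parameters:

```python
ladder = SubsetLadder(thresholds=[1e-2, 1e-9],
                      subsets=[["F", "CL"], ["F", "CL", "V"]])
report = run_refinement(model, data.times, data.values, ladder,
                        draws=50_000, seed=5, trace=trace, grid=grid)
print(report.to_text())
```

```
       eta  refined candidates                       C1 C2 C3  excluded
--------------------------------------------------------------------------------
      0.01  F, CL                                    +  +  +  —
     1e-09  F, V                                     +  +  +  CL(C1)
final refined subset: F, V
```

A command-line interface wraps the same pipeline:
`pkident simulate|sens|pss|dimred|sample|refine --config run.yaml`.

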