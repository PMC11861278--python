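# Methods

## The model

`depdyn` implements a seven-compartment model of depression spreading in a
population that also contains *saboteurs* — individuals who deliberately
undermine others' mental health.  The compartments are susceptible (S),
saboteurs (B), primary depression (P), secondary depression (D),
non-pharmacological treatment (M), pharmacological treatment (C) and
recovered (R).  With N = S+B+P+D+M+C+R,

    S' = Λ − β₁BS/N − β₂DS/N − μS
    B' = β₁BS/N − μB
    P' = β₂DS/N − λ₁BP/N − (λ₂+μ+ψ₁)P
    D' = λ₁BP/N + λ₂P + ωR − (ψ₂+μ+σ)D
    M' = ψ₁P − (γ₁+μ)M
    C' = ψ₂D − (μ+γ₂)C
    R' = γ₁M + γ₂C − (μ+ω)R

Both contact processes are frequency-dependent.  Summing the equations
gives N' = Λ − μN − σD, so the box 0 ≤ xᵢ, N ≤ Λ/μ is positively
invariant; the integrator's output is checked against this at run time.

The controlled variant adds three bounded intervention rates: u₁ on the
P→M uptake, u₂ on the D→C uptake, u₃ on the C→R recovery.  In the
controlled P and D equations the saboteur-aggravation term is λ₁BP/N, the
same mass-action term as the base model — the controlled system must
reduce exactly to the base system at u = 0, and the control terms are pure
transfers that cancel in N'.

A structural consequence worth knowing: M and C feed back into the
depressed compartments only through the relapse loop R→D (rate ω).
Raising a recovery rate γ₁ or γ₂ therefore leaves P+D exactly unchanged
when ω = 0 and *weakly raises* it when ω > 0, while unambiguously raising
R.  The package's monotonicity tests assert exactly these structurally
valid directions (P+D rises with β₂ and falls with ψ₁, ψ₂; R rises with
γ₁, γ₂).

## Parameters and defaults

Rates are per year.  The bundled baseline is the published Spain-scale
calibration: λ₁ = 0.2145, λ₂ = 0.7, ψ₁ = 0.0045, ψ₂ = 0.02, γ₁ = 0.6,
σ = 0.01, ω = 0.005, μ = 0.0125 (1/80-year lifespan), with the fitted
rates β₁ = 0.5665, β₂ = 0.1567, γ₂ = 0.9219.  Recruitment is a per-capita
birth rate of 7.816/10,000 per year; because the sources never fix the
population scale, Λ is configurable either as an absolute inflow or as
per-capita × reference population (default reference 47,400,000, giving
Λ ≈ 37,048/yr and a carrying capacity Λ/μ ≈ 2.96 million).  All
downstream quantities except absolute compartment counts (notably R₀ and
all elasticities) are invariant to this scale choice.

## Reproduction number

R₀ is the spectral radius of FV⁻¹ on the infected subsystem (P, D, M, C).
One unusual convention is inherited deliberately: the transition matrix V
is linearised at the *saboteur-present* depression-free equilibrium E₁
(saboteur fraction B*/N* = (β₁−μ)/β₁ enters the P outflow), while the
new-infection matrix F carries the bare β₂.  This yields the closed form

    R₀ = β₂(β₁λ₁ + β₁λ₂ − λ₁μ) /
         [(μ+ψ₂+σ)(β₁λ₁ + β₁λ₂ + β₁μ + β₁ψ₁ − λ₁μ)]

and requires β₁ > μ.  At the baseline, R₀ ≈ 3.6194.  Because of the mixed
linearisation, R₀ > 1 does **not** imply that E₁ is locally unstable — at
the baseline all seven eigenvalues of the Jacobian at E₁ are negative and
the depression-free state is in fact attracting from generic interior
starts, while depression-endemic equilibria coexist.  The package reports
both facts rather than forcing textbook threshold behaviour.

Elasticities (∂R₀/∂p · p/R₀) are computed by central finite differences
with relative step 1e-6 on the closed form; the two analytically known
cases (β₂ ↦ exactly 1, σ ↦ −σ/(μ+ψ₂+σ)) serve as built-in self-tests.
R₀ grids mark cells with β₁ ≤ μ as NaN instead of silently switching to a
different linearisation.

## Equilibria and stability

E₀ = (Λ/μ, 0, …, 0) and E₁ = (Λ/β₁, (β₁/μ−1)Λ/β₁, 0, …, 0) are exact.
The published closed-form chains for the saboteur-free equilibrium E₂ and
the endemic quintic coefficients contain transcription irregularities
(unbalanced grouping, a dimensionally inconsistent constant); they are
kept verbatim as cross-check material — the E₂ chain is evaluated and
labelled a candidate with its residual reported honestly — while the
authoritative path is multi-start root-finding (seeded Halton scatter in
[0, Λ/μ]⁷ plus the closed forms and a 200-year simulated attractor),
with roots verified by residual (≤ 1e-9 · max(1, N)), deduplicated at
1e-6 relative, and labelled E₀/E₁/E₂/E₃ by their zero pattern.

Stability is classified numerically from the Jacobian's eigenvalues with
threshold ε = 1e-8 × spectral scale; anything not clearly on one side is
reported `marginal`, never silently promoted.  The Jacobian is available
as central finite differences (relative step 1e-7) and as the exact
analytic derivative; the two agree to 1e-5 and the analytic form is
verified against a computer-algebra derivation in the test suite.

## Calibration

The observable is the reported yearly case count, by default the total
currently depressed (P+D) × population scale (configurable to D only).
The initial state is reconstructed from the series: the first-year case
mass is split between P and D (default 50/50), saboteurs start at 1% of
the configured total population, and M = C = R = 0.

Because the first observation is itself noisy, seeding the model
deterministically from it injects that noise into every prediction and
mis-calibrates the confidence intervals (measured coverage dropped to
~50–78% from this mechanism alone).  The initial depressed mass is
therefore co-estimated as a bounded nuisance multiplier on the first
observation (default on, bounds [0.5, 2]); the reported standard errors
are marginal over it.

The default noise model is Gaussian with standard deviation proportional
to the count (unknown CV, profiled analytically), under which maximum
likelihood is exactly weighted least squares on relative residuals — the
right weighting for a growing count series.  A constant-variance Gaussian
and a Poisson model are available behind `noise_model`.  Optimisation is
a bounded trust-region-reflective least-squares solver from a seeded
Latin-hypercube multi-start (default 8 starts, bounds (0, 1] per rate);
the inner ODE solve uses fixed-step RK4 with a 0.05-year sub-step,
cross-checked against the adaptive integrator in the tests.  Wald 95%
intervals come from the finite-difference Hessian of the profiled NLL at
the optimum, inverted by eigendecomposition: directions with non-positive
curvature carry no information and yield an infinite standard error and
an interval spanning the feasible box.

**Identifiability.**  On the default synthetic scenario the two contact
rates are well identified (median relative error ≈ 3% and 2% at 2% noise
over 12 years).  The pharmacological recovery rate γ₂ is *structurally
near-unidentifiable* from a P+D series under this initial-state rule:
with C(0) = 0, the C compartment is fed only through ψ₂ = 0.02·D, and a
10% change in γ₂ moves the observable by about 0.006% — three orders of
magnitude below the observation noise.  Its point estimates pile up at
the optimizer bounds, while the interval machinery correctly reports the
flat direction (coverage stays nominal because the interval widens to the
box).  Fitting γ₂ from this observable requires either treated-population
data or a drastically larger ψ₂; the package reports what the data can
and cannot determine instead of hiding the flat direction.

## Synthetic data

The generator simulates the model at known true parameters from a
deterministic compartment split, reads the observable at yearly points
and adds seeded noise (Gaussian with sd = CV × signal, truncated at zero
— negligible bias at the default CV = 2%, noticeable above CV ≈ 30%; or
Poisson).  The default scenario is loosely Spain-shaped but synthetic: 12
yearly points, baseline rates, total population Λ/μ, and an initial split
(S, B, P, D) = (94%, 1%, 2.5%, 2.5%) chosen to mirror the calibrator's
initial-state rule so that generator and fitter agree exactly in the
noise-free limit.  What passing tests show is internal consistency of the
whole pipeline under the model's own assumptions; they do not validate
the model against real surveillance data, which carries reporting delays,
definition changes and non-iid noise that the generator does not emulate.

## Optimal control

The objective charges the burden compartments linearly and the controls
quadratically, J = ∫₀^tf (W₁P + W₂D + W₃M + W₄C + ½W₅u₁² + ½W₆u₂² +
½W₇u₃²) dt, with published default weights (1, 1, 1, 1, 15, 40, 55),
box bounds [0, 1] and a 15-year horizon.  Pontryagin's principle gives
adjoints λ' = −∂H/∂x with λ(tf) = 0 and projected stationary controls
u₁ = clip((λ₃−λ₅)P/W₅), u₂ = clip((λ₄−λ₆)D/W₆), u₃ = clip((λ₆−λ₇)C/W₇).

The adjoint right-hand side is generated from the exact Jacobian of the
implemented dynamics (λ' = −(∇ₓL + Jᵀλ)); a historically printed version
of these equations with sign/term irregularities is retained as
`adjoint_rhs_printed` purely as a logged cross-check.

The solver is the standard forward–backward sweep: RK4 forward pass on a
uniform grid (default 1501 points over 15 years), RK4 backward pass for
the adjoints, control update with relaxation 0.5, iterated until the
worst relative sup-norm control change falls below 1e-6 (default; this is
deliberately tighter than the loosest tolerance that stops the iteration,
because the interior stationarity residual |∂H/∂u| scales like W·|u−ũ|
and W₇ = 55).  Non-convergence returns the flagged last iterate.

Strategy comparison runs the seven control masks A = {u₁} … G = {all}
plus a no-control baseline.  Enlarging the admissible control set can
only improve the optimal J, and G attains both the lowest J and the
lowest final secondary-depressed count on the default scenario.  One
caveat: in final-count terms a *larger* control set can marginally raise
D(tf) through the relapse loop (u₃ moves mass into R, which relapses at
ω), e.g. strategy F's D(tf) sits ~0.07% above A's; the component-wise
dominance statement is therefore exact in J but only approximate in
D(tf).

## Problem sizes and numerics

Defaults used by the test suite and the acceptance script: adaptive RK45
at rtol 1e-8/atol 1e-10 for trajectory work (undershoot guard at
−1e-8·max(1, Λ/μ), smaller undershoots clamped to zero in reported output
only); fixed-step RK4 (0.05-year sub-steps) in the calibration inner loop;
1000 draws for the invariance sweep; 20 replicates for the recovery study
and 100 for interval calibration (2 starts, 80-evaluation budget per
start); 1501-point sweep grid for the single optimal-control solve and a
301-point grid for the eight-run strategy comparison.

## Known limitations

- Homogeneous mixing; no age, spatial or network structure; no
  demographic stochasticity.
- The published absolute strategy trajectories (millions of secondary
  depressed) are not reproducible because their initial conditions were
  never stated; the package's scenario is a documented synthetic stand-in
  and only ordering/reduction properties are asserted.
- Real-data calibration against the Spanish case series requires the user
  to supply that series as CSV; it is not bundled.
- γ₂ is not identifiable from the default observable (see Calibration).
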