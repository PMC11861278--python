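# depdyn

Compartmental modelling, maximum-likelihood calibration and optimal
control of depression dynamics in a population that contains
**saboteurs** — individuals who deliberately undermine others' mental
health and accelerate the progression from mild to severe depression.

The package is aimed at infectious-disease-style modellers of mental
health and social contagion: it provides the deterministic model, its
basic reproduction number and sensitivity analysis, equilibrium and
stability analysis, calibration to yearly prevalence series, a
synthetic-data generator for end-to-end validation, and a Pontryagin
optimal-control solver for comparing treatment strategies.

## The model

Seven compartments — susceptible S, saboteurs B, primary (mild)
depression P, secondary (severe) depression D, non-pharmacological
treatment M, pharmacological treatment C, recovered R — with
frequency-dependent contact:

    S' = Λ − β₁BS/N − β₂DS/N − μS        B' = β₁BS/N − μB
    P' = β₂DS/N − λ₁BP/N − (λ₂+μ+ψ₁)P    D' = λ₁BP/N + λ₂P + ωR − (ψ₂+μ+σ)D
    M' = ψ₁P − (γ₁+μ)M                   C' = ψ₂D − (μ+γ₂)C
    R' = γ₁M + γ₂C − (μ+ω)R

The total population obeys N' = Λ − μN − σD, so [0, Λ/μ]⁷ is positively
invariant.  The basic reproduction number, from the next-generation
matrix linearised at the saboteur-present depression-free equilibrium, is

    R₀ = β₂(β₁λ₁ + β₁λ₂ − λ₁μ) /
         [(μ+ψ₂+σ)(β₁λ₁ + β₁λ₂ + β₁μ + β₁ψ₁ − λ₁μ)]

The optimal-control extension adds three bounded interventions (u₁:
non-pharmacological uptake, u₂: pharmacological uptake, u₃: enhanced
recovery) minimising
J = ∫ (W₁P + W₂D + W₃M + W₄C + ½W₅u₁² + ½W₆u₂² + ½W₇u₃²) dt
via a forward–backward sweep.  See `docs/methods.md` for assumptions,
numerics and known limitations (including which parameters the data can
actually identify).

## Worked example

The bundled `examples/spain_config.yaml` encodes the published
Spain-scale baseline (per-capita births 7.816/10,000, 1/80-year
lifespan, fitted rates β₁ = 0.5665, β₂ = 0.1567, γ₂ = 0.9219).

```console
$ depdyn r0 -c examples/spain_config.yaml
R0 = 3.61943
     beta1  +0.000095
     beta2  +1.000000
   lambda1  +0.004229
   lambda2  +0.014114
      psi1  -0.004856
      psi2  -0.470588
     sigma  -0.235294
        mu  -0.307701
```

R₀ ≈ 3.62: each depression case seeds well over one new case, so
depression persists.  The second column is the elasticity of R₀ —
doubling β₂ doubles R₀ (elasticity exactly 1), while the treatment
uptake ψ₂ and excess mortality σ pull R₀ down.

Generate a synthetic 12-year case series at the baseline with 2%
observation noise, then fit the three contact/recovery rates back:

```console
$ depdyn generate -c examples/spain_config.yaml -o series.csv --seed 7
wrote series.csv: 12 yearly observations
$ depdyn fit -c examples/spain_config.yaml -d series.csv -o fit.json
parameter  estimate  standard_error  ci95_lower  ci95_upper
    beta1  0.550973        0.016487    0.518659    0.583287
    beta2  0.155189        0.003388    0.148549    0.161828
   gamma2  1.000000        9.186621    0.000001    1.000000
```

The contact rates come back within ~3% of truth with tight intervals.
γ₂'s huge standard error is the honest answer: a P+D case series carries
almost no information about the pharmacological recovery rate (see the
identifiability discussion in `docs/methods.md`), so its interval spans
the whole feasible box.

Compare intervention strategies (subsets of u₁, u₂, u₃) over 15 years:

```console
$ depdyn strategies -c examples/spain_config.yaml -o strategies.csv
strategy            J       D_at_tf  percent_reduction_vs_baseline ...
baseline 3.417498e+06 233894.906304                       0.000000
       A 1.950374e+06  99829.482465                      57.318659
       B 4.912020e+05    872.326525                      99.627043
       ...
       G 3.143890e+05    786.138209                      99.663893
```

Deploying all three controls (strategy G) cuts the final
secondary-depressed count by ~99.7% relative to no intervention on this
synthetic scenario, and attains the lowest objective of all strategies.

Other commands: `simulate` (trajectory CSV), `sensitivity` (elasticity
CSV), `equilibria` (equilibrium/stability report), `control` (optimal
control profiles).  Every command is deterministic given its config and
seed, and embeds a provenance block in its output.

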