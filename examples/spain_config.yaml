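# Example configuration: the published Spain-scale baseline.
# Rates are per year; recruitment is per-capita births times the
# reference population.
parameters:
  recruitment:
    per_capita: 7.816e-4
    reference_population: 47400000
  beta1: 0.5665        # saboteur contact
  beta2: 0.1567        # depression contact
  lambda1: 0.2145      # saboteur aggravation (P -> D via contact with B)
  lambda2: 0.7         # progression P -> D
  psi1: 0.0045         # uptake of non-pharmacological treatment
  psi2: 0.02           # uptake of pharmacological treatment
  gamma1: 0.6          # recovery, non-pharmacological
  gamma2: 0.9219       # recovery, pharmacological
  sigma: 0.01          # depression-related mortality
  omega: 0.005         # relapse R -> D
  mu: 0.0125           # natural mortality (1/80 years)

population:
  # initial_total defaults to the carrying capacity Lambda/mu
  fractions: {S: 0.94, B: 0.01, P: 0.025, D: 0.025, M: 0.0, C: 0.0, R: 0.0}

simulate:
  horizon: 20
  points: 201

generate:
  n_years: 12
  start_year: 2011
  noise_model: gaussian
  cv: 0.02
  seed: 1

fit:
  free: [beta1, beta2, gamma2]
  n_starts: 8
  seed: 0

control:
  horizon: 15
  grid: 1501
  state_cost: [1, 1, 1, 1]
  control_cost: [15, 40, 55]
  lower: [0, 0, 0]
  upper: [1, 1, 1]
  strategy: G
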