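# Default run configuration for the LHS engine-drivetrain simulator.
#
# Axis order everywhere: (clinical, education, research, governance).
# Coupling rows receive, columns influence.  The four fixed spillovers
# (governance->clinical 0.18, governance->education 0.10,
# governance->research 0.10, clinical->research 0.12) are model
# constants; the remaining off-diagonal cells are free calibration
# choices, each kept <= 0.10.

transmission:
  a: 10.0        # logistic slope of transmission efficiency
  m0: 0.5        # CTI at which half of engine capacity transmits

friction:
  r_max: 0.6     # ceiling on contextual-friction reduction
  eta: 2.0       # Hill exponent
  c: 0.5         # CTI at half-maximal friction reduction

wheels:
  v_max: [1.33, 1.05, 1.34, 1.11]   # velocity ceilings, month^-1

coupling:
  matrix:
    - [0.00, 0.08, 0.10, 0.18]
    - [0.08, 0.00, 0.08, 0.10]
    - [0.12, 0.08, 0.00, 0.10]
    - [0.08, 0.08, 0.08, 0.00]

cti_beta:        # project CTI ~ Beta(shape1, shape2); mean ~ 0.525
  shape1: 3.1
  shape2: 2.8

engine:          # per-wheel engine power ~ LogNormal(log_mean, log_sd)
  log_mean: [0.0, 0.0, 0.0, 0.0]
  log_sd: [0.30, 0.30, 0.30, 0.30]

friction_env:    # per-wheel contextual friction ~ LogNormal
  log_mean: [0.0, 0.0, 0.0, 0.0]
  log_sd: [0.30, 0.30, 0.30, 0.30]

economics:
  innovation_intercept: [0.0, 0.0, 0.0, 0.0]
  innovation_slope: [10.0, 10.0, 10.0, 10.0]    # innovations per unit velocity
  revenue_base: [2000.0, 2000.0, 2000.0, 2000.0]
  revenue_velocity: [20000.0, 20000.0, 20000.0, 20000.0]
  revenue_innovation: [2000.0, 2000.0, 2000.0, 2000.0]
  cost_base: [5000.0, 5000.0, 5000.0, 5000.0]
  cost_velocity: [9000.0, 9000.0, 9000.0, 9000.0]
  pdca_practice_cost: 1000.0
  pdca_data_cost: 1000.0
  pdca_implementation_cost: 1000.0
  pdca_intensity: [1.0, 1.0, 1.0]

monte_carlo:
  n_iterations: 500
  n_projects: {mean: 25, sd: 3}   # rounded normal; use an int for a constant
  hyper_ranges:                   # uniform sampling ranges per iteration
    a: [6.0, 14.0]
    m0: [0.4, 0.6]
    r_max: [0.4, 0.7]
    eta: [1.5, 3.0]
    c: [0.35, 0.65]
  k_scale_range: [0.7, 1.3]       # stochastic scaling of the coupling matrix
  typology: {mode: median-split, teig_cut: 1.0, teib_cut: 0.8}
  norm: euclidean                 # TEI-G norm: euclidean | l1
  mission_weights: [0.25, 0.25, 0.25, 0.25]

seed: 20260101
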