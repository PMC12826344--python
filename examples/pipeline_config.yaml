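# Example pipeline configuration for `dmpacost pipeline --config ...`.
# Every section is optional; omitted sections use the calibrated study
# defaults. Unknown keys are rejected.
seed: 1

cohort:
  n_per_arm: [393, 299, 300]       # DMPA-IM, PA DMPA-SC, self-injection
  n_waves: 4
  cycle_days: 91
  # per-arm per-cycle probability of a method-status change
  hazard_change: [0.1388, 0.2595, 0.0871]
  # probability a change is a transition to self-injection, by arm
  p_transition_si: [0.3994, 0.5671, 0.0]
  retention_per_wave: 0.9713       # 0.89 annual retention ^ 1/4
  p_community: [0.0611, 0.0268, 0.32]
  change_split_other: 0.5          # non-SI changes: other method vs none
  units_per_si_visit: 2

engine:
  n0: 100000                       # simulated clients per cohort
  n_cycles: 4
  n_replicates: 1000               # Monte-Carlo cohorts
  failure_rate_annual: 0.0         # contraceptive failure exit (annual)
  beta_concentration: 300          # beta effective sample size (kappa)
  beta_fixed: false                # true = deterministic probabilities

breakeven:
  grid_step: 0.01
  locations: [facility, community]
  mode: visit                      # or: linear
  observed_si_share: 0.64          # routine-service SI visit share

# To override service costs, add an `inventory` section with subsections
# commodities / supplies / labour / infrastructure keyed by visit type
# (IM_inject, PASC_inject, SI_supervised, SI_resupply) and location
# (facility, community). Dump the calibrated defaults as a template with:
#   python -c "import dmpacost.costs as c; c.save_inventory(c.default_inventory(), 'inventory.yaml')"
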