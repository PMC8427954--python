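# Example configuration for the umsspd pipeline.
#
# model: ordinal sigmoid-Emax parameters (the published point estimates,
#   used as ground truth for synthetic studies).
# pk: SYNTHETIC pediatric-scale three-compartment + effect-site constants
#   for the simulator fixtures. These are plausible round numbers, not any
#   published pediatric propofol parameter set; supply your own values for
#   real model comparisons.
model:
  ce50: [1.84, 2.64, 3.98, 4.78]
  gamma: 5.76

pk:
  v1: 9.5      # L
  k10: 0.07    # 1/min
  k12: 0.11
  k21: 0.055
  k13: 0.042
  k31: 0.0033
  ke0: 0.8

protocol:
  targets: [1, 2, 3, 4, 5, 6]   # ug/mL effect-site staircase
  hold_after_reach: 120          # s at target before the next step
  eval_step: 20                  # s between sedation assessments
  ce_tolerance: 0.02             # ug/mL

fit:
  n_starts: 5
  seed: 0
  tol: 1.0e-8

seed: 20210909
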