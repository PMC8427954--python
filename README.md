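# umsspd

Ordinal sigmoid-Emax pharmacodynamics linking the effect-site concentration
(Ce) of propofol to the 5-level University of Michigan Sedation Scale
(UMSS) in children — with everything needed to run the full analysis
pipeline on self-generated data:

* **core_model** — threshold probabilities `P(UMSS >= n) = Ce^g / (Ce50_n^g + Ce^g)`
  with a shared Hill slope, exact-score probabilities (product formula),
  most-probable-score prediction, and the score-vs-Ce breakpoint table.
* **dataset_io** — NONMEM-style CSV readers/writers (`ID,TIME,CE,DV`),
  threshold expansion of ordinal scores into binary responses, infusion
  logs, YAML/JSON configuration, and the modeling-point selection rule
  (start of infusion, score increments, period midpoints, +20 s after
  score 4; at most 10 points per subject).
* **estimation** — naive-pooled maximum likelihood on the binary-expanded
  data (inter-individual variability fixed to zero), with cluster-robust
  Wald standard errors, RSE%, and 95% CIs.
* **validation** — subject-resampling bootstrap percentile intervals,
  prediction probability Pk = (Somers' d + 1)/2 with jackknife/bootstrap
  CIs, and percent-scale Bland-Altman agreement between concentration
  predictions.
* **simulation** — exact (matrix-exponential) three-compartment +
  effect-site PK replay of piecewise-constant infusions, an idealized
  effect-site TCI controller producing the 1-to-6 ug/mL staircase
  protocol, and a synthetic-study generator sampling UMSS scores every
  20 s from the fitted model.

## CLI

All commands live under a single `umsspd` entry point:

```sh
# synthetic 30-subject study from the example configuration
umsspd simulate --config examples/config.yaml --n 30 --seed 42 --out study.csv

# pooled-ML fit, bootstrap, and prediction-probability evaluation
umsspd fit --data study.csv --out fit.json
umsspd bootstrap --data study.csv --reps 1000 --seed 42 --out boot.json
umsspd evaluate-pk --data study.csv --fit fit.json --out pk.json

# most-probable-score table (0.1 ug/mL grid)
umsspd breakpoints --config examples/config.yaml --out breakpoints.json

# replay an infusion log through a PK model; compare two predictions
umsspd replay --infusion log.csv --pk examples/config.yaml --out conc.csv
umsspd compare --ref conc_a.csv --alt conc_b.csv --out agreement.json
```

The PK constants in `examples/config.yaml` are synthetic pediatric-scale
values for fixtures only; supply your own parameter sets for real model
comparisons.

## Notes on the generator

`generate_study` samples a subject's score at each assessment by comparing
one latent uniform draw against the four threshold probabilities, so each
threshold indicator has exactly its model marginal and pooled
binary-likelihood estimation is consistent. With the default
`selection="design"` the modeling-point selection rule is applied to the
deterministic expected score course of the shared TCI staircase, keeping
the observation plan independent of the sampled responses (an ignorable
design); `selection="subject"` applies the rule to each subject's own
sampled series, which mirrors data-adaptive point selection in a real
study but makes pooled estimates biased on resampled synthetic data (see
the docstring).
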