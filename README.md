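# physdens

Modelling regional differences in outpatient physician supply.

The package has two halves:

1. **Theory** (`physdens.theory`) — a two-region (urban/rural) economic
   model: a representative household with Cobb-Douglas preferences demands
   GP and specialist services, each visit carrying a money price and a
   time cost that falls with regional physician density
   (`t = (count/area)^-q`). Physicians allocate across regions until rural
   income equals a preference-weighted multiple `w >= 1` of urban income.
   Closed-form demands, a numeric utility-maximization oracle, an
   equilibrium solver (works for any coinsurance rate, matches the
   closed-form urban/rural ratios at zero coinsurance) and comparative
   statics for the model's hypotheses.

2. **Empirics** (`physdens.synth`, `physdens.ztnb`, `physdens.selection`,
   `physdens.effects`) — a district-level analysis pipeline:
   - `synth`: seeded synthetic district tables (412 districts, 17 regions
     by default) whose covariate distributions match published summary
     statistics, with GP/specialist counts simulated from the regression
     model itself so ground truth is known;
   - `ztnb`: from-scratch zero-truncated negative-binomial GLM with log
     link, population offset (log inhabitants per 10 000), region dummy
     intercepts, two-standard-deviation covariate scaling, Wald inference
     and BIC;
   - `selection`: three linked models (GP density, specialist density,
     GP/specialist ratio) with cross-model backward stepwise elimination —
     a term stays while significant at 0.05 in at least one model;
   - `effects`: back-transformation of coefficients into densities per
     10 000 inhabitants, two-SD density effects and net interaction
     effects, plus JSON/CSV/markdown report rendering.

## CLI

```sh
# two-region equilibrium, sweep the regional preference weight
physdens equilibrium --vary preference_weight --grid 1.0,1.1,1.2 --out sweep.csv

# synthetic district table with ground truth
physdens simulate --seed 1 --out table.csv --truth truth.json

# one model fit
physdens fit --table table.csv --model sp --out fit.json

# cross-model backward stepwise selection
physdens select --table table.csv --out selection.json --report report.csv

# back-transform a fit
physdens effects --fit fit.json --out effects.json

# full pipeline: simulate -> select -> effects -> report files
physdens report --seed 1 --out-dir report/
```

`--config` accepts a flat YAML file; generator keys mirror
`physdens.synth.GeneratorConfig`, and an optional `terms` list selects the
covariates/interactions entering the models (interactions written as
`metric:binary`, e.g. `population_density:city`).

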