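# twophase-audit

Optimal and multiwave **two-phase validation-study design** when a binary
outcome and a binary exposure are both (possibly differentially)
misclassified.

## The problem

Observational databases (EHR extracts, routinely collected cohort data)
record error-prone versions `Y*`, `X*` of a true binary outcome `Y` and
exposure `X`.  Validating (auditing) the whole database is too expensive, so
a *two-phase* study keeps the cheap Phase I variables on everyone and
validates the truth on a chosen subset of `n` subjects.  The scientific
target is the conditional log odds ratio `β` in

```
logit Pr(Y = 1 | X, Z) = β₀ + β X + βz' Z ,
```

estimated by maximum likelihood from the Phase I data plus the validated
subset, with logistic models for the differential misclassification
mechanisms `Pr(Y* | X*, Y, X, Z)` and `Pr(X* | Y, X, Z)` and for
`Pr(X | Z)`.  Which subjects should be validated?

This package implements the full design toolkit for that question:

- **MLE** of `θ = (β, η)` from a partially validated cohort via EM with
  Newton refinement of the observed-data log-likelihood, on collapsed
  contingency cells (cohort size does not affect fitting cost);
- **Design criterion**: the asymptotic variance
  `Var(β̂) = N⁻¹ {I(β,β) − I(β,η)' I(η,η)⁻¹ I(β,η)}⁻¹`, where the expected
  Fisher information is an affine function of the per-stratum sampling
  probabilities `π_{y*x*z} = n_{y*x*z} / N_{y*x*z}`;
- **optMLE**: an adaptive grid search over integer allocations
  `{n_{y*x*z}}` (budget `Σ n_s = n`, per-stratum minimum `m`) at
  iteratively finer step sizes, the "gold standard" design requiring known
  `θ`;
- **optMLE-2 / optMLE-3**: multiwave approximations that spend part of the
  budget on a balanced first wave, estimate `θ` from the accumulated data,
  and grid-search the remaining allocation;
- **Classical comparators**: simple random sampling (SRS), case–control on
  `Y*` (CC*), and balanced case–control on the `(Y*, X*, Z)` strata (BCC*);
- a **simulation harness** (percent bias, empirical SE, relative efficiency
  RE and relative IQR RI against the optMLE reference) and a CLI.

## Worked example

Plan a 200-record audit for a cohort with printed Phase I stratum counts,
then find the variance-minimizing allocation under known parameters:

```python
import numpy as np
from twophase_audit import (StratumTable, GridSchedule, allocate_bcc_star,
                            adaptive_grid_search, var_beta)
from twophase_audit.simulate import SimScenario, scenario_theta

counts = {(0, 0, 0): 504, (0, 1, 0): 1350, (1, 0, 0): 42, (1, 1, 0): 116}
strata = StratumTable.from_mapping(counts)

bcc = allocate_bcc_star(strata, 200)
print(dict(zip(strata.keys, bcc.alloc)))
# {(0, 0, 0): 53, (0, 1, 0): 53, (1, 0, 0): 42, (1, 1, 0): 52}
# -> the small (Y*=1, X*=0) stratum is taken in full, the rest split evenly

scenario = SimScenario()                 # p_x=0.1, p_y0=0.3, rates 0.1/0.9
theta = scenario_theta(scenario)
spec = scenario.model_spec()
strata10k = StratumTable.from_mapping(
    {(0, 0, 0): 5405, (0, 1, 0): 1085, (1, 0, 0): 2609, (1, 1, 0): 901})
opt, trace = adaptive_grid_search(theta, spec, strata10k, 400,
                                  GridSchedule(steps=(15, 5, 1), m=10))
print(opt.alloc, round(var_beta(theta, spec, opt), 5))
# [ 10 113  85 192] 0.03546
```

The optimal audit oversamples the rare strata (`Y*` or `X*` positive) and
takes only the minimum `m = 10` from the large double-negative stratum; its
criterion value 0.03546 corresponds to an asymptotic standard error of
about 0.19 for the log OR, versus 0.21 for the balanced design on the same
cohort (`var_beta(theta, spec, allocate_bcc_star(strata10k, 400))` →
0.04503).

A full simulated comparison (shared cohorts across designs):

```python
from twophase_audit.simulate import run_study, summarize
study = run_study(SimScenario(), ["optMLE", "optMLE-2", "BCC*", "SRS"],
                  reps=200, seed=1)
print(summarize(study, reference="optMLE")[["percent_bias", "se_empirical", "re"]])
```

RE below 1 means less efficient than the gold-standard optMLE; the
two-wave optMLE-2 typically lands near 1 while SRS loses most of the
budget's value.

The same operations are scriptable:

```bash
twophase-audit design bcc --strata strata.csv --n 200
twophase-audit study --scenario base.yaml --reps 200 --seed 1 --out results/
```

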