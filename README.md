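# statemerge

Choosing the state structure of a discrete-time Markov cost-effectiveness
model — should two similar disease severities be one state or two? — is
usually done informally, because merging states aggregates the transition
data and makes naive likelihood comparisons between structures invalid.

`statemerge` implements a constraint-based resolution: a model with merged
states is re-expressed as a model on the *split* state space in which, for
every exit state E_i reachable from the candidate group A_1, …, A_n, the
outward transition probabilities are constrained equal,

    P(A_1 → E_i) = P(A_2 → E_i) = ⋯ = P(A_n → E_i),   i = 1, …, m,

together with equal per-cycle costs c_{A_j} = c and utilities u_{A_j} = u.
Subject to these constraints the split model's likelihood is proportional to
the merged model's, and both give identical expected survival, lifetime
costs and QALYs — so the structural choice reduces to testing ordinary
parameter constraints on a *common* dataset. Candidate structures are then
compared by maximised likelihood and AIC = 2k − 2 log L, and the
decision-analytic consequences of the choice are propagated through
probabilistic sensitivity analysis (net benefit, CEAC) and value-of-
information measures (EVPI, EVPPI).

It is intended for health economists and biostatisticians building
state-transition cost-effectiveness models from transition-count data
(or from published risk summaries when individual data are unavailable).

## What is in the package

| module | contents |
| --- | --- |
| `statemerge.structures` | state spaces, merge proposals, derived constraint sets, encompassing-model construction for groups with different exit states |
| `statemerge.likelihood` | constrained multinomial MLE (closed form + numerical fallback), AIC comparison tables, per-destination assessment, back-derivation of event counts from published risks |
| `statemerge.outcomes` | gamma cost and upper-truncated-normal utility model comparisons, prevalence-weighted cost merging |
| `statemerge.cohort` | Markov cohort engine (discounting, half-cycle correction), merged-model construction, equivalence checking |
| `statemerge.voi` | PSA sampling (Dirichlet rows, log-normal costs, truncated-normal utilities), INB, CEAC, EVPI, EVPPI (regression and two-level estimators) |
| `statemerge.synthetic` | transition histories, cost/utility samples and AIC selection experiments from known ground truth |
| `statemerge.fixtures` | packaged examples: the CAD severity models, the published CECaT summaries and derived counts, the four-state depression structures |
| `statemerge.io` / `statemerge.cli` | CSV/YAML readers and writers, the `statemerge` command line |

## Worked example: are medium- and high-risk CAD one state or two?

The CECaT study published 1-year relative risks of death for medium- and
high-risk coronary artery disease. The implied event counts (126 deaths of
571 medium-risk patients; 259 of 754 high-risk) ship with the package:

```python
import statemerge as sm
from statemerge.fixtures import cecat_death_counts

table = cecat_death_counts()
pooled = sm.ConstraintSet(prob_constraints=[
    ("dead", ["medium", "high"]), ("alive", ["medium", "high"]),
])
print(sm.compare_structures(table, {"medium=high": pooled}).rendered())
```

```
   constraint  loglik  k  aic  delta_aic   verdict
unconstrained   -6.70  2 17.4        0.0 reference
  medium=high  -18.81  1 39.6       22.2     split
```

The unconstrained model (a separate death probability per risk group, k = 2)
has AIC 17.4; pooling the two probabilities (k = 1) raises it to 39.6. The
ΔAIC of +22.2 strongly favours keeping the states split — the two groups
really do die at different rates (22% vs 34% per year). Running the same
comparison on the non-fatal-MI counts (39/1717 vs 62/2159) gives ΔAIC −0.6:
a common MI risk is mildly preferred, so a *partially merged* structure
(separate death probabilities, shared MI risk) is defensible.

The same comparison from the shell:

```sh
statemerge fixtures --outdir fx
statemerge compare --counts fx/cecat_deaths.csv --model fx/cad_model.yaml
```

Structure choice can flip the decision. On the packaged two-strategy
example (treatment shifts patients towards the low-severity state at an
upfront cost):

```python
from statemerge.fixtures import structure_sensitivity_example
for name, r in structure_sensitivity_example().items():
    print(name, {s: round(v, 1) for s, v in r["nb"].items()}, "->", r["optimal"])
```

```
split            {'treat': 96261.4, 'no_treat': 73859.9} -> treat
partially_merged {'treat': 96261.4, 'no_treat': 73859.9} -> treat
merged           {'treat': 81020.5, 'no_treat': 84020.5} -> no_treat
```

Merging the severity states pools their very different costs and utilities,
erases the benefit of starting patients in the milder state, and reverses
the recommendation — while the partially merged structure (pooled
transitions, separate costs/utilities) preserves it.

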