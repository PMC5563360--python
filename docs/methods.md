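# Methods

## The model and the equivalence it rests on

A discrete-time state-transition (Markov) cohort model is specified by an
ordered state space, a row-stochastic per-cycle transition matrix P, a
per-cycle cost c_X and utility u_X for each state X, and a cycle length in
years. The cohort distribution evolves as v_{t+1} = v_t P; expected costs
and QALYs accumulate over the horizon with optional annual discounting and
half-cycle (trapezoidal) correction.

Merging a group of states A_1, …, A_n whose possible destinations outside
the group ("exit states" E_1, …, E_m) coincide is equivalent to keeping the
split space and imposing

- P(A_j → E_i) equal across j for every exit i,
- c_{A_j} equal across j, and u_{A_j} equal across j.

Under these constraints the split model's multinomial likelihood is
proportional to the merged model's (the within-group transition terms factor
out), and the two models produce identical aggregated occupancy, expected
costs and QALYs for any initial distribution and horizon — including
"reversible" models with transitions among the A_j and models with inbound
transitions into the group. `cohort.check_equivalence` verifies this
numerically; a derandomised property test and a 1000-model sweep hold it to
1e-10 (absolute for occupancy, relative for cost/QALY totals, whose currency
scale puts absolute float64 accumulation error well above 1e-10 over 50
cycles).

Only *outbound* probabilities, costs and utilities are constrained; inbound
probabilities into the group are free and are simply summed when the merged
model is constructed. Transitions among group members are never constrained.

When the candidate states do **not** share exits there is no parameter
choice making the small model equal the merged one. Both are instead
expressed as constrained versions of an *encompassing* model in which every
member has every exit seen in the group: forcing the added transitions to
zero recovers the original model, equating outward probabilities recovers
the merged one, and the two constrained fits can be compared by AIC against
the common encompassing fit (`structures.extend_for_unshared_exits`).

## Likelihood, constrained MLE, and AIC

Transition data are origin-wise multinomial counts x_{ji} with row totals
n_j. Log-likelihoods **include** the multinomial normalising coefficient, so
absolute AICs — not only differences — are meaningful; 0·log 0 is taken as 0
and boundary MLEs are accepted.

For constraints induced by disjoint merge groups the constrained MLE has a
closed form, derived by Lagrange multipliers: the shared probability of
destination i over origin group G is the pooled proportion
q̂_i = Σ_{j∈G} x_{ji} / Σ_{j∈G} n_j, and the remaining cells of each
constrained row are the unconstrained conditional proportions rescaled to
the residual mass 1 − Σ_i q̂_i. Structural zeros fix cells to 0 (the
observed count there must be 0). Constraint patterns outside this structure
(origin sets that overlap without coinciding) are handled by a numerical
maximiser (trust-region constrained optimisation over tied cell variables
with linear row-sum constraints). The closed form is validated against an
independent profile-likelihood oracle to 1e-8 in log-likelihood.

The free-parameter count k is the number of distinct probability values
minus the rank of the row-sum constraint system. This reduces to the usual
tally — m − 1 per row, minus g − 1 per equality, minus 1 per zero — whenever
each constrained row retains a free destination, but it also handles the
degenerate case where shared values cover an entire row (pooling a binomial
pair leaves exactly one free parameter, the pooled probability), which is
what the published binomial AIC comparisons require.

Comparisons report AIC = 2k − 2 log L and ΔAIC = AIC(constrained) −
AIC(unconstrained): positive favours separate parameters (split), negative
favours the constraint (merge), and ties resolve to the more parsimonious
(merged) model. Rendered tables round AIC to 1 decimal place; machine output
keeps full precision. The per-destination table assesses one destination at
a time with all other destinations profiled free; these per-destination
ΔAICs are an interpretable decomposition but are *not* exactly additive when
several constraints share rows (row normalisation couples destinations);
additivity is exact across constraints on disjoint origin groups, where the
likelihood factorises by row.

When only published summaries are available, `derive_counts` back-derives
integer (events, denominator) pairs: the 95% CI width is moment-matched on
the log scale, se(log risk) = (log hi − log lo)/(2·1.96), the denominator is
solved from the delta-method binomial variance (1 − p)/(np), and a
round-trip diagnostic reports how closely the recomputed CI matches the
input. The packaged CECaT counts are shipped as fixtures rather than
regenerated, since the original back-calculation procedure is not fully
specified by its published description.

## Cost and utility comparisons

Whether candidate-merge states share a cost (utility) parameter is assessed
on individual-level samples with the same AIC contract. Costs use a gamma
model with log link and a shape parameter shared across groups — the
standard GLM family for right-skewed healthcare costs; with a group factor
the fitted means are the group sample means and the shape is profiled by
solving log a − digamma(a) = mean(log μ − log y). Utilities use a normal
truncated above at 1 by default (utilities cannot exceed full health; the
bound is configurable, and +∞ recovers the plain normal), with per-group
means and a shared scale fitted numerically. In both families the common-
mean model has k = 2 and the separate-means model k = G + 1, so identical
groups give ΔAIC → −2 and a fixed mean difference drives ΔAIC → +∞ with n.

Merged-state costs and utilities are prevalence-weighted means of the
members' values; weights are normalised, so any rescaling is immaterial.

## PSA and value of information

PSA draws transition rows from Dirichlet distributions (parameterised by
observed counts plus a uniform prior by default — the conjugate, standard
choice), state costs from log-normals, and state utilities from upper-
truncated normals; each draw is pushed through the cohort engine per
strategy and NB = wtp·QALY − cost is recorded. All sampling takes an
explicit seed and is bit-reproducible. A Dirichlet row may be *shared* by
the origins of a merge group (exit probabilities drawn once, within-group
mass split in template proportions), which makes the PSA of a constrained
split model match the merged model's draw for draw under the same seed —
the equivalence extends to decision uncertainty.

From the draw × strategy NB matrix: INB is the mean and central 95% interval
of NB differences against a reference; P(CE) is the fraction of draws in
which each strategy attains the maximum NB (ties split equally), with the
CEAC tracing this over a willingness-to-pay grid; per-decision
EVPI = E[max_k NB_k] − max_k E[NB_k] ≥ 0, scaled to a population by an
explicit (size, horizon, discount) configuration — no population defaults
are assumed.

EVPPI uses a regression estimator by default: each strategy's NB is smoothed
on the parameter subset (a cubic regression spline with quantile knots in
one dimension; quadratic least squares for multi-parameter subsets) and
EVPPI = mean(max_k fit_k) − max_k mean(NB_k), clipped at 0. This estimator
carries a small positive bias of order the smoother's noise (visible as a
few percent of EVPI for irrelevant parameters). A two-level nested Monte
Carlo estimator is provided for validation; because priors are independent,
conditioning on a subset simply fixes those entries while the complement is
redrawn. It is accurate but costs n_outer × n_inner model evaluations.

## Synthetic data

The generator simulates independent subjects, one observed transition per
subject-cycle, no censoring — the complete-observation count-data form the
likelihood assumes. It emulates multinomial transition histories from a true
matrix, gamma costs (mean/shape) and upper-truncated-normal utilities.
It does not emulate features of real transition data such as interval
censoring, dropout, covariate heterogeneity or measurement error in state
assignment, so passing tests demonstrate correctness of the estimators under
the stated sampling model, not robustness to those complications.

Selection experiments repeat simulate-and-compare to estimate how often AIC
chooses the merge. When one equality truly holds, the ΔAIC is −2 plus a
χ²₁ likelihood-ratio statistic, so the split model is still chosen with
probability P(χ²₁ > 2) ≈ 15.7% asymptotically — the familiar AIC selection
error; a gross violation (0.1 vs 0.4 with 500 observations per row) drives
the merge rate to essentially zero. Both behaviours are asserted at
simulation sizes (1000 and 300 replicates; ~2000 and ~500 subjects per row)
chosen to keep Monte-Carlo error a small fraction of the effects tested.

## Numerical and design choices

- State labels are strings; the order in `StateSpace` fixes matrix row and
  column order everywhere. Self-transitions are ordinary destinations.
- Merge groups may not overlap; nested proposals are separate candidates.
- Discounting defaults to 0 (no rate is silently injected); the per-cycle
  factor is (1 + annual rate)^(−cycle_length). Half-cycle correction is off
  by default. Both are flags.
- Prevalence weights for merged costs/utilities default to the initial
  distribution restricted to the group (uniform if it places no mass there).
- `merge_model` checks the outward-equality constraints to 1e-9 and refuses
  to pool silently; `force=True` pools by prevalence weighting, which is the
  operation an analyst adopting the coarser structure performs.
- Equivalence tolerance 1e-10 on each outcome's natural scale (see above).
- Degenerate inputs: rows with a single destination contribute log L = 0 and
  k = 0; zero counts sit on the boundary; a constrained row left with free
  cells but no free observations receives a uniform allocation of the
  residual mass (the likelihood is flat there).
- The two-strategy structure-sensitivity example uses a 10-cycle annual
  horizon, £20,000 per QALY, a £3,000 upfront treatment cost, and severity
  costs/utilities (£200, 0.85) vs (£2,000, 0.55) — values in the range of
  chronic-disease severity models, chosen so that neither decision is
  knife-edge.

## Known limitations

- Transitions only: panel/interval-censored likelihoods, continuous-time
  multi-state models, semi-Markov/tunnel states and time-varying matrices
  are out of scope.
- The per-destination AIC decomposition profiles the other destinations;
  alternative conditional decompositions would give different cell values.
- Bayesian structure comparison (DIC, posterior model weights) is not
  implemented.
- `derive_counts` assumes the published CI is approximately symmetric on the
  log scale and that the baseline risk carries no uncertainty.
- The regression EVPPI estimator's positive bias means very small EVPPI
  values should be confirmed with the two-level estimator.
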