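"""Probabilistic sensitivity analysis and value-of-information measures.

Parameter uncertainty is propagated by sampling transition rows from
Dirichlet distributions (conjugate to the multinomial counts), state costs
from log-normals, and state utilities from upper-truncated normals, running
the cohort engine per strategy and draw, and recording net monetary benefit
NB = wtp · QALYs - costs.  From the draw × strategy NB matrix derive the
incremental net benefit (INB), the probability each strategy is
cost-effective (and the CEAC over a willingness-to-pay grid), the expected
value of perfect information (EVPI), and the expected value of partial
perfect information (EVPPI) for parameter subsets.

A Dirichlet prior can be shared by several origins of a merge group: the
exit probabilities are then drawn once for the whole group, which makes the
PSA of a constrained split model match the merged model's draw for draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm as _truncnorm

from .cohort import TransitionModel, cohort_trace, expected_outcomes

__all__ = [
    "TransitionPrior",
    "CostPrior",
    "UtilityPrior",
    "PSASpec",
    "PSAResults",
    "sample_psa",
    "inb",
    "prob_ce",
    "ceac",
    "evpi",
    "evppi",
    "evppi_two_level",
    "population_scale",
]


@dataclass(frozen=True)
class TransitionPrior:
    """Dirichlet prior on a transition row (or a shared row of a merge group).

    With a single origin, ``alpha`` maps every destination of that row to its
    Dirichlet parameter.  With several origins, ``alpha`` maps the *exit*
    destinations (outside the group) plus the pseudo-destination ``"<stay>"``
    for the within-group mass; one draw is shared by all origins and the stay
    mass is split among within-group destinations in each origin's template
    proportions.
    """

    origins: tuple[str, ...]
    alpha: Mapping[str, float]
    name: str = ""

    def __init__(self, origins: str | Sequence[str], alpha: Mapping[str, float], name: str = ""):
        origins = (origins,) if isinstance(origins, str) else tuple(origins)
        if not origins:
            raise ValueError("transition prior needs >=1 origin")
        if any(a <= 0 for a in alpha.values()):
            raise ValueError("Dirichlet parameters must be > 0")
        object.__setattr__(self, "origins", origins)
        object.__setattr__(self, "alpha", dict(alpha))
        object.__setattr__(self, "name", name or f"P[{'/'.join(origins)}]")


@dataclass(frozen=True)
class CostPrior:
    """Log-normal prior on a state's per-cycle cost (mean/sd on the log scale)."""

    state: str
    meanlog: float
    sdlog: float
    name: str = ""

    def __post_init__(self):
        if self.sdlog < 0:
            raise ValueError("sdlog must be >= 0")
        if not self.name:
            object.__setattr__(self, "name", f"cost[{self.state}]")


@dataclass(frozen=True)
class UtilityPrior:
    """Normal prior truncated above at ``upper`` on a state's utility."""

    state: str
    mean: float
    sd: float
    upper: float = 1.0
    name: str = ""

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not self.name:
            object.__setattr__(self, "name", f"utility[{self.state}]")


@dataclass
class PSASpec:
    """Everything needed to run a reproducible PSA.

    ``init`` is the cohort's starting distribution (may be overridden per
    strategy via ``init_by_strategy``), ``wtp`` the willingness to pay per
    QALY, and the population block scales per-decision EVPI to a population.
    """

    transition_priors: Sequence[TransitionPrior] = ()
    cost_priors: Sequence[CostPrior] = ()
    utility_priors: Sequence[UtilityPrior] = ()
    n_draws: int = 1000
    seed: int = 0
    wtp: float = 20000.0
    init: Mapping[str, float] | None = None
    init_by_strategy: Mapping[str, Mapping[str, float]] | None = None
    n_cycles: int = 10
    discount_rate: float = 0.0
    half_cycle: bool = False
    extra_cost: Mapping[str, float] | None = None  # one-off cost per strategy
    population_size: float | None = None
    decision_horizon_years: float | None = None
    population_discount: float = 0.035

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.wtp < 0:
            raise ValueError("wtp must be >= 0")


@dataclass
class PSAResults:
    """Per-draw costs, QALYs and net benefits per strategy, plus parameter draws."""

    strategies: tuple[str, ...]
    costs: np.ndarray  # (n_draws, n_strategies)
    qalys: np.ndarray
    nb: np.ndarray
    wtp: float
    param_draws: pd.DataFrame  # one column per scalar parameter

    @property
    def n_draws(self) -> int:
        return self.nb.shape[0]

    def column(self, strategy: str) -> int:
        try:
            return self.strategies.index(strategy)
        except ValueError:
            raise KeyError(f"unknown strategy {strategy!r}") from None


def _sample_params(spec: PSASpec, rng: np.random.Generator) -> dict[str, float]:
    """One joint draw of all scalar parameters, keyed by stable names."""
    out: dict[str, float] = {}
    for tp in spec.transition_priors:
        labels = list(tp.alpha)
        draw = rng.dirichlet([tp.alpha[l] for l in labels])
        for l, v in zip(labels, draw):
            out[f"{tp.name}:{l}"] = float(v)
    for cp in spec.cost_priors:
        out[cp.name] = float(rng.lognormal(cp.meanlog, cp.sdlog)) if cp.sdlog > 0 else math.exp(cp.meanlog)
    for up in spec.utility_priors:
        if up.sd > 0:
            b = (up.upper - up.mean) / up.sd
            u = _truncnorm.ppf(rng.uniform(), -np.inf, b, loc=up.mean, scale=up.sd)
            out[up.name] = float(u)
        else:
            out[up.name] = up.mean
    return out


def _apply_params(
    model: TransitionModel, spec: PSASpec, params: Mapping[str, float]
) -> TransitionModel:
    """Patch a strategy template with one parameter draw."""
    P = model.P.copy()
    cost = model.cost.copy()
    util = model.utility.copy()
    sp = model.space
    for tp in spec.transition_priors:
        origins = [o for o in tp.origins if o in sp.states]
        if not origins:
            continue
        if len(tp.origins) == 1:
            o = origins[0]
            i = sp.index(o)
            row = np.zeros(len(sp))
            for d in tp.alpha:
                row[sp.index(d)] = params[f"{tp.name}:{d}"]
            P[i] = row
        else:
            group = set(tp.origins)
            exits = [d for d in tp.alpha if d != "<stay>"]
            stay = params.get(f"{tp.name}:<stay>", 1.0 - sum(
                params[f"{tp.name}:{d}"] for d in exits))
            for o in origins:
                i = sp.index(o)
                template_stay = np.array(
                    [P[i, sp.index(m)] if m in sp.states else 0.0 for m in sorted(group)]
                )
                tot = template_stay.sum()
                w = template_stay / tot if tot > 0 else np.full(len(template_stay), 1 / len(template_stay))
                newrow = np.zeros(len(sp))
                for m, wm in zip(sorted(group), w):
                    if m in sp.states:
                        newrow[sp.index(m)] = stay * wm
                for d in exits:
                    newrow[sp.index(d)] = params[f"{tp.name}:{d}"]
                P[i] = newrow
    for cp in spec.cost_priors:
        if cp.state in sp.states:
            cost[sp.index(cp.state)] = params[cp.name]
    for up in spec.utility_priors:
        if up.state in sp.states:
            util[sp.index(up.state)] = params[up.name]
    return TransitionModel(sp, P, cost, util, cycle_length=model.cycle_length)


def _evaluate(
    models: Mapping[str, TransitionModel], spec: PSASpec, params: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (cost, qaly) per strategy at one parameter draw."""
    costs = np.empty(len(models))
    qalys = np.empty(len(models))
    for k, (name, template) in enumerate(models.items()):
        m = _apply_params(template, spec, params)
        init = (
            spec.init_by_strategy.get(name, spec.init)
            if spec.init_by_strategy
            else spec.init
        )
        if init is None:
            raise ValueError("PSASpec.init (or init_by_strategy) is required")
        tr = cohort_trace(m, init, spec.n_cycles)
        c, q = expected_outcomes(tr, m, spec.discount_rate, spec.half_cycle)
        if spec.extra_cost:
            c += float(spec.extra_cost.get(name, 0.0))
        costs[k] = c
        qalys[k] = q
    return costs, qalys


def sample_psa(
    models: Mapping[str, TransitionModel], spec: PSASpec
) -> PSAResults:
    """Run the PSA loop: sample parameters, run the cohort engine, record NB.

    Reproducible: the same seed yields a bit-identical NB matrix.
    """
    names = tuple(models)
    if not names:
        raise ValueError("no strategies supplied")
    rng = np.random.default_rng(spec.seed)
    costs = np.empty((spec.n_draws, len(names)))
    qalys = np.empty((spec.n_draws, len(names)))
    records = []
    for d in range(spec.n_draws):
        params = _sample_params(spec, rng)
        records.append(params)
        costs[d], qalys[d] = _evaluate(models, spec, params)
    nb = spec.wtp * qalys - costs
    return PSAResults(
        strategies=names,
        costs=costs,
        qalys=qalys,
        nb=nb,
        wtp=spec.wtp,
        param_draws=pd.DataFrame.from_records(records),
    )


def inb(results: PSAResults, reference: str) -> pd.DataFrame:
    """Mean and central 95% interval of NB(strategy) - NB(reference) per draw."""
    j = results.column(reference)
    diff = results.nb - results.nb[:, [j]]
    lo, hi = np.percentile(diff, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "strategy": results.strategies,
            "inb_mean": diff.mean(axis=0),
            "inb_lo": lo,
            "inb_hi": hi,
        }
    )


def prob_ce(results: PSAResults) -> pd.Series:
    """Probability each strategy attains the highest NB; ties split equally."""
    if len(results.strategies) < 2:
        raise ValueError("need >=2 strategies")
    nb = results.nb
    best = nb.max(axis=1, keepdims=True)
    is_best = nb == best
    share = is_best / is_best.sum(axis=1, keepdims=True)
    return pd.Series(share.mean(axis=0), index=list(results.strategies), name="p_ce")


def ceac(results: PSAResults, wtps: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid."""
    rows = []
    for w in wtps:
        nb = w * results.qalys - results.costs
        best = nb.max(axis=1, keepdims=True)
        is_best = nb == best
        share = (is_best / is_best.sum(axis=1, keepdims=True)).mean(axis=0)
        for s, p in zip(results.strategies, share):
            rows.append({"wtp": w, "strategy": s, "p_ce": p})
    return pd.DataFrame(rows)


def evpi(results: PSAResults) -> float:
    """Per-decision EVPI = E[max_k NB_k] - max_k E[NB_k] >= 0."""
    nb = results.nb
    return float(nb.max(axis=1).mean() - nb.mean(axis=0).max())


def population_scale(
    per_decision: float,
    population_size: float,
    decision_horizon_years: float,
    discount_rate: float = 0.035,
) -> float:
    """Scale a per-decision value to the discounted affected population.

    Assumes ``population_size`` new decisions per year over the horizon,
    discounted annually (year 0 undiscounted).
    """
    years = np.arange(int(round(decision_horizon_years)))
    weights = (1.0 + discount_rate) ** (-years)
    return float(per_decision * population_size * weights.sum())


def _smooth_fit(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fitted conditional mean of y given x (columns = parameters)."""
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] == 1:
        from scipy.interpolate import BSpline

        xs = x[:, 0]
        xu = np.unique(xs)
        if xu.size < 5:
            # nearly discrete parameter: group means
            means = {v: y[xs == v].mean() for v in xu}
            return np.array([means[v] for v in xs])
        # cubic regression spline with interior knots at quantiles
        n_interior = int(np.clip(len(y) // 200, 3, 20))
        interior = np.unique(np.quantile(xs, np.linspace(0, 1, n_interior + 2)[1:-1]))
        lo, hi = xs.min(), xs.max()
        t = np.r_[[lo] * 4, interior, [hi] * 4]
        X = BSpline.design_matrix(np.clip(xs, lo, hi), t, 3).toarray()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return X @ beta
    # multi-parameter subset: quadratic polynomial least squares
    cols = [np.ones(len(y))]
    for j in range(x.shape[1]):
        cols.append(x[:, j])
    for j in range(x.shape[1]):
        for l in range(j, x.shape[1]):
            cols.append(x[:, j] * x[:, l])
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return X @ beta


def evppi(
    results: PSAResults, subset: Sequence[str], method: str = "regression"
) -> float:
    """EVPPI of a parameter subset from stored PSA draws.

    The regression estimator fits a smooth of each strategy's NB on the
    subset (spline in one dimension, quadratic least squares otherwise); the
    fitted values estimate the conditional expected NB given the subset, and
    EVPPI = mean(max_k fit_k) - max_k mean(NB_k).
    """
    if method != "regression":
        raise ValueError("use evppi_two_level for the nested Monte Carlo estimator")
    cols = list(subset)
    missing = [c for c in cols if c not in results.param_draws.columns]
    if missing:
        raise KeyError(f"unknown parameter names {missing}")
    x = results.param_draws[cols].to_numpy()
    fitted = np.column_stack(
        [_smooth_fit(x, results.nb[:, k]) for k in range(len(results.strategies))]
    )
    val = float(fitted.max(axis=1).mean() - results.nb.mean(axis=0).max())
    return max(0.0, val)


def evppi_two_level(
    models: Mapping[str, TransitionModel],
    spec: PSASpec,
    subset: Sequence[str],
    n_outer: int = 100,
    n_inner: int = 100,
    seed: int | None = None,
) -> float:
    """Nested Monte Carlo EVPPI: outer draws of the subset, inner draws of the rest.

    Priors are independent, so conditioning on the subset just fixes those
    entries while the complement is redrawn.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    subset = set(subset)
    probe = _sample_params(spec, np.random.default_rng(0))
    unknown = subset - set(probe)
    if unknown:
        raise KeyError(f"unknown parameter names {sorted(unknown)}")
    nbars = []
    overall = np.zeros(len(models))
    for _ in range(n_outer):
        outer = _sample_params(spec, rng)
        inner_nb = np.zeros(len(models))
        for _ in range(n_inner):
            params = _sample_params(spec, rng)
            params.update({k: outer[k] for k in subset})
            c, q = _evaluate(models, spec, params)
            inner_nb += spec.wtp * q - c
        inner_nb /= n_inner
        nbars.append(inner_nb.max())
        overall += inner_nb
    overall /= n_outer
    return max(0.0, float(np.mean(nbars) - overall.max()))
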