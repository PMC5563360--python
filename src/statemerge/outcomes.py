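"""Comparing state-specific cost and utility parameters from individual data.

Whether two candidate-merge states share a cost (or utility) parameter is
assessed exactly like the transition constraints: fit a model with a common
mean and one with group-specific means to the individual-level samples by
maximum likelihood, and compare AICs.  Costs are modelled as gamma with a
log link and a shape parameter shared across groups — the standard GLM family
for right-skewed healthcare costs; utilities as normal truncated above (at 1
by default, full health) with a shared scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import digamma, gammaln
from scipy.stats import norm

from .likelihood import ComparisonTable, aic

__all__ = [
    "OutcomeSamples",
    "fit_cost_models",
    "fit_utility_models",
    "merge_costs",
    "gamma_loglik",
    "truncnorm_loglik",
]


@dataclass(frozen=True)
class OutcomeSamples:
    """Individual-level outcome values labelled by the state they belong to."""

    frame: pd.DataFrame  # columns: group, value

    def __init__(self, values: Iterable[tuple[str, float]] | pd.DataFrame):
        if isinstance(values, pd.DataFrame):
            if not {"group", "value"}.issubset(values.columns):
                raise ValueError("samples frame needs columns 'group' and 'value'")
            frame = values[["group", "value"]].copy()
        else:
            frame = pd.DataFrame(list(values), columns=["group", "value"])
        if frame.empty:
            raise ValueError("no outcome samples")
        frame["group"] = frame["group"].astype(str)
        frame["value"] = frame["value"].astype(float)
        object.__setattr__(self, "frame", frame.reset_index(drop=True))

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.frame["group"]))

    def values_for(self, group: str) -> np.ndarray:
        vals = self.frame.loc[self.frame["group"] == group, "value"].to_numpy()
        if vals.size == 0:
            raise KeyError(f"no samples for group {group!r}")
        return vals


def gamma_loglik(y: np.ndarray, mean: np.ndarray | float, shape: float) -> float:
    """Gamma log-likelihood in mean/shape parameterisation (rate = shape/mean)."""
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(np.asarray(mean, dtype=float), y.shape)
    a = shape
    return float(
        np.sum(a * np.log(a / mu) - gammaln(a) + (a - 1) * np.log(y) - a * y / mu)
    )


def _profile_gamma_shape(y: np.ndarray, mu: np.ndarray) -> float:
    """MLE of the shared shape given fitted (group-mean) means.

    With means at the group sample means, the score reduces to
    log a - digamma(a) = mean(log mu - log y).
    """
    s = float(np.mean(np.log(mu) - np.log(y) + y / mu - 1.0))
    if s <= 0:
        raise ValueError("zero within-group variability: gamma shape unbounded")
    f = lambda a: math.log(a) - digamma(a) - s
    lo, hi = 1e-8, 1.0
    while f(hi) > 0:
        hi *= 10.0
        if hi > 1e12:
            break
    return brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)


def fit_cost_models(samples: OutcomeSamples) -> ComparisonTable:
    """Common-mean vs group-mean gamma cost models, compared by AIC.

    Both models share one shape parameter; group means enter through a log
    link, so the group-specific model's fitted means are the group sample
    means.  ΔAIC = AIC(common) - AIC(separate): negative supports merging the
    states' costs, positive supports keeping them separate.
    """
    groups = samples.groups
    if len(groups) < 2:
        raise ValueError("need >=2 groups to compare cost models")
    y_all = samples.frame["value"].to_numpy()
    if np.any(y_all <= 0):
        raise ValueError("costs must be strictly positive for a gamma model")
    for g in groups:
        if samples.values_for(g).size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    # separate means, shared shape
    mu_sep = np.empty_like(y_all)
    for g in groups:
        mask = (samples.frame["group"] == g).to_numpy()
        mu_sep[mask] = y_all[mask].mean()
    a_sep = _profile_gamma_shape(y_all, mu_sep)
    ll_sep = gamma_loglik(y_all, mu_sep, a_sep)
    k_sep = len(groups) + 1

    mu_com = np.full_like(y_all, y_all.mean())
    a_com = _profile_gamma_shape(y_all, mu_com)
    ll_com = gamma_loglik(y_all, mu_com, a_com)
    k_com = 2

    return _two_model_table("costs equal", ll_com, k_com, ll_sep, k_sep)


def truncnorm_loglik(
    y: np.ndarray, mean: np.ndarray | float, sd: float, upper: float
) -> float:
    """Log-likelihood of a normal truncated above at ``upper`` (no lower bound)."""
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(np.asarray(mean, dtype=float), y.shape)
    if sd <= 0:
        return -math.inf
    if np.any(y > upper):
        return -math.inf
    ll = norm.logpdf(y, loc=mu, scale=sd)
    if math.isfinite(upper):
        ll = ll - norm.logcdf((upper - mu) / sd)
    return float(np.sum(ll))


def _fit_truncnorm(
    y_groups: list[np.ndarray], upper: float
) -> tuple[float, np.ndarray, float]:
    """ML fit of per-group means with shared scale; returns (loglik, means, sd)."""
    all_y = np.concatenate(y_groups)
    sd0 = all_y.std(ddof=0)
    if sd0 <= 0:
        raise ValueError("zero variance in utility samples")
    mu0 = np.array([g.mean() for g in y_groups])

    def negll(theta):
        means, log_sd = theta[:-1], theta[-1]
        sd = math.exp(log_sd)
        return -sum(
            truncnorm_loglik(g, m, sd, upper) for g, m in zip(y_groups, means)
        )

    x0 = np.append(mu0, math.log(sd0))
    res = minimize(negll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    res = minimize(negll, res.x, method="BFGS", options={"gtol": 1e-10})
    means, sd = res.x[:-1], math.exp(res.x[-1])
    return -float(res.fun), means, sd


def fit_utility_models(
    samples: OutcomeSamples, upper_bound: float = 1.0
) -> ComparisonTable:
    """Common-mean vs group-mean upper-truncated-normal utility models.

    The truncation bound defaults to 1 (utilities cannot exceed full health);
    pass ``math.inf`` for an untruncated normal comparison.  Scale is shared
    across groups.  Same ΔAIC convention as :func:`fit_cost_models`.
    """
    groups = samples.groups
    if len(groups) < 2:
        raise ValueError("need >=2 groups to compare utility models")
    y_all = samples.frame["value"].to_numpy()
    if np.any(y_all > upper_bound):
        raise ValueError("utility values above the truncation bound")
    y_groups = [samples.values_for(g) for g in groups]

    ll_sep, _, _ = _fit_truncnorm(y_groups, upper_bound)
    k_sep = len(groups) + 1
    ll_com, _, _ = _fit_truncnorm([y_all], upper_bound)
    k_com = 2
    return _two_model_table("utilities equal", ll_com, k_com, ll_sep, k_sep)


def _two_model_table(
    label: str, ll_com: float, k_com: int, ll_sep: float, k_sep: int
) -> ComparisonTable:
    delta = aic(ll_com, k_com) - aic(ll_sep, k_sep)
    rows = pd.DataFrame.from_records(
        [
            {
                "constraint": "separate means",
                "loglik": ll_sep,
                "k": k_sep,
                "aic": aic(ll_sep, k_sep),
                "delta_aic": 0.0,
                "verdict": "reference",
            },
            {
                "constraint": label,
                "loglik": ll_com,
                "k": k_com,
                "aic": aic(ll_com, k_com),
                "delta_aic": delta,
                "verdict": "merge" if delta <= 0 else "split",
            },
        ]
    )
    return ComparisonTable(rows)


def merge_costs(
    costs: Mapping[str, float], prevalence: Mapping[str, float]
) -> float:
    """Prevalence-weighted mean cost for a merged state.

    Weights are normalised, so any rescaling of the prevalence vector leaves
    the result unchanged.
    """
    missing = set(costs) - set(prevalence)
    if missing:
        raise ValueError(f"no prevalence weight for states {sorted(missing)}")
    w = np.array([float(prevalence[s]) for s in costs])
    if np.any(w < 0):
        raise ValueError("prevalence weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("prevalence weights must not all be zero")
    c = np.array([float(costs[s]) for s in costs])
    return float(np.dot(w, c) / total)
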