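"""Constrained maximum-likelihood estimation of transition probabilities.

Transition data are multinomial: for each origin state j, counts x_{ji} of
individuals observed moving to destination i out of n_j at risk.  A merge
proposal translates into equality constraints on the outward probabilities,
and candidate structures are compared by maximised log-likelihood and AIC
(2k - 2 logL, lower is better).  Log-likelihoods include the multinomial
normalising coefficient, so absolute AICs — not only differences — are
comparable across reports.

The constrained MLE has a closed form when, as for disjoint merge groups,
all constraints touching an origin share the same origin set: the common
probability of a constrained destination is the pooled proportion across the
group, and the remaining probabilities in each row are the unconstrained
conditional proportions rescaled to the residual mass.  Arbitrary constraint
patterns fall back to a numerical maximiser.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint, minimize
from scipy.special import gammaln

from .structures import ConstraintSet, MergeSpec, count_free_parameters

__all__ = [
    "TransitionCountTable",
    "FitResult",
    "ComparisonTable",
    "PublishedRiskSummary",
    "row_mle",
    "constrained_mle",
    "aic",
    "compare_structures",
    "per_destination_table",
    "derive_counts",
]


@dataclass(frozen=True)
class TransitionCountTable:
    """Observed origin -> destination transition counts with row totals."""

    counts: Mapping[tuple[str, str], int]

    def __init__(self, counts: Mapping[tuple[str, str], int]):
        clean: dict[tuple[str, str], int] = {}
        for (o, d), x in counts.items():
            xi = int(x)
            if xi != x or xi < 0:
                raise ValueError(f"count for ({o!r}, {d!r}) must be a non-negative integer")
            clean[(str(o), str(d))] = xi
        object.__setattr__(self, "counts", clean)

    @property
    def origins(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for o, _ in self.counts:
            seen.setdefault(o)
        return tuple(seen)

    def destinations(self, origin: str) -> tuple[str, ...]:
        ds = tuple(d for (o, d) in self.counts if o == origin)
        if not ds:
            raise KeyError(f"no rows for origin {origin!r}")
        return ds

    def row_total(self, origin: str) -> int:
        return sum(x for (o, _), x in self.counts.items() if o == origin)

    def row_destinations(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {}
        for o, d in self.counts:
            out.setdefault(o, []).append(d)
        return {o: tuple(ds) for o, ds in out.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(o, d, x) for (o, d), x in self.counts.items()],
            columns=["from", "to", "count"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TransitionCountTable":
        """Build from a long-format frame with columns from,to,count.

        Duplicate (from, to) rows are summed.
        """
        required = {"from", "to", "count"}
        if not required.issubset(frame.columns):
            raise ValueError(f"count table needs columns {sorted(required)}")
        grouped = frame.groupby(["from", "to"], sort=False)["count"].sum()
        return cls({(str(o), str(d)): int(x) for (o, d), x in grouped.items()})

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int]]
    ) -> "TransitionCountTable":
        counts: dict[tuple[str, str], int] = {}
        for o, d, x in records:
            counts[(o, d)] = counts.get((o, d), 0) + int(x)
        return cls(counts)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class FitResult:
    """A maximised fit: probability estimates, log-likelihood, k, and AIC."""

    estimates: Mapping[tuple[str, str], float]
    loglik: float
    k: int

    @property
    def aic(self) -> float:
        return aic(self.loglik, self.k)

    def row_estimates(self, origin: str) -> dict[str, float]:
        return {d: p for (o, d), p in self.estimates.items() if o == origin}


@dataclass
class ComparisonTable:
    """One row per candidate structure: loglik, k, AIC, ΔAIC, verdict.

    ΔAIC = AIC(constrained) - AIC(unconstrained); by the sign convention used
    throughout, a positive ΔAIC favours separate parameters (split), negative
    favours the constraint (merge).  Ties go to the more parsimonious model.
    """

    rows: pd.DataFrame
    baseline: FitResult | None = None

    COLUMNS = ("constraint", "loglik", "k", "aic", "delta_aic", "verdict")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"comparison table missing columns {sorted(missing)}")

    @property
    def frame(self) -> pd.DataFrame:
        return self.rows

    def rendered(self) -> pd.DataFrame:
        """Presentation copy with AIC columns rounded to 1 decimal place."""
        out = self.rows.copy()
        for col in ("aic", "delta_aic"):
            out[col] = out[col].round(1)
        out["loglik"] = out["loglik"].round(2)
        return out


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 logL."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return 2.0 * k - 2.0 * loglik


def _multinomial_loglik(counts: Sequence[int], probs: Sequence[float]) -> float:
    """Multinomial log-pmf with the normalising coefficient; 0·log 0 := 0."""
    x = np.asarray(counts, dtype=float)
    p = np.asarray(probs, dtype=float)
    n = x.sum()
    coef = gammaln(n + 1.0) - gammaln(x + 1.0).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(x > 0, x * np.log(p), 0.0)
    if np.any((x > 0) & (p <= 0)):
        return -math.inf
    return float(coef + terms.sum())


def _table_loglik(
    table: TransitionCountTable, estimates: Mapping[tuple[str, str], float]
) -> float:
    total = 0.0
    for origin, dests in table.row_destinations().items():
        xs = [table.counts[(origin, d)] for d in dests]
        ps = [estimates[(origin, d)] for d in dests]
        total += _multinomial_loglik(xs, ps)
    return total


def row_mle(table: TransitionCountTable) -> FitResult:
    """Unconstrained MLE: each row's probabilities are its sample proportions."""
    if len(table) == 0:
        raise ValueError("empty transition count table")
    estimates: dict[tuple[str, str], float] = {}
    k = 0
    for origin, dests in table.row_destinations().items():
        n = table.row_total(origin)
        if n <= 0:
            raise ValueError(f"row total for origin {origin!r} must be > 0")
        for d in dests:
            estimates[(origin, d)] = table.counts[(origin, d)] / n
        k += len(dests) - 1
    return FitResult(estimates=estimates, loglik=_table_loglik(table, estimates), k=k)


def _constraint_groups_by_origin(
    table: TransitionCountTable, constraints: ConstraintSet
) -> tuple[dict[str, frozenset[str]], dict[str, set[str]]] | None:
    """If every constraint touching an origin shares one origin set, return
    (origin -> its group, origin -> constrained destinations); else None."""
    rows = table.row_destinations()
    group_of: dict[str, frozenset[str]] = {}
    constrained_dests: dict[str, set[str]] = {}
    for dest, origins in constraints.prob_constraints:
        present = frozenset(o for o in origins if o in rows and dest in set(rows[o]))
        if len(present) < 2:
            # constraint collapses to nothing on this table
            continue
        for o in present:
            prev = group_of.get(o)
            if prev is not None and prev != present:
                return None
            group_of[o] = present
            constrained_dests.setdefault(o, set()).add(dest)
    return group_of, constrained_dests


def constrained_mle(
    table: TransitionCountTable, constraints: ConstraintSet
) -> FitResult:
    """MLE of transition probabilities under equality and zero constraints.

    Closed form (grouped constraints): the common probability of destination i
    shared by origin group G is q̂_i = Σ_{j∈G} x_{ji} / Σ_{j∈G} n_j, and the
    free probabilities in each constrained row are the conditional proportions
    rescaled to the residual mass 1 - Σ_i q̂_i.  Zero constraints fix cells to
    0 exactly (the observed count there must be 0).  k is reduced by |G| - 1
    per equality and by 1 per zero constraint.
    """
    rows = table.row_destinations()
    for dest, origins in constraints.prob_constraints:
        for o in origins:
            if o in rows and dest not in rows[o]:
                raise ValueError(
                    f"constraint references destination {dest!r} absent from row {o!r}"
                )
    for o, d in constraints.zero_constraints:
        if (o, d) in table.counts and table.counts[(o, d)] > 0:
            raise ValueError(
                f"zero constraint on ({o!r}, {d!r}) conflicts with observed count "
                f"{table.counts[(o, d)]}"
            )
    grouped = _constraint_groups_by_origin(table, constraints)
    if grouped is None:
        return _constrained_mle_numerical(table, constraints)
    group_of, constrained_dests = grouped

    zero_cells = {
        (o, d) for o, d in constraints.zero_constraints if (o, d) in table.counts
    }
    # zero-constrained cells must not themselves be equality-constrained
    for o, ds in constrained_dests.items():
        overlap = {d for d in ds if (o, d) in zero_cells}
        if overlap:
            raise ValueError(
                f"cells {sorted((o, d) for d in overlap)} are both zero- and "
                "equality-constrained"
            )

    estimates: dict[tuple[str, str], float] = {}
    # pooled estimates per (group, destination)
    pooled: dict[tuple[frozenset[str], str], float] = {}
    for origin, group in group_of.items():
        n_pool = sum(table.row_total(o) for o in group)
        for dest in constrained_dests[origin]:
            key = (group, dest)
            if key not in pooled:
                x_pool = sum(table.counts[(o, dest)] for o in group)
                pooled[key] = x_pool / n_pool

    for origin, dests in rows.items():
        n = table.row_total(origin)
        if n <= 0:
            raise ValueError(f"row total for origin {origin!r} must be > 0")
        cdests = constrained_dests.get(origin, set())
        group = group_of.get(origin)
        q_row = 0.0
        for d in cdests:
            q = pooled[(group, d)]
            estimates[(origin, d)] = q
            q_row += q
        if q_row > 1.0 + 1e-12:
            raise ValueError(
                f"constraints force row {origin!r} to sum above 1 ({q_row:.6f})"
            )
        free = [d for d in dests if d not in cdests and (origin, d) not in zero_cells]
        for d in dests:
            if (origin, d) in zero_cells:
                estimates[(origin, d)] = 0.0
        x_free = sum(table.counts[(origin, d)] for d in free)
        residual = max(0.0, 1.0 - q_row)
        if free:
            if x_free > 0:
                for d in free:
                    estimates[(origin, d)] = (
                        table.counts[(origin, d)] / x_free * residual
                    )
            else:
                # no data on the free cells: any allocation maximises; spread evenly
                for d in free:
                    estimates[(origin, d)] = residual / len(free)

    k = count_free_parameters(rows, constraints)
    return FitResult(estimates=estimates, loglik=_table_loglik(table, estimates), k=k)


def _constrained_mle_numerical(
    table: TransitionCountTable, constraints: ConstraintSet
) -> FitResult:
    """General-purpose maximiser for constraint patterns without a closed form.

    Ties equality-constrained cells to shared variables and maximises the
    multinomial log-likelihood subject to linear row-sum constraints.
    """
    rows = table.row_destinations()
    zero_cells = {
        (o, d) for o, d in constraints.zero_constraints if (o, d) in table.counts
    }
    # variable id per cell; equality constraints unify ids (union-find)
    cells = [c for c in table.counts if c not in zero_cells]
    parent = {c: c for c in cells}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for dest, origins in constraints.prob_constraints:
        present = [o for o in origins if (o, dest) in parent]
        for a, b in zip(present, present[1:]):
            ra, rb = find((a, dest)), find((b, dest))
            if ra != rb:
                parent[ra] = rb
    var_of = {}
    var_index: dict[tuple[str, str], int] = {}
    for c in cells:
        root = find(c)
        if root not in var_index:
            var_index[root] = len(var_index)
        var_of[c] = var_index[root]
    nvar = len(var_index)

    counts_per_var = np.zeros(nvar)
    for c in cells:
        counts_per_var[var_of[c]] += table.counts[c]
    # row-sum equality constraints A p = 1
    origins = list(rows)
    A = np.zeros((len(origins), nvar))
    for i, o in enumerate(origins):
        for d in rows[o]:
            if (o, d) in var_of:
                A[i, var_of[(o, d)]] += 1.0

    def negll(p):
        with np.errstate(divide="ignore"):
            terms = np.where(counts_per_var > 0, counts_per_var * np.log(p), 0.0)
        return -terms.sum()

    def grad(p):
        g = np.where(counts_per_var > 0, -counts_per_var / p, 0.0)
        return g

    x0 = np.full(nvar, 1.0 / max(2, nvar))
    # feasible start: project row-wise proportional allocation
    for i, o in enumerate(origins):
        idx = [var_of[(o, d)] for d in rows[o] if (o, d) in var_of]
        if idx:
            x0[idx] = 1.0 / A[i, idx].sum() / 1.0
    res = minimize(
        negll,
        x0,
        jac=grad,
        method="trust-constr",
        constraints=[LinearConstraint(A, 1.0, 1.0)],
        bounds=[(1e-12, 1.0)] * nvar,
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 5000},
    )
    p = res.x
    estimates = {c: 0.0 for c in zero_cells}
    estimates.update({c: float(p[v]) for c, v in var_of.items()})
    k = count_free_parameters(rows, constraints)
    return FitResult(estimates=estimates, loglik=_table_loglik(table, estimates), k=k)


def compare_structures(
    table: TransitionCountTable,
    candidates: Mapping[str, ConstraintSet] | Sequence[ConstraintSet],
) -> ComparisonTable:
    """AIC comparison of candidate constraint sets against the unconstrained fit.

    Each row reports the candidate's maximised log-likelihood, parameter count,
    AIC, and ΔAIC = AIC(candidate) - AIC(unconstrained).  Verdict is "merge"
    when ΔAIC <= 0 (the constraint is supported, ties going to parsimony) and
    "split" otherwise.
    """
    if isinstance(candidates, Mapping):
        items = list(candidates.items())
    else:
        items = [(f"candidate_{i}", c) for i, c in enumerate(candidates)]
    if not items:
        raise ValueError("no candidate constraint sets supplied")
    base = row_mle(table)
    records = [
        {
            "constraint": "unconstrained",
            "loglik": base.loglik,
            "k": base.k,
            "aic": base.aic,
            "delta_aic": 0.0,
            "verdict": "reference",
        }
    ]
    for name, cset in items:
        fit = constrained_mle(table, cset)
        delta = fit.aic - base.aic
        records.append(
            {
                "constraint": name,
                "loglik": fit.loglik,
                "k": fit.k,
                "aic": fit.aic,
                "delta_aic": delta,
                "verdict": "merge" if delta <= 0 else "split",
            }
        )
    return ComparisonTable(pd.DataFrame.from_records(records), baseline=base)


def per_destination_table(
    table: TransitionCountTable, merge: MergeSpec
) -> ComparisonTable:
    """Destination-by-destination assessment of a merge proposal.

    For each destination reachable from a merge group, compares the model in
    which the group's probabilities into that destination are equal against
    the unconstrained model, leaving all other destinations free.  Degenerate
    groups (a single origin present in the data) contribute only the
    unconstrained reference row.
    """
    rows = table.row_destinations()
    base = row_mle(table)
    records = [
        {
            "constraint": "unconstrained",
            "loglik": base.loglik,
            "k": base.k,
            "aic": base.aic,
            "delta_aic": 0.0,
            "verdict": "reference",
        }
    ]
    for label, members in merge.groups:
        present = [o for o in members if o in rows]
        if len(present) < 2:
            continue
        shared = set.intersection(*(set(rows[o]) for o in present)) - set(members)
        for dest in sorted(shared):
            cset = ConstraintSet(prob_constraints=[(dest, present)])
            fit = constrained_mle(table, cset)
            delta = fit.aic - base.aic
            records.append(
                {
                    "constraint": f"{label}:{dest} equal",
                    "loglik": fit.loglik,
                    "k": fit.k,
                    "aic": fit.aic,
                    "delta_aic": delta,
                    "verdict": "merge" if delta <= 0 else "split",
                }
            )
    return ComparisonTable(pd.DataFrame.from_records(records), baseline=base)


@dataclass(frozen=True)
class PublishedRiskSummary:
    """A published risk estimate with its 95% CI, for count back-derivation.

    ``kind`` is "absolute-risk" (point is a probability) or "relative-risk"
    (point multiplies ``baseline_risk`` to give the absolute risk).
    """

    kind: str
    point: float
    ci_low: float
    ci_high: float
    baseline_risk: float | None = None
    time_unit: str = "year"

    def __post_init__(self):
        if self.kind not in ("absolute-risk", "relative-risk"):
            raise ValueError("kind must be 'absolute-risk' or 'relative-risk'")
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("require ci_low <= point <= ci_high")
        if self.kind == "relative-risk" and self.baseline_risk is None:
            raise ValueError("relative-risk summaries need a baseline_risk")
        risk = self.absolute_risk
        if not 0.0 < risk < 1.0:
            raise ValueError("implied absolute risk must lie strictly in (0, 1)")

    @property
    def absolute_risk(self) -> float:
        if self.kind == "absolute-risk":
            return self.point
        return self.point * float(self.baseline_risk)


def derive_counts(
    summary: PublishedRiskSummary, denominator_hint: int | None = None
) -> tuple[int, int, dict[str, float]]:
    """Back-derive integer (events, denominator) from a published risk summary.

    The CI width is moment-matched on the log scale:
    se(log risk) = (log ci_high - log ci_low) / (2 · 1.96), and by the delta
    method var(log p̂) ≈ (1 - p) / (n p), giving the denominator; events are
    the rounded implied risk times the denominator.  Returns a diagnostics
    dict with the recomputed CI so callers can check the round trip.
    """
    if summary.ci_high <= summary.ci_low:
        raise ValueError("degenerate CI: zero or negative implied variance")
    p = summary.absolute_risk
    se_log = (math.log(summary.ci_high) - math.log(summary.ci_low)) / (2 * 1.959964)
    if se_log <= 0:
        raise ValueError("degenerate CI: zero or negative implied variance")
    if denominator_hint is not None:
        n = int(denominator_hint)
    else:
        n = round((1.0 - p) / (p * se_log**2))
    if n < 1:
        raise ValueError("implied denominator below 1")
    events = round(p * n)
    p_hat = events / n
    se_back = math.sqrt((1 - p_hat) / (n * p_hat)) if events > 0 else float("nan")
    scale = summary.point / p  # map absolute risk back to the published scale
    diag = {
        "implied_risk": p,
        "recovered_risk": p_hat,
        "ci_low_recomputed": p_hat * math.exp(-1.959964 * se_back) * scale,
        "ci_high_recomputed": p_hat * math.exp(1.959964 * se_back) * scale,
        "ci_low_discrepancy": abs(p_hat * math.exp(-1.959964 * se_back) * scale - summary.ci_low),
        "ci_high_discrepancy": abs(p_hat * math.exp(1.959964 * se_back) * scale - summary.ci_high),
    }
    return events, n, diag
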