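"""Discrete-time Markov cohort engine and the merged/split equivalence check.

The engine propagates a cohort through a row-stochastic transition matrix,
accumulates expected costs and quality-adjusted life-years (QALYs) with
optional discounting and half-cycle correction, and constructs merged-state
models from split ones.  When a split model's outward probabilities, costs
and utilities are equal across the states of a merge group, the merged model
reproduces its aggregated occupancy, costs and QALYs exactly — the
equivalence that justifies comparing structures via parameter constraints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .structures import MergeSpec, StateSpace

__all__ = [
    "TransitionModel",
    "CohortTrace",
    "EquivalenceReport",
    "cohort_trace",
    "expected_outcomes",
    "merge_model",
    "check_equivalence",
    "per_cycle_discount",
]

_ROW_TOL = 1e-12


@dataclass(frozen=True)
class TransitionModel:
    """A state space with per-cycle transition matrix, costs and utilities.

    ``P[i, j]`` is the probability of moving from ``space.states[i]`` to
    ``space.states[j]`` in one cycle.  ``cost`` is currency per state per
    cycle; ``utility`` is dimensionless (1 = full health).  ``cycle_length``
    is in years and scales utilities into QALYs.
    """

    space: StateSpace
    P: np.ndarray
    cost: np.ndarray
    utility: np.ndarray
    cycle_length: float = 1.0

    def __init__(
        self,
        space: StateSpace,
        P: Sequence[Sequence[float]] | np.ndarray,
        cost: Mapping[str, float] | Sequence[float] | None = None,
        utility: Mapping[str, float] | Sequence[float] | None = None,
        cycle_length: float = 1.0,
    ):
        n = len(space)
        P = np.asarray(P, dtype=float)
        if P.shape != (n, n):
            raise ValueError(f"P must be {n}x{n} for this state space")
        if np.any(P < -_ROW_TOL) or np.any(P > 1 + _ROW_TOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rowsums = P.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            bad = [space.states[i] for i in np.flatnonzero(np.abs(rowsums - 1) > 1e-9)]
            raise ValueError(f"rows of P must sum to 1; offending states: {bad}")
        P = P / rowsums[:, None]  # renormalise away float dust
        for s in space.absorbing:
            i = space.index(s)
            if abs(P[i, i] - 1.0) > 1e-9:
                raise ValueError(f"absorbing state {s!r} must have P_XX = 1")

        def _vec(values, name):
            if values is None:
                return np.zeros(n)
            if isinstance(values, Mapping):
                missing = set(space.states) - set(values)
                if missing:
                    raise ValueError(f"{name} missing for states {sorted(missing)}")
                return np.array([float(values[s]) for s in space.states])
            arr = np.asarray(values, dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per state")
            return arr

        object.__setattr__(self, "space", space)
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "cost", _vec(cost, "cost"))
        object.__setattr__(self, "utility", _vec(utility, "utility"))
        object.__setattr__(self, "cycle_length", float(cycle_length))

    def cost_of(self, state: str) -> float:
        return float(self.cost[self.space.index(state)])

    def utility_of(self, state: str) -> float:
        return float(self.utility[self.space.index(state)])


@dataclass(frozen=True)
class CohortTrace:
    """Cohort occupancy by cycle: row t is the distribution entering cycle t."""

    space: StateSpace
    occupancy: np.ndarray  # shape (n_cycles + 1, n_states)

    @property
    def cycles(self) -> int:
        return self.occupancy.shape[0] - 1


def _init_vector(space: StateSpace, init) -> np.ndarray:
    if isinstance(init, Mapping):
        v = np.zeros(len(space))
        for s, w in init.items():
            v[space.index(s)] = float(w)
    else:
        v = np.asarray(init, dtype=float)
        if v.shape != (len(space),):
            raise ValueError("init must have one entry per state")
    if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
        raise ValueError("init must be a probability distribution over states")
    return v / v.sum()


def cohort_trace(model: TransitionModel, init, n_cycles: int) -> CohortTrace:
    """Propagate a cohort: occupancy_{t+1} = occupancy_t · P."""
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    v = _init_vector(model.space, init)
    occ = np.empty((n_cycles + 1, len(model.space)))
    occ[0] = v
    for t in range(n_cycles):
        occ[t + 1] = occ[t] @ model.P
    return CohortTrace(space=model.space, occupancy=occ)


def per_cycle_discount(annual_rate: float, cycle_length: float) -> float:
    """Per-cycle discount factor from an annual rate and cycle length in years."""
    if annual_rate < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + annual_rate) ** (-cycle_length)


def expected_outcomes(
    trace: CohortTrace,
    model: TransitionModel,
    discount_rate: float = 0.0,
    half_cycle: bool = False,
) -> tuple[float, float]:
    """Total expected (cost, QALYs) over the trace horizon.

    Accrual uses the occupancy entering each cycle; with ``half_cycle`` the
    trapezoidal average of the entering and exiting occupancy is used instead.
    ``discount_rate`` is the annual rate, converted per cycle via the model's
    cycle length.  Utilities are scaled by the cycle length in years.
    """
    if trace.space.states != model.space.states:
        raise ValueError("trace and model state spaces differ")
    T = trace.cycles
    occ = trace.occupancy
    if half_cycle:
        accrual = 0.5 * (occ[:-1] + occ[1:])
    else:
        accrual = occ[:-1]
    delta = per_cycle_discount(discount_rate, model.cycle_length)
    weights = delta ** np.arange(T)
    cost = float(weights @ (accrual @ model.cost))
    qaly = float(weights @ (accrual @ model.utility)) * model.cycle_length
    return cost, qaly


def _group_weights(
    members: Sequence[str], prevalence: Mapping[str, float] | None, init, space
) -> np.ndarray:
    if prevalence is not None:
        w = np.array([float(prevalence[m]) for m in members])
    else:
        v = _init_vector(space, init) if init is not None else None
        if v is None:
            w = np.ones(len(members))
        else:
            w = np.array([v[space.index(m)] for m in members])
            if w.sum() == 0:
                w = np.ones(len(members))
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("prevalence weights must be non-negative, not all zero")
    return w / w.sum()


def merge_model(
    model: TransitionModel,
    merge: MergeSpec,
    prevalence: Mapping[str, float] | None = None,
    init=None,
    force: bool = False,
    tol: float = 1e-9,
) -> TransitionModel:
    """Collapse merge groups of a split model into single states.

    The merged state's outward probabilities are the common constrained values
    (checked equal across members within ``tol`` unless ``force``); inbound
    probabilities are summed over members; its cost and utility are
    prevalence-weighted means of the members'.  ``prevalence`` defaults to the
    initial distribution restricted to the group (uniform if unavailable).
    With ``force`` the outward probabilities are prevalence-weighted averages,
    which is how an analyst adopting the coarser structure would pool them.
    """
    merge.validate_against(model.space)
    space = model.space
    old = list(space.states)
    # merged space keeps order: group replaced at its first member's position
    new_states: list[str] = []
    owner: dict[str, str] = {}
    for s in old:
        g = merge.group_of(s)
        if g is None:
            new_states.append(s)
            owner[s] = s
        else:
            owner[s] = g
            if g not in new_states:
                new_states.append(g)
    absorbing = frozenset(
        owner[s] for s in space.absorbing
        if all(m in space.absorbing for m in (merge.members(owner[s]) if owner[s] in merge.labels else {s}))
    )
    new_space = StateSpace(new_states, absorbing)

    weights: dict[str, np.ndarray] = {}
    member_order: dict[str, list[str]] = {}
    for label, members in merge.groups:
        ms = [s for s in old if s in members]
        member_order[label] = ms
        weights[label] = _group_weights(ms, prevalence, init, space)

    n_new = len(new_states)
    P_new = np.zeros((n_new, n_new))
    cost_new = np.zeros(n_new)
    util_new = np.zeros(n_new)
    # column aggregation matrix old -> new
    C = np.zeros((len(old), n_new))
    for s in old:
        C[space.index(s), new_space.index(owner[s])] = 1.0
    P_cols = model.P @ C  # old-rows x new-cols

    for s_new in new_states:
        i_new = new_space.index(s_new)
        if s_new in merge.labels:
            ms = member_order[s_new]
            w = weights[s_new]
            rows = np.array([P_cols[space.index(m)] for m in ms])
            if not force:
                spread = np.abs(rows - rows[0])
                # within-group column (the merged self-transition) is allowed
                # to differ; only outward columns are constrained
                outward = [j for j in range(n_new) if j != i_new]
                if np.max(spread[:, outward], initial=0.0) > tol:
                    raise ValueError(
                        f"group {s_new!r} violates outward-probability equality "
                        f"beyond tol={tol}; pass force=True to pool anyway"
                    )
            P_new[i_new] = w @ rows
            cost_new[i_new] = w @ np.array([model.cost_of(m) for m in ms])
            util_new[i_new] = w @ np.array([model.utility_of(m) for m in ms])
        else:
            P_new[i_new] = P_cols[space.index(s_new)]
            cost_new[i_new] = model.cost_of(s_new)
            util_new[i_new] = model.utility_of(s_new)

    return TransitionModel(
        new_space, P_new, cost_new, util_new, cycle_length=model.cycle_length
    )


@dataclass(frozen=True)
class EquivalenceReport:
    """Discrepancies between the aggregated split model and the merged model.

    Occupancy differences are absolute (occupancies live on [0, 1]); cost and
    QALY differences are reported both absolutely and relative to the
    magnitude of the outcome, since totals in currency units can be many
    orders of magnitude above 1 and double-precision accumulation error
    scales with them.
    """

    max_occupancy_diff: float
    cost_diff: float
    qaly_diff: float
    cost_rel_diff: float
    qaly_rel_diff: float

    @property
    def max_diff(self) -> float:
        """Worst discrepancy, each outcome on its natural scale: absolute for
        occupancy, relative for costs and QALYs (absolute when magnitude <= 1)."""
        return max(self.max_occupancy_diff, self.cost_rel_diff, self.qaly_rel_diff)


def check_equivalence(
    split: TransitionModel,
    merged: TransitionModel,
    merge: MergeSpec,
    init,
    n_cycles: int,
    discount_rate: float = 0.0,
    half_cycle: bool = False,
) -> EquivalenceReport:
    """Compare the split model's aggregated trace/outcomes with the merged one.

    The split model's initial distribution is mapped to the merged space by
    summing group members.  Costs and QALYs on the split side use the split
    model's own per-state values, so a true equivalence additionally requires
    equal costs/utilities within each group (or prevalence weighting that
    matches the realised within-group mix).
    """
    merge.validate_against(split.space)
    v_split = _init_vector(split.space, init)
    # aggregate map old index -> merged index
    agg = np.zeros((len(split.space), len(merged.space)))
    for s in split.space.states:
        g = merge.group_of(s) or s
        if g not in merged.space.states:
            raise ValueError(f"merged model lacks state {g!r}")
        agg[split.space.index(s), merged.space.index(g)] = 1.0
    v_merged = v_split @ agg

    tr_split = cohort_trace(split, v_split, n_cycles)
    tr_merged = cohort_trace(merged, v_merged, n_cycles)
    occ_diff = float(np.max(np.abs(tr_split.occupancy @ agg - tr_merged.occupancy)))

    c_s, q_s = expected_outcomes(tr_split, split, discount_rate, half_cycle)
    c_m, q_m = expected_outcomes(tr_merged, merged, discount_rate, half_cycle)

    def rel(a, b):
        return abs(a - b) / max(1.0, abs(a), abs(b))

    return EquivalenceReport(
        max_occupancy_diff=occ_diff,
        cost_diff=abs(c_s - c_m),
        qaly_diff=abs(q_s - q_m),
        cost_rel_diff=rel(c_s, c_m),
        qaly_rel_diff=rel(q_s, q_m),
    )
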