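"""State spaces, merge proposals, and the equality constraints they imply.

Merging a set of states in a discrete-time transition model is equivalent to
keeping the full (split) state space but constraining, for every exit state
reachable from the group, the outward transition probabilities of the group
members to be equal — together with their per-cycle costs and utilities.
This module represents those objects and derives the constraint set implied
by a proposed merge, including the encompassing-model construction needed
when the candidate states do not share the same exits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence


@dataclass(frozen=True)
class StateSpace:
    """An ordered set of state labels, some of which may be absorbing.

    The label order fixes matrix row/column order everywhere in the package.
    """

    states: tuple[str, ...]
    absorbing: frozenset[str] = frozenset()

    def __init__(self, states: Sequence[str], absorbing: Iterable[str] = ()):
        states = tuple(states)
        if len(states) != len(set(states)):
            raise ValueError("state labels must be unique")
        if not states or any(not s for s in states):
            raise ValueError("state labels must be non-empty")
        absorbing = frozenset(absorbing)
        unknown = absorbing - set(states)
        if unknown:
            raise ValueError(f"absorbing labels not in state list: {sorted(unknown)}")
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "absorbing", absorbing)

    def index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise KeyError(f"unknown state label {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self.states

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class MergeSpec:
    """A proposal to merge one or more disjoint groups of states.

    ``groups`` maps the merged-state label to the (>=2) member labels it
    replaces.  Groups must be pairwise disjoint.
    """

    groups: tuple[tuple[str, frozenset[str]], ...]

    def __init__(self, groups: Mapping[str, Iterable[str]]):
        norm = tuple((label, frozenset(members)) for label, members in groups.items())
        seen: set[str] = set()
        for label, members in norm:
            if len(members) < 2:
                raise ValueError(f"merge group {label!r} needs >=2 members")
            if seen & members:
                raise ValueError("merge groups must be pairwise disjoint")
            seen |= members
        object.__setattr__(self, "groups", norm)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.groups)

    def members(self, label: str) -> frozenset[str]:
        for lab, mem in self.groups:
            if lab == label:
                return mem
        raise KeyError(f"no merge group labelled {label!r}")

    def group_of(self, state: str) -> str | None:
        """Merged label owning ``state``, or None if the state is untouched."""
        for lab, mem in self.groups:
            if state in mem:
                return lab
        return None

    def validate_against(self, space: StateSpace) -> None:
        for label, members in self.groups:
            unknown = members - set(space.states)
            if unknown:
                raise ValueError(
                    f"merge group {label!r} references unknown states {sorted(unknown)}"
                )


@dataclass(frozen=True)
class ConstraintSet:
    """Equality and structural-zero constraints on a transition model.

    prob_constraints: for each (destination, origins) pair, the probability of
        moving to that destination is equal across all listed origins.
    cost_equal / utility_equal: sets of states sharing one cost / utility.
    zero_constraints: (origin, destination) transition probabilities fixed to 0.
    """

    prob_constraints: tuple[tuple[str, frozenset[str]], ...] = ()
    cost_equal: tuple[frozenset[str], ...] = ()
    utility_equal: tuple[frozenset[str], ...] = ()
    zero_constraints: tuple[tuple[str, str], ...] = ()

    def __init__(
        self,
        prob_constraints: Iterable[tuple[str, Iterable[str]]] = (),
        cost_equal: Iterable[Iterable[str]] = (),
        utility_equal: Iterable[Iterable[str]] = (),
        zero_constraints: Iterable[tuple[str, str]] = (),
    ):
        pc = tuple(
            sorted(
                ((dest, frozenset(orig)) for dest, orig in prob_constraints),
                key=lambda c: (c[0], tuple(sorted(c[1]))),
            )
        )
        per_dest: dict[str, set[str]] = {}
        for dest, origins in pc:
            if len(origins) < 2:
                raise ValueError("probability constraint needs >=2 origins")
            prev = per_dest.setdefault(dest, set())
            if prev & origins:
                raise ValueError(
                    f"origin appears twice in constraints for destination {dest!r}"
                )
            prev |= origins
        object.__setattr__(self, "prob_constraints", pc)
        object.__setattr__(
            self, "cost_equal", tuple(sorted(map(frozenset, cost_equal), key=sorted))
        )
        object.__setattr__(
            self,
            "utility_equal",
            tuple(sorted(map(frozenset, utility_equal), key=sorted)),
        )
        object.__setattr__(self, "zero_constraints", tuple(sorted(zero_constraints)))

    def validate_against(self, space: StateSpace) -> None:
        known = set(space.states)
        for dest, origins in self.prob_constraints:
            bad = ({dest} | origins) - known
            if bad:
                raise ValueError(f"constraint references unknown states {sorted(bad)}")
        for group in (*self.cost_equal, *self.utility_equal):
            bad = group - known
            if bad:
                raise ValueError(f"constraint references unknown states {sorted(bad)}")
        for o, d in self.zero_constraints:
            if o not in known or d not in known:
                raise ValueError(f"zero constraint references unknown states ({o}, {d})")

    @property
    def n_prob_reductions(self) -> int:
        """Free probability parameters removed by this constraint set."""
        return sum(len(origins) - 1 for _, origins in self.prob_constraints) + len(
            self.zero_constraints
        )


@dataclass(frozen=True)
class GroupVerdict:
    """Mergeability report for one candidate group."""

    label: str
    shared_exits: bool
    exits_by_member: Mapping[str, frozenset[str]]
    missing: tuple[tuple[str, str], ...]  # (member, exit it lacks)


@dataclass(frozen=True)
class MergeabilityReport:
    verdicts: tuple[GroupVerdict, ...] = ()

    @property
    def all_shared(self) -> bool:
        return all(v.shared_exits for v in self.verdicts)


def _group_exits(
    members: frozenset[str], allowed: set[tuple[str, str]]
) -> dict[str, frozenset[str]]:
    """Per-member exit sets: destinations outside the group (self loops and
    within-group moves are not exits)."""
    return {
        m: frozenset(d for o, d in allowed if o == m and d not in members)
        for m in members
    }


def validate_mergeability(
    space: StateSpace, merge: MergeSpec, allowed_transitions: Iterable[tuple[str, str]]
) -> MergeabilityReport:
    """Report, per merge group, whether members share the same exit states.

    A group with shared exits can be merged directly; otherwise the comparison
    requires the encompassing model built by :func:`extend_for_unshared_exits`.
    """
    merge.validate_against(space)
    allowed = set(allowed_transitions)
    verdicts = []
    for label, members in merge.groups:
        exits = _group_exits(members, allowed)
        union = frozenset().union(*exits.values()) if exits else frozenset()
        missing = tuple(
            sorted((m, e) for m in members for e in union if e not in exits[m])
        )
        verdicts.append(
            GroupVerdict(
                label=label,
                shared_exits=not missing,
                exits_by_member=exits,
                missing=missing,
            )
        )
    return MergeabilityReport(tuple(verdicts))


def constraints_from_merge(
    space: StateSpace,
    merge: MergeSpec,
    exits: Mapping[str, Iterable[str]] | None = None,
    allowed_transitions: Iterable[tuple[str, str]] | None = None,
) -> ConstraintSet:
    """Equality constraints making the split model equivalent to the merged one.

    For each group with members A_1..A_n and shared exits E_1..E_m this yields
    one probability constraint P(A_1 -> E_i) = ... = P(A_n -> E_i) per exit,
    plus one cost-equality and one utility-equality set per group.  Transitions
    among the group members themselves are left unconstrained.

    ``exits`` maps each merged label to its exit set; if omitted it is derived
    from ``allowed_transitions``, which must then show every member sharing the
    same exits (otherwise use :func:`extend_for_unshared_exits` first).
    """
    merge.validate_against(space)
    if exits is None:
        if allowed_transitions is None:
            raise ValueError("provide either exits or allowed_transitions")
        report = validate_mergeability(space, merge, allowed_transitions)
        bad = [v for v in report.verdicts if not v.shared_exits]
        if bad:
            detail = "; ".join(
                f"group {v.label!r} missing {list(v.missing)}" for v in bad
            )
            raise ValueError(
                "groups have non-shared exits — build the encompassing model with "
                f"extend_for_unshared_exits first: {detail}"
            )
        exits = {
            v.label: frozenset().union(*v.exits_by_member.values())
            for v in report.verdicts
        }
    prob = []
    cost_eq = []
    util_eq = []
    for label, members in merge.groups:
        for e in sorted(exits[label]):
            if e not in space:
                raise ValueError(f"unknown exit label {e!r}")
            if e in members:
                raise ValueError(f"exit {e!r} is inside merge group {label!r}")
            prob.append((e, members))
        cost_eq.append(members)
        util_eq.append(members)
    return ConstraintSet(
        prob_constraints=prob, cost_equal=cost_eq, utility_equal=util_eq
    )


def extend_for_unshared_exits(
    space: StateSpace, merge: MergeSpec, allowed_transitions: Iterable[tuple[str, str]]
) -> tuple[frozenset[tuple[str, str]], ConstraintSet, ConstraintSet]:
    """Encompassing-model construction for groups with different exit states.

    When the candidate states have different exits there is no parameter choice
    under which the smaller model equals the merged one; instead both are
    expressed as constrained versions of an *encompassing* model in which every
    group member is given every exit seen in the group:

    - constraint set A forces the added transitions to zero, recovering the
      original smaller model;
    - constraint set B equates outward probabilities (and costs/utilities)
      across the group, recovering the merged model.

    Fitting A and B against the encompassing model makes the AIC comparison
    between the two structures valid.
    """
    merge.validate_against(space)
    if not merge.groups:
        raise ValueError("merge spec has no groups")
    allowed = set(allowed_transitions)
    extended = set(allowed)
    zeros: list[tuple[str, str]] = []
    exits_map: dict[str, frozenset[str]] = {}
    for label, members in merge.groups:
        exits = _group_exits(members, allowed)
        union = frozenset().union(*exits.values()) if exits else frozenset()
        exits_map[label] = union
        for m in sorted(members):
            for e in sorted(union):
                if (m, e) not in extended:
                    extended.add((m, e))
                    zeros.append((m, e))
    set_a = ConstraintSet(zero_constraints=zeros)
    set_b = constraints_from_merge(space, merge, exits=exits_map)
    return frozenset(extended), set_a, set_b


def count_free_parameters(
    row_destinations: Mapping[str, Iterable[str]], constraints: ConstraintSet
) -> int:
    """Free transition-probability parameters under a constraint set.

    Counted as the number of distinct probability values (equality-constrained
    cells share one value; structural zeros are dropped) minus the rank of the
    row-sum-to-1 constraint system.  In the usual case — every constrained row
    keeps at least one free destination — this equals the familiar tally
    Σ_rows (destinations - 1) - Σ_equalities (origins - 1) - #zeros; when an
    entire row is covered by shared values (e.g. pooling a binomial pair) the
    row-sum constraints coincide and the rank correction keeps the pooled
    probability itself as a free parameter.  Origins absent from
    ``row_destinations`` are ignored.
    """
    import numpy as np

    rows = {o: list(dict.fromkeys(ds)) for o, ds in row_destinations.items()}
    zero = set(constraints.zero_constraints)
    cells = [(o, d) for o, ds in rows.items() for d in ds if (o, d) not in zero]
    if not cells:
        return 0
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
    var_index: dict[tuple[str, str], int] = {}
    for c in cells:
        root = find(c)
        if root not in var_index:
            var_index[root] = len(var_index)
    nvar = len(var_index)
    A = np.zeros((len(rows), nvar))
    for i, (o, ds) in enumerate(rows.items()):
        for d in ds:
            if (o, d) in parent:
                A[i, var_index[find((o, d))]] += 1.0
    rank = int(np.linalg.matrix_rank(A))
    return nvar - rank
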