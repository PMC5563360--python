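"""Shared generators for random tables, models and constrained structures."""

from __future__ import annotations

import numpy as np
import pytest

from statemerge import (
    ConstraintSet,
    MergeSpec,
    StateSpace,
    TransitionCountTable,
    TransitionModel,
)


def random_count_table(
    rng: np.random.Generator,
    n_origins: int | None = None,
    n_dests: int | None = None,
    max_count: int = 50,
) -> TransitionCountTable:
    """Random small multinomial table; every row has at least one observation."""
    n_origins = n_origins or int(rng.integers(2, 5))
    n_dests = n_dests or int(rng.integers(2, 5))
    origins = [f"o{i}" for i in range(n_origins)]
    dests = [f"d{j}" for j in range(n_dests)]
    counts = {}
    for o in origins:
        row = rng.integers(0, max_count + 1, size=n_dests)
        if row.sum() == 0:
            row[rng.integers(n_dests)] = 1
        for d, x in zip(dests, row):
            counts[(o, d)] = int(x)
    return TransitionCountTable(counts)


def single_exit_constraint(table: TransitionCountTable) -> ConstraintSet:
    """Equality of one shared destination across all origins of a table."""
    origins = table.origins
    dest = table.destinations(origins[0])[0]
    return ConstraintSet(prob_constraints=[(dest, origins)])


def random_constrained_split(
    rng: np.random.Generator,
) -> tuple[TransitionModel, MergeSpec, np.ndarray]:
    """A random split model whose merge-group states satisfy the equality
    constraints on outward probabilities, costs and utilities, plus a random
    initial distribution.  Within-group transitions (including reversible
    moves) are unconstrained and randomly generated.
    """
    n = int(rng.integers(3, 7))
    states = [f"s{i}" for i in range(n)]
    g = int(rng.integers(2, min(4, n)))
    group = states[:g]
    outside = states[g:]
    space = StateSpace(states)
    merge = MergeSpec({"grp": group})

    P = np.zeros((n, n))
    # shared outward block: one probability per exit, same for every member
    exit_probs = rng.dirichlet(np.ones(len(outside) + 1))
    stay_total, exits = exit_probs[0], exit_probs[1:]
    for i in range(g):
        within = rng.dirichlet(np.ones(g))
        P[i, :g] = stay_total * within
        P[i, g:] = exits
    for i in range(g, n):
        P[i] = rng.dirichlet(np.ones(n))

    cost = rng.uniform(0, 1000, size=n)
    util = rng.uniform(0, 1, size=n)
    cost[:g] = cost[0]
    util[:g] = util[0]
    model = TransitionModel(space, P, cost, util)
    init = rng.dirichlet(np.ones(n))
    return model, merge, init


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
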