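"""Packaged example structures and published summary data.

Ships ready-made objects for the worked examples: the coronary-artery-disease
(CAD) split/merged severity models, the published CECaT summaries and the
event counts derived from them, the four-state depression state space with
its candidate merges, the different-exit-states example and its encompassing
model, and a small two-strategy decision problem whose recommended strategy
flips between the merged and split structures.
"""

from __future__ import annotations

import pandas as pd

from .cohort import TransitionModel, cohort_trace, expected_outcomes
from .likelihood import PublishedRiskSummary, TransitionCountTable
from .structures import MergeSpec, StateSpace, extend_for_unshared_exits

__all__ = [
    "cecat_death_counts",
    "cecat_mi_counts",
    "cecat_risk_summaries",
    "cecat_outcome_summaries",
    "cad_space",
    "cad_merge",
    "cad_split_model",
    "panda_space",
    "panda_merges",
    "panda_allowed_transitions",
    "different_exits_example",
    "structure_sensitivity_example",
]


def cecat_death_counts() -> TransitionCountTable:
    """1-year death counts derived from the published CECaT relative risks.

    126 of 571 medium-risk and 259 of 754 high-risk patients died within a
    year; the complements remained alive.
    """
    return TransitionCountTable(
        {
            ("medium", "dead"): 126,
            ("medium", "alive"): 445,
            ("high", "dead"): 259,
            ("high", "alive"): 495,
        }
    )


def cecat_mi_counts() -> TransitionCountTable:
    """1-year non-fatal myocardial infarction counts derived for CECaT."""
    return TransitionCountTable(
        {
            ("medium", "mi"): 39,
            ("medium", "no_mi"): 1678,
            ("high", "mi"): 62,
            ("high", "no_mi"): 2097,
        }
    )


def cecat_risk_summaries() -> dict[str, PublishedRiskSummary]:
    """Published CECaT risk estimates with 95% CIs.

    Relative risks of death are versus no CAD; the non-fatal-MI rows are
    absolute annual risks.
    """
    return {
        "death_medium": PublishedRiskSummary(
            "relative-risk", 2.3, 1.9, 2.8, baseline_risk=126 / 571 / 2.3
        ),
        "death_high": PublishedRiskSummary(
            "relative-risk", 3.6, 3.1, 4.1, baseline_risk=259 / 754 / 3.6
        ),
        "mi_medium": PublishedRiskSummary("absolute-risk", 0.022, 0.016, 0.029),
        "mi_high": PublishedRiskSummary("absolute-risk", 0.028, 0.021, 0.035),
    }


def cecat_outcome_summaries() -> pd.DataFrame:
    """Published mean/SD/n of individual-level CECaT costs and utilities.

    Summary statistics only — the individual records behind them are not
    published, so these support documentation and sanity checks, not a
    likelihood comparison.
    """
    return pd.DataFrame(
        [
            {"outcome": "cost", "group": "medium", "mean": 1530.0, "sd": 880.0, "n": 59},
            {"outcome": "cost", "group": "high", "mean": 1930.0, "sd": 1070.0, "n": 19},
            {"outcome": "utility", "group": "medium", "mean": 0.81, "sd": 0.12, "n": 59},
            {"outcome": "utility", "group": "high", "mean": 0.78, "sd": 0.21, "n": 19},
        ]
    )


def cad_space() -> StateSpace:
    """Split CAD severity space: low risk, high risk, dead."""
    return StateSpace(["low", "high", "dead"], absorbing=["dead"])


def cad_merge() -> MergeSpec:
    return MergeSpec({"cad": ["low", "high"]})


def cad_split_model(
    p_ld: float = 0.1,
    p_hd: float = 0.1,
    p_lh: float = 0.15,
    p_hl: float = 0.0,
    cost: tuple[float, float] = (200.0, 2000.0),
    utility: tuple[float, float] = (0.85, 0.55),
) -> TransitionModel:
    """Three-state split CAD model; defaults satisfy the merge constraint
    P(low->dead) = P(high->dead).  Set ``p_hl`` > 0 for a reversible variant."""
    space = cad_space()
    P = [
        [1 - p_lh - p_ld, p_lh, p_ld],
        [p_hl, 1 - p_hl - p_hd, p_hd],
        [0.0, 0.0, 1.0],
    ]
    return TransitionModel(
        space,
        P,
        cost={"low": cost[0], "high": cost[1], "dead": 0.0},
        utility={"low": utility[0], "high": utility[1], "dead": 0.0},
    )


def panda_space() -> StateSpace:
    """Four depression severity states: well, mild, moderate, severe."""
    return StateSpace(["well", "mild", "moderate", "severe"])


def panda_allowed_transitions() -> frozenset[tuple[str, str]]:
    """All pairwise transitions between the four severity states are allowed."""
    states = panda_space().states
    return frozenset((a, b) for a in states for b in states)


def panda_merges() -> dict[str, MergeSpec]:
    """The candidate coarser structures for the four-state depression model."""
    return {
        "two_state": MergeSpec({"depressed": ["mild", "moderate", "severe"]}),
        "mod_severe": MergeSpec({"mod_severe": ["moderate", "severe"]}),
        "mild_mod": MergeSpec({"mild_mod": ["mild", "moderate"]}),
    }


def different_exits_example():
    """Two states considered for merging that do not share exit states.

    Model (a) lets only state 2 exit to state 3; the merged alternative (b)
    treats 1 and 2 as one state.  Returns (space, merge, allowed_a) plus the
    encompassing transition set and the two constraint sets recovering (a)
    (added transition forced to 0) and (b) (outward probabilities equated).
    """
    space = StateSpace(["s1", "s2", "s3"], absorbing=["s3"])
    merge = MergeSpec({"s12": ["s1", "s2"]})
    allowed_a = {
        ("s1", "s1"),
        ("s1", "s2"),
        ("s2", "s1"),
        ("s2", "s2"),
        ("s2", "s3"),
        ("s3", "s3"),
    }
    extended, set_a, set_b = extend_for_unshared_exits(space, merge, allowed_a)
    return space, merge, allowed_a, extended, set_a, set_b


def structure_sensitivity_example(
    wtp: float = 20000.0, n_cycles: int = 10, treatment_cost: float = 3000.0
):
    """A two-strategy decision whose recommendation depends on the structure.

    Treatment shifts the initial severity mix towards low-risk CAD (its only
    effect, at an upfront cost); transition probabilities already satisfy the
    merge constraint, but costs and utilities differ sharply between low and
    high severity.  Under the split structure the per-state costs/utilities
    reward starting low, so treating wins; the merged structure pools costs
    and utilities by baseline prevalence, erasing that reward, so not
    treating wins; the partially merged structure (pooled transitions,
    separate costs/utilities) restores the split decision.

    Returns a dict: structure name -> {"nb": {strategy: NB}, "optimal": name}.
    """
    split = cad_split_model(p_lh=0.0)  # no progression: effect is initial mix only
    inits = {
        "treat": {"low": 0.8, "high": 0.2, "dead": 0.0},
        "no_treat": {"low": 0.3, "high": 0.7, "dead": 0.0},
    }
    extra = {"treat": treatment_cost, "no_treat": 0.0}
    prevalence = {"low": 0.5, "high": 0.5}

    from .cohort import merge_model

    merged = merge_model(split, cad_merge(), prevalence=prevalence, force=True)

    def nb_for(model: TransitionModel, init) -> float:
        tr = cohort_trace(model, init, n_cycles)
        c, q = expected_outcomes(tr, model)
        return wtp * q - c

    out = {}
    # split and partially merged: per-state costs/utilities retained.  The
    # transition rows already satisfy the equality, so pooling them changes
    # nothing — the two structures share one model here by construction.
    for name, model in (("split", split), ("partially_merged", split)):
        nb = {
            s: nb_for(model, inits[s]) - extra[s] for s in inits
        }
        out[name] = {"nb": nb, "optimal": max(nb, key=nb.get)}
    merged_inits = {
        s: {"cad": inits[s]["low"] + inits[s]["high"], "dead": 0.0} for s in inits
    }
    nb = {s: nb_for(merged, merged_inits[s]) - extra[s] for s in inits}
    out["merged"] = {"nb": nb, "optimal": max(nb, key=nb.get)}
    return out
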