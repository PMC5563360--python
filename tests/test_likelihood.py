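"""Constrained multinomial MLE, AIC comparison, and count back-derivation.

The independent oracle for the constrained fits is a profile likelihood:
the shared (pooled) probabilities are optimised numerically while the free
cells of each row take their conditional maximum given the shared mass —
a route that never uses the package's pooled-count closed form.
"""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import binom, multinomial

from statemerge import (
    ConstraintSet,
    MergeSpec,
    PublishedRiskSummary,
    TransitionCountTable,
    aic,
    compare_structures,
    constrained_mle,
    derive_counts,
    per_destination_table,
    row_mle,
)
from statemerge.fixtures import cecat_death_counts, cecat_mi_counts
from tests.conftest import random_count_table, single_exit_constraint


def profile_loglik_oracle(table, dest, origins):
    """Maximise the multinomial likelihood with P(origin -> dest) shared
    across ``origins``, by numerical search over the shared probability with
    the remaining cells at their conditional optimum."""
    rows = table.row_destinations()

    def negll(qv):
        q = qv[0]
        total = 0.0
        for o, dests in rows.items():
            xs = np.array([table.counts[(o, d)] for d in dests], dtype=float)
            n = xs.sum()
            ps = np.empty_like(xs)
            if o in origins:
                j = dests.index(dest)
                free = [i for i in range(len(dests)) if i != j]
                xf = xs[free].sum()
                ps[j] = q
                if free:
                    ps[free] = (xs[free] / xf if xf > 0 else 1.0 / len(free)) * (1 - q)
            else:
                ps = xs / n
            ll = math.lgamma(n + 1) - sum(math.lgamma(x + 1) for x in xs)
            for x, p in zip(xs, ps):
                if x > 0:
                    if p <= 0:
                        return 1e12
                    ll += x * math.log(p)
            total += ll
        return -total

    best = None
    for q0 in (0.1, 0.3, 0.5, 0.7, 0.9):
        res = minimize(negll, [q0], bounds=[(1e-9, 1 - 1e-9)], method="L-BFGS-B",
                       options={"ftol": 1e-16, "gtol": 1e-12})
        if best is None or res.fun < best:
            best = res.fun
    return -best


class TestRowMle:
    def test_binomial_row_matches_sample_proportion(self):
        """126 deaths out of 571 gives the death probability 126/571."""
        t = TransitionCountTable({("medium", "dead"): 126, ("medium", "alive"): 445})
        fit = row_mle(t)
        assert fit.estimates[("medium", "dead")] == pytest.approx(126 / 571)
        assert fit.k == 1

    def test_single_destination_row_is_deterministic(self):
        t = TransitionCountTable({("a", "b"): 7})
        fit = row_mle(t)
        assert fit.estimates[("a", "b")] == 1.0
        assert fit.loglik == 0.0
        assert fit.k == 0

    def test_loglik_is_multinomial_pmf_at_the_mle(self):
        t = TransitionCountTable({("o", "a"): 2, ("o", "b"): 3, ("o", "c"): 5})
        fit = row_mle(t)
        expected = multinomial.logpmf([2, 3, 5], 10, [0.2, 0.3, 0.5])
        assert fit.loglik == pytest.approx(float(expected), abs=1e-12)

    def test_row_estimates_sum_to_one(self, rng):
        for _ in range(10):
            t = random_count_table(rng)
            fit = row_mle(t)
            for o in t.origins:
                assert sum(fit.row_estimates(o).values()) == pytest.approx(1, abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            row_mle(TransitionCountTable({}))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            TransitionCountTable({("a", "b"): -1})


class TestConstrainedMle:
    def test_pooled_binomial_closed_form(self):
        """Equating the death probability of the two CECaT rows pools the
        counts: q̂ = 385/1325."""
        fit = constrained_mle(
            cecat_death_counts(),
            ConstraintSet(prob_constraints=[("dead", ["medium", "high"]),
                                            ("alive", ["medium", "high"])]),
        )
        assert fit.estimates[("medium", "dead")] == pytest.approx(385 / 1325)
        assert fit.estimates[("high", "dead")] == pytest.approx(385 / 1325)
        assert fit.k == 1

    def test_identical_rows_fully_constrained_lose_nothing(self):
        t = TransitionCountTable(
            {("a", "x"): 10, ("a", "y"): 30, ("b", "x"): 10, ("b", "y"): 30}
        )
        cs = ConstraintSet(prob_constraints=[("x", ["a", "b"]), ("y", ["a", "b"])])
        assert constrained_mle(t, cs).loglik == pytest.approx(row_mle(t).loglik)

    def test_constrained_never_beats_unconstrained(self, rng):
        for _ in range(25):
            t = random_count_table(rng)
            fit_c = constrained_mle(t, single_exit_constraint(t))
            assert fit_c.loglik <= row_mle(t).loglik + 1e-10

    def test_matches_profile_likelihood_oracle(self, rng):
        """Closed-form pooled estimates agree with an independent numerical
        profile-likelihood maximiser to 1e-8 in log-likelihood."""
        for _ in range(30):
            t = random_count_table(rng, max_count=50)
            origins = t.origins
            dest = t.destinations(origins[0])[0]
            cs = ConstraintSet(prob_constraints=[(dest, origins)])
            fit = constrained_mle(t, cs)
            oracle = profile_loglik_oracle(t, dest, set(origins))
            assert fit.loglik == pytest.approx(oracle, abs=1e-8)

    def test_four_state_depression_shaped_constraint(self, rng):
        """Recovery-rate equality P(mild->well) = P(moderate->well) =
        P(severe->well) matches the profile oracle on a synthetic table."""
        states = ["well", "mild", "moderate", "severe"]
        counts = {}
        for o in states[1:]:
            row = rng.integers(5, 80, size=4)
            for d, x in zip(states, row):
                counts[(o, d)] = int(x)
        t = TransitionCountTable(counts)
        cs = ConstraintSet(prob_constraints=[("well", states[1:])])
        fit = constrained_mle(t, cs)
        oracle = profile_loglik_oracle(t, "well", set(states[1:]))
        assert fit.loglik == pytest.approx(oracle, abs=1e-8)

    def test_zero_constraint_with_positive_count_rejected(self):
        t = TransitionCountTable({("a", "x"): 3, ("a", "y"): 7})
        with pytest.raises(ValueError):
            constrained_mle(t, ConstraintSet(zero_constraints=[("a", "x")]))

    def test_zero_constraint_renormalises_and_reduces_k(self):
        t = TransitionCountTable({("a", "x"): 0, ("a", "y"): 7, ("a", "z"): 3})
        fit = constrained_mle(t, ConstraintSet(zero_constraints=[("a", "x")]))
        assert fit.estimates[("a", "x")] == 0.0
        assert fit.estimates[("a", "y")] == pytest.approx(0.7)
        assert fit.k == 1


class TestAic:
    def test_arithmetic(self):
        assert aic(0.0, 0) == 0.0
        assert aic(-5.0, 2) == 14.0

    def test_cecat_death_aics_match_published_values(self):
        """Binomial fits to the derived death counts give AIC 17.4
        (separate probabilities) and 39.6 (common), to 1 d.p."""
        t = cecat_death_counts()
        base = row_mle(t)
        cs = ConstraintSet(prob_constraints=[("dead", ["medium", "high"]),
                                             ("alive", ["medium", "high"])])
        fit = constrained_mle(t, cs)
        assert round(base.aic, 1) == 17.4
        assert round(fit.aic, 1) == 39.6


class TestCompareStructures:
    MERGE_CS = ConstraintSet(
        prob_constraints=[("dead", ["medium", "high"]), ("alive", ["medium", "high"])]
    )
    MERGE_CS_MI = ConstraintSet(
        prob_constraints=[("mi", ["medium", "high"]), ("no_mi", ["medium", "high"])]
    )

    def test_death_counts_favour_split(self):
        comp = compare_structures(cecat_death_counts(), {"pooled": self.MERGE_CS})
        row = comp.frame.set_index("constraint").loc["pooled"]
        assert round(row["delta_aic"], 1) == 22.2
        assert row["verdict"] == "split"

    def test_mi_counts_favour_merge(self):
        comp = compare_structures(cecat_mi_counts(), {"pooled": self.MERGE_CS_MI})
        row = comp.frame.set_index("constraint").loc["pooled"]
        assert round(row["delta_aic"], 1) == -0.6
        assert row["verdict"] == "merge"

    def test_identical_rows_one_equality_gives_minus_two(self):
        t = TransitionCountTable(
            {("a", "x"): 12, ("a", "y"): 8, ("b", "x"): 12, ("b", "y"): 8}
        )
        cs = ConstraintSet(prob_constraints=[("x", ["a", "b"])])
        comp = compare_structures(t, [cs])
        assert comp.frame.iloc[1]["delta_aic"] == pytest.approx(-2.0)

    def test_unconstrained_reference_row_has_zero_delta(self, rng):
        t = random_count_table(rng)
        comp = compare_structures(t, [single_exit_constraint(t)])
        assert comp.frame.iloc[0]["delta_aic"] == 0.0


class TestPerDestinationTable:
    def test_cross_checks_compare_structures_on_binomial(self):
        """For a two-destination table the per-destination rows reproduce the
        whole-model comparison."""
        merge = MergeSpec({"cad": ["medium", "high"]})
        per = per_destination_table(cecat_death_counts(), merge)
        whole = compare_structures(
            cecat_death_counts(),
            {"pooled": ConstraintSet(prob_constraints=[("dead", ["medium", "high"])])},
        )
        dead_row = per.frame.set_index("constraint").loc["cad:dead equal"]
        whole_row = whole.frame.set_index("constraint").loc["pooled"]
        assert dead_row["loglik"] == pytest.approx(whole_row["loglik"])

    def test_degenerate_group_yields_reference_only(self):
        t = TransitionCountTable({("a", "x"): 3, ("a", "y"): 7})
        per = per_destination_table(t, MergeSpec({"g": ["a", "b"]}))
        assert list(per.frame["constraint"]) == ["unconstrained"]

    def test_delta_aic_adds_over_constraints_on_disjoint_rows(self, rng):
        """Constraints acting on disjoint origin groups contribute additively
        to the whole-model ΔAIC, because the multinomial likelihood factorises
        by row."""
        for _ in range(5):
            t = random_count_table(rng, n_origins=4, n_dests=3)
            o = t.origins
            d = t.destinations(o[0])
            cs_a = ConstraintSet(prob_constraints=[(d[0], [o[0], o[1]])])
            cs_b = ConstraintSet(prob_constraints=[(d[1], [o[2], o[3]])])
            cs_both = ConstraintSet(
                prob_constraints=[(d[0], [o[0], o[1]]), (d[1], [o[2], o[3]])]
            )
            frame = compare_structures(
                t, {"a": cs_a, "b": cs_b, "both": cs_both}
            ).frame.set_index("constraint")
            assert frame.loc["both", "delta_aic"] == pytest.approx(
                frame.loc["a", "delta_aic"] + frame.loc["b", "delta_aic"], abs=1e-8
            )

    def test_true_equality_detected_in_most_replicates(self, rng):
        """When the recovery probabilities truly coincide, the equal-parameter
        cell wins that destination's AIC comparison in the large majority of
        replicates (n = 300 per row)."""
        from statemerge import StateSpace, TransitionModel, TruthSpec, simulate_counts

        states = ["well", "mild", "moderate", "severe"]
        P = np.array(
            [
                [1.0, 0.0, 0.0, 0.0],
                [0.30, 0.40, 0.20, 0.10],
                [0.30, 0.20, 0.35, 0.15],
                [0.10, 0.15, 0.25, 0.50],
            ]
        )
        model = TransitionModel(StateSpace(states, absorbing=["well"]), P)
        truth = TruthSpec(
            model=model, n_subjects=900, n_cycles=1,
            init={"mild": 1 / 3, "moderate": 1 / 3, "severe": 1 / 3},
        )
        merge = MergeSpec({"mm": ["mild", "moderate"]})
        wins = 0
        n_reps = 200
        for _ in range(n_reps):
            t = simulate_counts(truth, int(rng.integers(0, 2**31 - 1)))
            per = per_destination_table(t, merge).frame.set_index("constraint")
            if per.loc["mm:well equal"]["delta_aic"] <= 0:
                wins += 1
        assert wins / n_reps >= 0.8


class TestDeriveCounts:
    def test_round_trip_ci_for_published_mi_risk(self):
        """The derived counts for the annual MI risk 0.022 (0.016–0.029)
        reproduce the CI endpoints to within 0.001."""
        s = PublishedRiskSummary("absolute-risk", 0.022, 0.016, 0.029)
        events, denom, diag = derive_counts(s)
        assert events / denom == pytest.approx(0.022, abs=0.001)
        assert diag["ci_low_discrepancy"] < 0.001
        assert diag["ci_high_discrepancy"] < 0.001

    def test_relative_risk_kind_uses_baseline(self):
        s = PublishedRiskSummary("relative-risk", 2.3, 1.9, 2.8, baseline_risk=0.096)
        events, denom, _ = derive_counts(s)
        assert events / denom == pytest.approx(2.3 * 0.096, rel=0.02)

    def test_degenerate_ci_rejected(self):
        with pytest.raises(ValueError):
            derive_counts(PublishedRiskSummary("absolute-risk", 0.5, 0.5, 0.5))

    def test_relative_risk_requires_baseline(self):
        with pytest.raises(ValueError):
            PublishedRiskSummary("relative-risk", 2.0, 1.5, 2.5)
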