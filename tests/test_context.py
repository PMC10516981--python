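"""Expression mapping, iMAT extraction (with an exhaustive-enumeration
oracle), threshold grid search, and model QC."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linprog

from slscan.context import (
    ConstructionReport,
    ExpressionProfile,
    FunctionalityTask,
    NoViableThresholdsError,
    ThresholdPair,
    classify_reactions,
    construction_report,
    default_threshold_grid,
    imat_extract,
    map_expression_to_reactions,
    random_model_benchmark,
    run_functionality_tasks,
    threshold_grid_search,
    verify_context_model,
)
from slscan.context import _imat_milp, IMAT_EPSILON
from slscan.fba import solve_fba
from slscan.fixtures import make_toy_model

PROFILE = ExpressionProfile(
    "cl1", {"g1": 10.0, "g2": 1.0, "g3": 1.0, "g4": 1.0}
)


class TestExpressionMapping:
    def test_and_takes_minimum(self, toy_linear):
        vec = map_expression_to_reactions(
            toy_linear, ExpressionProfile("c", {"gA": 10.0, "gB": 2.0})
        )
        assert vec.values["R1"] == 2.0

    def test_or_takes_maximum(self, toy_parallel):
        vec = map_expression_to_reactions(
            toy_parallel, ExpressionProfile("c", {"g3": 1.0, "g4": 7.0})
        )
        assert vec.values["R2b"] == 7.0

    def test_no_gpr_unmapped(self, toy_parallel):
        vec = map_expression_to_reactions(toy_parallel, PROFILE)
        assert vec.values["EX_A"] is None
        assert vec.values["BIO"] is None

    def test_missing_genes_ignored_within_rule(self, toy_parallel):
        # g4 absent from profile: OR falls back to g3's value
        vec = map_expression_to_reactions(
            toy_parallel, ExpressionProfile("c", {"g3": 3.0})
        )
        assert vec.values["R2b"] == 3.0
        assert vec.values["R1"] is None  # wholly missing rule -> unmapped


class TestClassification:
    @pytest.mark.parametrize(
        "value,expected",
        [(7.0, "high"), (5.0, "high"), (1.0, "low"), (2.0, "low"), (3.0, "moderate")],
    )
    def test_boundaries(self, value, expected):
        from slscan.context import ReactionExpressionVector

        vec = ReactionExpressionVector(values={"r": value})
        assert classify_reactions(vec, ThresholdPair(2, 5))["r"] == expected

    def test_unmapped_is_moderate(self):
        from slscan.context import ReactionExpressionVector

        vec = ReactionExpressionVector(values={"r": None})
        assert classify_reactions(vec, ThresholdPair(2, 5))["r"] == "moderate"

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ThresholdPair(5, 2)


def enumeration_imat_score(model, classes, epsilon):
    """Independent iMAT oracle: enumerate every on/off assignment of the
    high/low indicator variables and check LP feasibility directly."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    l, u = model.bounds_arrays()
    idx = {rid: j for j, rid in enumerate(rxn_ids)}
    high = [r for r in rxn_ids if classes.get(r) == "high"]
    low = [r for r in rxn_ids if classes.get(r) == "low"]
    best = -1
    for h_on in itertools.product([0, 1], repeat=len(high)):
        for l_off in itertools.product([0, 1], repeat=len(low)):
            lo, hi = l.copy(), u.copy()
            for r, on in zip(high, h_on):
                if on:  # force forward flux >= epsilon (toys irreversible)
                    lo[idx[r]] = max(lo[idx[r]], epsilon)
            for r, off in zip(low, l_off):
                if off:
                    lo[idx[r]] = hi[idx[r]] = 0.0
            res = linprog(
                np.zeros(len(rxn_ids)),
                A_eq=S,
                b_eq=np.zeros(S.shape[0]),
                bounds=list(zip(lo, hi)),
                method="highs",
            )
            if res.status == 0:
                best = max(best, sum(h_on) + sum(l_off))
    return best


class TestImatExtract:
    def test_toy_parallel_drops_silent_branch(self, toy_parallel):
        vec = map_expression_to_reactions(toy_parallel, PROFILE)
        classes = classify_reactions(vec, ThresholdPair(2, 5))
        ctx = imat_extract(toy_parallel, classes, core={"BIO", "EX_A"})
        assert set(ctx.reaction_ids) == {"EX_A", "R1", "BIO"}
        assert set(ctx.metabolites) == {"A", "B"}  # orphan C pruned

    def test_all_high_is_identity_on_reactions(self, toy_parallel):
        classes = {r.id: "high" for r in toy_parallel.reactions}
        core = {r.id for r in toy_parallel.reactions}
        ctx = imat_extract(toy_parallel, classes, core=core)
        assert set(ctx.reaction_ids) == set(toy_parallel.reaction_ids)

    def test_core_must_contain_objective(self, toy_parallel):
        with pytest.raises(ValueError):
            imat_extract(toy_parallel, {}, core={"EX_A"})

    def test_biomass_always_in_output(self, toy_parallel):
        classes = {r.id: "low" for r in toy_parallel.reactions}
        ctx = imat_extract(toy_parallel, classes, core={"BIO"})
        assert "BIO" in ctx.reaction_ids

    @pytest.mark.parametrize("toy", ["parallel", "linear", "branched"])
    @pytest.mark.parametrize("thresholds", [(2, 5), (0.5, 11)])
    def test_milp_matches_exhaustive_enumeration(self, toy, thresholds):
        model = make_toy_model(toy)
        profile = ExpressionProfile(
            "c", {g: (10.0 if g in ("g1", "gA", "gB", "g7") else 1.0) for g in model.genes}
        )
        classes = classify_reactions(
            map_expression_to_reactions(model, profile), ThresholdPair(*thresholds)
        )
        _v, milp_score = _imat_milp(model, classes, IMAT_EPSILON)
        assert milp_score == pytest.approx(
            enumeration_imat_score(model, classes, IMAT_EPSILON), abs=1e-6
        )


class TestThresholdGridSearch:
    def test_first_viable_pair_wins(self, toy_parallel):
        # (11, 12): everything low/moderate -> extraction silences the
        # network -> zero biomass; (2, 5) succeeds
        thr, ctx = threshold_grid_search(
            toy_parallel, PROFILE, grid=[ThresholdPair(11, 12), ThresholdPair(2, 5)]
        )
        assert thr == ThresholdPair(2, 5)
        assert solve_fba(ctx).objective_value > 1e-6

    def test_single_viable_pair(self, toy_parallel):
        thr, _ = threshold_grid_search(toy_parallel, PROFILE, grid=[ThresholdPair(2, 5)])
        assert thr == ThresholdPair(2, 5)

    def test_exhausted_grid_raises(self, toy_parallel):
        with pytest.raises(NoViableThresholdsError):
            threshold_grid_search(toy_parallel, PROFILE, grid=[ThresholdPair(11, 12)])

    def test_default_grid_order_and_bounds(self, toy_parallel):
        vec = map_expression_to_reactions(toy_parallel, PROFILE)
        grid = default_threshold_grid(vec)
        assert len(grid) == 5
        assert all(p.lb <= p.ub for p in grid)

    def test_returned_model_grows(self, toy_parallel):
        _, ctx = threshold_grid_search(toy_parallel, PROFILE)
        assert solve_fba(ctx).objective_value > 1e-6


class TestVerifyContextModel:
    def test_parallel_fully_consistent(self, toy_parallel):
        rep = verify_context_model(toy_parallel)
        assert rep.blocked_reactions == []
        assert rep.biomass_value == pytest.approx(10.0)
        assert rep.consistent

    def test_dangling_reaction_blocked(self, toy_parallel):
        from slscan.model import Metabolite, Reaction

        toy_parallel.metabolites["X"] = Metabolite("X")
        toy_parallel.reactions.append(Reaction("D", {"B": -1.0, "X": 1.0}, 0, 1000))
        rep = verify_context_model(toy_parallel)
        assert rep.blocked_reactions == ["D"]
        assert not rep.consistent

    def test_missing_objective_flagged(self, toy_parallel):
        for r in toy_parallel.reactions:
            r.objective_coefficient = 0.0
        rep = verify_context_model(toy_parallel)
        assert rep.structural_problems
        assert not rep.consistent


class TestFunctionalityTasks:
    def test_produce_b_from_a_passes(self, toy_parallel):
        assert run_functionality_tasks(
            toy_parallel, [FunctionalityTask("t", ["A"], "B")]
        ) == 1

    def test_absent_target_fails(self, toy_parallel):
        assert run_functionality_tasks(
            toy_parallel, [FunctionalityTask("t", ["A"], "D")]
        ) == 0

    def test_empty_task_list(self, toy_parallel):
        assert run_functionality_tasks(toy_parallel, []) == 0

    def test_inputs_restricted_to_task(self, toy_parallel):
        # without importing A nothing can be made
        assert run_functionality_tasks(
            toy_parallel, [FunctionalityTask("t", [], "B")]
        ) == 0


class TestRandomBenchmark:
    TASKS = [FunctionalityTask("t1", ["A"], "B"), FunctionalityTask("t2", ["A"], "C")]

    def test_returns_n_counts(self, toy_parallel):
        counts = random_model_benchmark(toy_parallel, 4, self.TASKS, n=100, seed=5)
        assert len(counts) == 100

    def test_reproducible(self, toy_parallel):
        a = random_model_benchmark(toy_parallel, 4, self.TASKS, n=10, seed=5)
        b = random_model_benchmark(toy_parallel, 4, self.TASKS, n=10, seed=5)
        assert a == b

    def test_size_validation(self, toy_parallel):
        with pytest.raises(ValueError):
            random_model_benchmark(toy_parallel, 99, self.TASKS, n=1, seed=0)


class TestConstructionReport:
    def test_success_when_all_randoms_exceeded(self):
        rep = ConstructionReport(
            passed_tasks=5, random_pass_counts=[4] * 100,
            blocked_reactions=[], biomass_value=1.0,
        )
        assert rep.success

    def test_failure_at_98_of_100(self):
        rep = ConstructionReport(
            passed_tasks=3, random_pass_counts=[2] * 98 + [4, 4],
            blocked_reactions=[], biomass_value=1.0,
        )
        assert not rep.success

    def test_full_report_on_toy(self, toy_parallel):
        rep = construction_report(
            toy_parallel, toy_parallel,
            tasks=[FunctionalityTask("t", ["A"], "B")],
            n_random=10, seed=3,
        )
        assert rep.passed_tasks == 1
        assert len(rep.random_pass_counts) == 10
        assert rep.biomass_value == pytest.approx(10.0)
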