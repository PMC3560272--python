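"""Optimization and enumeration: published toy results, caps, determinism,
oracle equivalence and backend agreement."""

import pytest

from emcut.builder import build_base_problem
from emcut.core import BLPProblem, BinaryEM, EMPartition, LinearConstraint
from emcut.io import generate_random_instance
from emcut.oracle import brute_force_mcs
from emcut.solver import delta_min, enumerate_mcs, solve


class TestSolve:
    def test_toy_optimum_deletes_r2_r9(self, toy_partition, uniform):
        sol = solve(build_base_problem(toy_partition, uniform))
        assert sol.reaction_deletions == {"R2", "R9"}
        assert sol.objective_value == pytest.approx(10.0)

    def test_contradictory_equalities_infeasible(self):
        p = BLPProblem()
        p.add_variable("x:a", "reaction")
        p.reaction_ids = ("a",)
        p.set_objective_coeff("x:a", 1.0)
        p.add_constraint(LinearConstraint.from_mapping({"x:a": 1}, lower=1, upper=1))
        p.add_constraint(LinearConstraint.from_mapping({"x:a": 1}, lower=0, upper=0))
        assert solve(p) is None

    def test_weighted_kill_row_deletes_cheapest(self):
        part = EMPartition(("R1", "R2"), kill=(BinaryEM("k", (1, 1)),))
        sol = solve(build_base_problem(part, {"R1": 1.0, "R2": 5.0}))
        assert sol.reaction_deletions == {"R1"}

    def test_unknown_backend_rejected(self, toy_partition, uniform):
        with pytest.raises(ValueError, match="backend"):
            solve(build_base_problem(toy_partition, uniform), backend="gurobi")


class TestEnumerateUnweighted:
    def test_toy_full_mcs_set(self, toy_partition, uniform, toy_mcs_sets):
        res = enumerate_mcs(toy_partition, uniform)
        assert res.exhausted
        assert {s.reaction_deletions for s in res.solutions} == toy_mcs_sets
        assert res.solutions[0].reaction_deletions == {"R2", "R9"}
        assert res.delta_min == 2

    def test_objectives_non_increasing(self, toy_partition, uniform):
        res = enumerate_mcs(toy_partition, uniform)
        objs = [s.objective_value for s in res.solutions]
        assert objs == sorted(objs, reverse=True)

    def test_enumeration_is_deterministic(self, toy_partition, uniform):
        a = enumerate_mcs(toy_partition, uniform)
        b = enumerate_mcs(toy_partition, uniform)
        assert [s.reaction_deletions for s in a.solutions] == [
            s.reaction_deletions for s in b.solutions
        ]

    def test_max_solutions_cap_marks_not_exhausted(self, toy_partition, uniform):
        res = enumerate_mcs(toy_partition, uniform, max_solutions=2)
        assert len(res.solutions) == 2 and not res.exhausted

    def test_min_objective_cap(self, toy_partition, uniform):
        # only the two-deletion optimum clears an objective floor of 10
        res = enumerate_mcs(toy_partition, uniform, min_objective=10.0)
        assert len(res.solutions) == 1 and not res.exhausted

    def test_infeasible_design_reports_conflicts(self):
        part = EMPartition(
            ("R1", "R2"),
            goal=(BinaryEM("g", (1, 1)),),
            kill=(BinaryEM("k", (1, 0)),),
        )
        res = enumerate_mcs(part, {"R1": 1, "R2": 1})
        assert res.solutions == [] and res.delta_min is None
        assert res.conflicts == ["k"]

    def test_empty_kill_yields_single_empty_solution(self):
        part = EMPartition(("R1",), goal=(BinaryEM("g", (1,)),))
        res = enumerate_mcs(part, {"R1": 1})
        assert len(res.solutions) == 1
        assert res.solutions[0].interventions == frozenset()
        assert res.exhausted and res.delta_min == 0


class TestEnumerateWeighted:
    def test_w2_ranking(self, toy_partition, feas_weights):
        res = enumerate_mcs(toy_partition, feas_weights)
        patterns = [s.reaction_deletions for s in res.solutions]
        # the two fully implementable designs come first (tie order free)
        assert set(patterns[:2]) == {
            frozenset({"R2", "R5", "R10"}),
            frozenset({"R2", "R10", "R11"}),
        }
        # the cheap-but-unimplementable {R2,R9} outranks the two solutions
        # that touch the doubly-unannotated R6
        assert patterns[2] == frozenset({"R2", "R9"})
        assert set(patterns[3:]) == {
            frozenset({"R2", "R5", "R6"}),
            frozenset({"R2", "R6", "R11"}),
        }
        # weighting reorders but never changes the solution set
        assert set(patterns) == {s for s in set(patterns)}
        assert res.delta_min == 2

    def test_weight_scaling_preserves_order(self, toy_partition, feas_weights):
        scaled = {r: 10 * w for r, w in feas_weights.items()}
        a = enumerate_mcs(toy_partition, feas_weights)
        b = enumerate_mcs(toy_partition, scaled)
        assert [s.reaction_deletions for s in a.solutions] == [
            s.reaction_deletions for s in b.solutions
        ]


class TestEnumerateRegulated:
    def test_regulated_solution_set(self, toy_partition, feas_weights, toy_rules):
        res = enumerate_mcs(toy_partition, feas_weights, rules=toy_rules)
        assert res.exhausted and len(res.solutions) == 4
        interventions = {
            (frozenset(s.gene_deletions), frozenset(s.reaction_deletions))
            for s in res.solutions
        }
        assert interventions == {
            (frozenset({"GR2", "GR5a"}), frozenset()),
            (frozenset({"GR2", "GR5b"}), frozenset()),
            (frozenset({"GR2", "GR11"}), frozenset()),
            (frozenset({"GR2"}), frozenset({"R9"})),
        }

    def test_r10_is_regulation_forced_not_deleted(self, toy_partition, feas_weights, toy_rules):
        res = enumerate_mcs(toy_partition, feas_weights, rules=toy_rules)
        for sol in res.solutions:
            assert sol.regulation_forced_off == {"R10"}
            assert "R10" not in sol.reaction_deletions

    def test_regulation_collapses_reaction_patterns(self, toy_partition, feas_weights,
                                                    toy_rules):
        # five unregulated reaction-level MCS collapse to three distinct
        # reaction patterns once R10 is always suppressed
        res = enumerate_mcs(toy_partition, feas_weights, rules=toy_rules)
        assert len({s.reaction_pattern for s in res.solutions}) == 3

    def test_gene_level_delta_min(self, toy_partition, feas_weights, toy_rules):
        res = enumerate_mcs(toy_partition, feas_weights, rules=toy_rules)
        assert res.delta_min == 2
        for sol in res.solutions:
            if not sol.reaction_deletions:  # the implementable designs
                assert len(sol.gene_deletions) == 2

    def test_side_constraints_restrict_solutions(self, toy_partition, uniform):
        # forbid keeping both R5 and R11 on top of the base design
        side = [LinearConstraint.from_mapping({"R5": 1, "R11": 1}, upper=1)]
        res = enumerate_mcs(toy_partition, uniform, side_constraints=side)
        for sol in res.solutions:
            assert not {"R5", "R11"} <= sol.kept_reactions


class TestDeltaMin:
    def test_toy(self, toy_partition, uniform):
        res = enumerate_mcs(toy_partition, uniform)
        assert delta_min(res, toy_partition.n) == 2

    def test_empty_kill(self):
        part = EMPartition(("R1",), goal=(BinaryEM("g", (1,)),))
        res = enumerate_mcs(part, {"R1": 1})
        assert delta_min(res, 1) == 0

    def test_single_disjoint_kill_mode(self):
        part = EMPartition(
            ("R1", "R2"),
            goal=(BinaryEM("g", (1, 0)),),
            kill=(BinaryEM("k", (0, 1)),),
        )
        res = enumerate_mcs(part, {"R1": 1, "R2": 1})
        assert delta_min(res, 2) == 1

    def test_empty_result_rejected(self):
        from emcut.core import MCSResult

        with pytest.raises(ValueError, match="empty result"):
            delta_min(MCSResult(None, [], True), 5)


class TestBackendAgreement:
    @pytest.mark.parametrize("which", ["uniform", "feas_weights", "regulated"])
    def test_backends_return_identical_solution_sets(
        self, toy_partition, uniform, feas_weights, toy_rules, which
    ):
        kwargs = {
            "uniform": dict(weights=uniform),
            "feas_weights": dict(weights=feas_weights),
            "regulated": dict(weights=feas_weights, rules=toy_rules),
        }[which]
        builtin = enumerate_mcs(toy_partition, backend="builtin", **kwargs)
        highs = enumerate_mcs(toy_partition, backend="highs", **kwargs)
        assert {s.interventions for s in builtin.solutions} == {
            s.interventions for s in highs.solutions
        }


class TestOracleEquivalenceSpotChecks:
    @pytest.mark.parametrize("seed", range(12))
    def test_random_instances_match_brute_force(self, seed):
        inst = generate_random_instance(n_reactions=10, n_modes=12, seed=seed)
        res = enumerate_mcs(
            inst.partition, {r: 1.0 for r in inst.partition.reaction_ids}
        )
        assert {s.interventions for s in res.solutions} == brute_force_mcs(
            inst.partition
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_deletion_patterns_form_an_antichain(self, seed):
        inst = generate_random_instance(n_reactions=12, n_modes=15, seed=100 + seed)
        res = enumerate_mcs(
            inst.partition, {r: 1.0 for r in inst.partition.reaction_ids}
        )
        pats = [s.interventions for s in res.solutions]
        for i, a in enumerate(pats):
            for b in pats[i + 1:]:
                assert not (a <= b or b <= a)
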