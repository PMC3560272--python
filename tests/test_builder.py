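"""BLP assembly: base rows, hitting-set reduction, exclusion cuts, survivor
indicators and side constraints."""

import itertools

import pytest

from emcut.builder import (
    add_exclusion,
    add_side_constraint,
    add_survivor_indicators,
    build_base_problem,
    reduce_to_hitting_set,
)
from emcut.core import BinaryEM, EMPartition, LinearConstraint, pvar, xvar
from emcut.io import generate_random_instance
from emcut.oracle import brute_force_mcs
from emcut.solver import solve


class TestBuildBaseProblem:
    def test_toy_rows(self, toy_partition, uniform):
        problem = build_base_problem(toy_partition, uniform)
        goal = [c for c in problem.constraints if c.tag == "goal"]
        kill = [c for c in problem.constraints if c.tag == "kill"]
        assert len(goal) == 1 and goal[0].lower == goal[0].upper == 5
        assert [c.upper for c in kill] == [7, 5, 3, 5, 6]
        assert all(c.lower is None for c in kill)
        # helper rows are skipped by default (they never constrain)
        assert not [c for c in problem.constraints if c.tag == "helper"]

    def test_helper_rows_on_request(self, toy_partition, uniform):
        problem = build_base_problem(toy_partition, uniform, include_helper_rows=True)
        helper = [c for c in problem.constraints if c.tag == "helper"]
        assert [c.upper for c in helper] == [3, 5, 6]

    def test_objective_is_weighted_maximization(self, toy_partition, feas_weights):
        problem = build_base_problem(toy_partition, feas_weights)
        assert problem.sense == "max"
        assert problem.objective[xvar("R4")] == 99.0

    def test_empty_kill_optimum_keeps_everything(self):
        part = EMPartition(("R1", "R2"), goal=(BinaryEM("g", (1, 0)),))
        sol = solve(build_base_problem(part, {"R1": 1, "R2": 1}))
        assert sol.kept_reactions == {"R1", "R2"}

    def test_goal_covering_all_reactions_with_kill_is_infeasible(self):
        part = EMPartition(
            ("R1", "R2"),
            goal=(BinaryEM("g", (1, 1)),),
            kill=(BinaryEM("k", (1, 0)),),
        )
        assert solve(build_base_problem(part, {"R1": 1, "R2": 1})) is None

    def test_nonpositive_weight_rejected(self, toy_partition, uniform):
        bad = dict(uniform, R5=0.0)
        with pytest.raises(ValueError, match="positive"):
            build_base_problem(toy_partition, bad)

    def test_zero_norm_kill_rejected(self):
        part = EMPartition(("R1",), kill=(BinaryEM("k", (0,)),))
        with pytest.raises(ValueError, match="empty support"):
            build_base_problem(part, {"R1": 1})


class TestReduceToHittingSet:
    def test_toy_reduction(self, toy_partition):
        red = reduce_to_hitting_set(toy_partition)
        assert {frozenset(r) for r in red.rows} == {
            frozenset({"R2"}),
            frozenset({"R5", "R9", "R11"}),
            frozenset({"R6", "R9", "R10"}),
        }
        assert red.feasible
        # goal reactions and reactions in no surviving row are provably kept
        assert {"R1", "R4", "R7", "R8", "R12"} <= set(red.fixed_one) | \
            toy_partition.goal_union()
        assert "R3" in red.fixed_one

    def test_forced_zero_drops_hit_rows(self, toy_partition):
        red = reduce_to_hitting_set(toy_partition, forced_zero={"R10"})
        assert {frozenset(r) for r in red.rows} == {
            frozenset({"R2"}),
            frozenset({"R5", "R9", "R11"}),
        }

    def test_kill_inside_goal_union_is_a_conflict(self):
        part = EMPartition(
            ("R1", "R2", "R3"),
            goal=(BinaryEM("g", (1, 1, 0)),),
            kill=(BinaryEM("k", (1, 0, 0)),),
        )
        red = reduce_to_hitting_set(part)
        assert red.conflicts == ["k"]
        assert not red.feasible

    def test_unknown_forced_zero_rejected(self, toy_partition):
        with pytest.raises(ValueError, match="unknown"):
            reduce_to_hitting_set(toy_partition, forced_zero={"nope"})

    def test_dominance_removal_preserves_minimal_hitting_sets(self):
        # the minimal hitting sets of the reduced rows must equal the
        # minimal cut sets computed without any dominance removal
        for seed in range(30):
            inst = generate_random_instance(8, 10, seed=seed)
            if not inst.feasible:
                continue
            part = inst.partition
            red = reduce_to_hitting_set(part)
            rows = [set(r) for r in red.rows]
            universe = sorted(set().union(*rows)) if rows else []
            hitting = []
            for k in range(len(universe) + 1):
                for combo in itertools.combinations(universe, k):
                    s = set(combo)
                    if any(set(h) <= s for h in hitting):
                        continue
                    if all(r & s for r in rows):
                        hitting.append(frozenset(s))
            assert set(hitting) == brute_force_mcs(part), f"seed {seed}"


class TestFeasibleSetCharacterization:
    def test_base_problem_feasible_set_equals_hitting_set_form(self):
        # exhaustive over all 2^n assignments for small random partitions:
        # x is feasible iff all goal reactions are kept and the deleted set
        # hits every reduced kill row
        for seed in range(10):
            inst = generate_random_instance(8, 8, seed=seed)
            part = inst.partition
            problem = build_base_problem(part, {r: 1.0 for r in part.reaction_ids})
            goal_union = part.goal_union()
            red = reduce_to_hitting_set(part)
            for bits in itertools.product((0, 1), repeat=part.n):
                assign = {xvar(r): b for r, b in zip(part.reaction_ids, bits)}
                feasible = all(c.satisfied_by(assign) for c in problem.constraints)
                deleted = {r for r, b in zip(part.reaction_ids, bits) if not b}
                expected = (
                    not (goal_union & deleted)
                    and red.feasible
                    and all(set(row) & deleted for row in red.rows)
                )
                assert feasible == expected, (seed, bits)


class TestAddExclusion:
    def test_toy_exclusion_pair(self, toy_partition, uniform):
        problem = build_base_problem(toy_partition, uniform)
        sol = solve(problem)
        assert sol.reaction_deletions == {"R2", "R9"}
        add_exclusion(problem, sol)
        cuts = [c for c in problem.constraints if c.tag == "exclusion"]
        assert len(cuts) == 2
        subset_cut, superset_cut = cuts
        assert subset_cut.upper == 9 and len(subset_cut.coefficients) == 10
        assert superset_cut.lower == 1
        assert {v for v, _ in superset_cut.coefficients} == {xvar("R2"), xvar("R9")}

    def test_resolving_avoids_subsets_and_supersets(self, toy_partition, uniform):
        problem = build_base_problem(toy_partition, uniform)
        first = solve(problem)
        add_exclusion(problem, first)
        second = solve(problem)
        d1, d2 = first.reaction_deletions, second.reaction_deletions
        assert not (d1 <= d2 or d2 <= d1)

    def test_nothing_deleted_is_an_error(self):
        part = EMPartition(("R1",), goal=(BinaryEM("g", (1,)),))
        problem = build_base_problem(part, {"R1": 1})
        sol = solve(problem)
        with pytest.raises(ValueError, match="nothing to exclude"):
            add_exclusion(problem, sol)


class TestSurvivorIndicators:
    @pytest.mark.parametrize("norm", [1, 3])
    def test_indicator_tracks_full_support(self, norm):
        rids = tuple(f"R{i}" for i in range(norm))
        part = EMPartition(rids, helper=(BinaryEM("h", (1,) * norm),))
        problem = build_base_problem(part, {r: 1.0 for r in rids})
        add_survivor_indicators(problem, part.helper)
        cons = [c for c in problem.constraints if c.tag == "survivor"]
        for bits in itertools.product((0, 1), repeat=norm + 1):
            assign = {xvar(r): b for r, b in zip(rids, bits[:-1])}
            assign[pvar("h")] = bits[-1]
            admitted = all(c.satisfied_by(assign) for c in cons)
            assert admitted == (bits[-1] == int(all(bits[:-1])))


class TestSideConstraints:
    def test_mutual_exclusion_resolves_bare_names(self, toy_partition, uniform):
        problem = build_base_problem(toy_partition, uniform)
        add_side_constraint(
            problem, LinearConstraint.from_mapping({"R1": 1, "R2": 1}, upper=1)
        )
        added = problem.constraints[-1]
        assert {v for v, _ in added.coefficients} == {xvar("R1"), xvar("R2")}
        assert added.tag == "side"

    def test_vacuous_bounds_accepted(self, toy_partition, uniform):
        problem = build_base_problem(toy_partition, uniform)
        add_side_constraint(
            problem, LinearConstraint.from_mapping({"R1": 1}, lower=0, upper=1)
        )
        assert solve(problem) is not None

    def test_unknown_variable_rejected(self, toy_partition, uniform):
        problem = build_base_problem(toy_partition, uniform)
        with pytest.raises(ValueError, match="unknown variable"):
            add_side_constraint(
                problem, LinearConstraint.from_mapping({"R99": 1}, upper=1)
            )
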