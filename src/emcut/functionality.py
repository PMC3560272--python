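"""Optimization of surviving metabolic functionality.

Minimal cut sets with equal intervention counts can leave very different
residual networks: helper modes may or may not survive the deletions.  This
module optimizes the *number of surviving helper modes* directly — one binary
survivor indicator per helper mode, linked to the reaction variables — so the
smallest or largest residual functionality is found without enumerating the
whole solution space.  With an empty goal class the same machinery yields the
maximum number of preservable modes from a pool, an upper bound on the
"keep at least n desired modes" parameter of constrained-MCS formulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

from .builder import (
    WeightsLike,
    add_survivor_indicators,
    build_base_problem,
)
from .core import (
    BLPProblem,
    BinaryEM,
    EMPartition,
    GeneRule,
    LinearConstraint,
    SolutionRecord,
    pvar,
    xvar,
)
from .regulation import attach_regulation
from .solver import solve


class InfeasibleDesign(ValueError):
    """The base design constraints admit no solution."""


@dataclass
class SurvivorResult:
    """Outcome of a survivor optimization."""

    n_survivors: int
    solution: SolutionRecord
    p_assignment: Dict[str, int]  # helper mode id -> survivor indicator


def optimize_survivors(partition: EMPartition, weights: WeightsLike,
                       rules: Optional[Sequence[GeneRule]] = None,
                       sense: str = "max",
                       fixed_deletion_budget: Optional[int] = None,
                       backend: str = "builtin") -> SurvivorResult:
    """Minimize or maximize the number of surviving helper modes.

    The objective is lexicographic: first the survivor count (in the
    requested sense), then the weighted kept-reaction objective to break ties
    toward the cheapest interventions — implemented as two solves with the
    first optimum fixed by a constraint.  ``fixed_deletion_budget`` pins the
    number of interventions (over the deletion-decision vector), e.g. to
    compare equal-size cut sets.
    """
    if sense not in ("min", "max"):
        raise ValueError(f"sense must be 'min' or 'max', got {sense!r}")
    if not partition.helper:
        raise ValueError("no helper modes: nothing to optimize")
    problem = build_base_problem(partition, weights, include_helper_rows=False)
    if rules:
        attach_regulation(problem, rules)
    add_survivor_indicators(problem, partition.helper)
    if fixed_deletion_budget is not None:
        nz = len(problem.deletion_vars)
        if not 0 <= fixed_deletion_budget <= nz:
            raise ValueError(
                f"deletion budget {fixed_deletion_budget} outside [0, {nz}]"
            )
        problem.add_constraint(
            LinearConstraint.from_mapping(
                {v: 1 for v in problem.deletion_vars},
                lower=nz - fixed_deletion_budget,
                upper=nz - fixed_deletion_budget,
                tag="side",
            )
        )

    p_vars = [pvar(em.mode_id) for em in partition.helper]

    # pass 1: survivor count only
    pass1 = problem.copy()
    pass1.sense = sense
    pass1.objective = {pv: 1.0 for pv in p_vars}
    sol1 = solve(pass1, backend=backend)
    if sol1 is None:
        raise InfeasibleDesign(
            "base design constraints are infeasible; shift modes out of the goal class"
        )
    count = sum(sol1.raw_assignment[pv] for pv in p_vars)

    # pass 2: fix the survivor count, break ties by the weighted objective
    pass2 = problem.copy()
    pass2.add_constraint(
        LinearConstraint.from_mapping(
            {pv: 1 for pv in p_vars}, lower=count, upper=count, tag="survivor"
        )
    )
    sol2 = solve(pass2, backend=backend)
    assert sol2 is not None  # pass 1 found a witness with this count
    p_assignment = {
        em.mode_id: sol2.raw_assignment[pvar(em.mode_id)] for em in partition.helper
    }
    return SurvivorResult(n_survivors=count, solution=sol2, p_assignment=p_assignment)


def max_preservable(kill: Sequence[BinaryEM], pool: Sequence[BinaryEM],
                    weights: Optional[WeightsLike] = None,
                    reaction_ids: Optional[Sequence[str]] = None,
                    backend: str = "builtin") -> int:
    """Maximum number of pool modes that can survive while all kill modes die.

    No goal class is involved: the only constraints are the kill rows.  The
    returned count upper-bounds the number of desired modes any constrained
    cut set can preserve.  ``weights`` is accepted for interface symmetry and
    tie-breaking of the witness but cannot change the count.
    """
    if not pool:
        return 0
    n = len((kill[0] if kill else pool[0]).support)
    if reaction_ids is None:
        reaction_ids = tuple(f"v{i + 1}" for i in range(n))
    partition = EMPartition(
        reaction_ids=tuple(reaction_ids), goal=(), kill=tuple(kill), helper=tuple(pool)
    )
    if weights is None:
        weights = {r: 1.0 for r in partition.reaction_ids}
    problem = build_base_problem(partition, weights, include_helper_rows=False)
    add_survivor_indicators(problem, partition.helper)
    problem.objective = {pvar(em.mode_id): 1.0 for em in partition.helper}
    sol = solve(problem, backend=backend)
    if sol is None:
        raise InfeasibleDesign("kill constraints are infeasible")
    return int(
        sum(sol.raw_assignment[pvar(em.mode_id)] for em in partition.helper)
    )
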