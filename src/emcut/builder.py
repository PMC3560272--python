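"""Assembly of the cut-set BLP: base constraints, exclusion cuts, survivor
indicators, side constraints, and the hitting-set preprocessing reduction.

The base program maximizes the weighted number of retained reactions subject
to one equality per goal mode (its full support must be kept) and one
inequality per kill mode (its support must lose at least one reaction).
Helper rows never constrain the feasible set and are skipped by default; a
flag re-enables them for completeness audits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Union

from .core import (
    BLPProblem,
    BinaryEM,
    EMPartition,
    LinearConstraint,
    SolutionRecord,
    pvar,
    xvar,
    yvar,
)

WeightsLike = Union[Mapping[str, float], Sequence[float]]


def normalize_weights(partition_or_ids, weights: WeightsLike) -> Dict[str, float]:
    """Return a reaction-id keyed weight dict; validate positivity/coverage."""
    rids = getattr(partition_or_ids, "reaction_ids", partition_or_ids)
    if isinstance(weights, Mapping):
        wmap = {r: float(weights[r]) for r in rids if r in weights}
        missing = [r for r in rids if r not in weights]
        if missing:
            raise ValueError(f"weights missing for reactions {missing}")
    else:
        ws = list(weights)
        if len(ws) != len(rids):
            raise ValueError(
                f"weights length {len(ws)} does not match {len(rids)} reactions"
            )
        wmap = {r: float(w) for r, w in zip(rids, ws)}
    for r, w in wmap.items():
        if not w > 0:
            raise ValueError(f"weight for {r!r} must be positive, got {w}")
    return wmap


def build_base_problem(partition: EMPartition, weights: WeightsLike,
                       include_helper_rows: bool = False) -> BLPProblem:
    """Build the weighted base BLP for a goal/kill/helper partition.

    Objective: maximize sum(w_i * x_i).  Constraints: ``e^T x == ||e||`` per
    goal row, ``e^T x <= ||e|| - 1`` per kill row, and (optionally)
    ``e^T x <= ||e||`` per helper row.

    Raises
    ------
    ValueError
        For nonpositive weights or a kill row of norm zero (such a mode can
        never be cut).
    """
    wmap = normalize_weights(partition, weights)
    problem = BLPProblem(sense="max")
    problem.reaction_ids = partition.reaction_ids
    for r in partition.reaction_ids:
        problem.add_variable(xvar(r), "reaction")
        problem.set_objective_coeff(xvar(r), wmap[r])
    problem.deletion_vars = [xvar(r) for r in partition.reaction_ids]

    def row_coeffs(em: BinaryEM) -> Dict[str, int]:
        return {xvar(partition.reaction_ids[i]): 1 for i in em.active_indices()}

    for em in partition.goal:
        problem.add_constraint(
            LinearConstraint.from_mapping(
                row_coeffs(em), lower=em.norm, upper=em.norm, tag="goal"
            )
        )
    for em in partition.kill:
        if em.norm == 0:
            raise ValueError(
                f"kill mode {em.mode_id!r} has empty support and cannot be cut"
            )
        problem.add_constraint(
            LinearConstraint.from_mapping(
                row_coeffs(em), upper=em.norm - 1, tag="kill"
            )
        )
    if include_helper_rows:
        for em in partition.helper:
            problem.add_constraint(
                LinearConstraint.from_mapping(
                    row_coeffs(em), upper=em.norm, tag="helper"
                )
            )
    return problem


@dataclass
class HittingSetReduction:
    """Outcome of the preprocessing reduction to a minimal-hitting-set problem.

    ``rows`` are the reduced kill supports (reaction-id frozensets) after
    removing goal-fixed reactions, rows already hit by ``forced_zero``, and
    dominated (superset) rows; ``fixed_one`` are reactions provably kept in
    every solution; ``conflicts`` lists kill modes whose reduced row is empty
    — the design is infeasible unless modes are shifted out of the goal class.
    """

    rows: List[frozenset]
    row_modes: List[str]
    fixed_one: frozenset
    fixed_zero: frozenset
    conflicts: List[str] = field(default_factory=list)

    @property
    def feasible(self) -> bool:
        return not self.conflicts


def reduce_to_hitting_set(partition: EMPartition,
                          forced_zero: Iterable[str] = ()) -> HittingSetReduction:
    """Reduce the cut-set problem to minimal hitting sets of kill supports.

    Every reaction in a goal support is fixed to 1; each kill support is
    stripped of goal-fixed reactions; rows already hit by ``forced_zero`` are
    dropped; rows that are supersets of other rows are dropped (hitting the
    subset hits the superset); reactions occurring in no surviving row are
    fixed to 1.  Empty reduced rows are reported as irreducible conflicts,
    never raised.
    """
    fz = frozenset(forced_zero)
    unknown = fz - set(partition.reaction_ids)
    if unknown:
        raise ValueError(f"forced_zero references unknown reactions {sorted(unknown)}")
    goal_fixed = partition.goal_union()
    conflicts: List[str] = []
    reduced: List[frozenset] = []
    modes: List[str] = []
    for em in partition.kill:
        supp = em.active_reactions(partition.reaction_ids)
        row = supp - goal_fixed
        if not row:
            conflicts.append(em.mode_id)
            continue
        if row & fz:
            continue  # already hit by an externally imposed zero
        reduced.append(row)
        modes.append(em.mode_id)
    # dominance removal: drop any row that strictly contains another row,
    # and collapse duplicates (keep first occurrence)
    keep: List[int] = []
    for i, row in enumerate(reduced):
        dominated = False
        for j, other in enumerate(reduced):
            if i == j:
                continue
            if other < row or (other == row and j < i):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    rows = [reduced[i] for i in keep]
    row_modes = [modes[i] for i in keep]
    covered = set().union(*rows) if rows else set()
    fixed_one = frozenset(
        r for r in partition.reaction_ids if r not in covered and r not in fz
    )
    return HittingSetReduction(
        rows=rows,
        row_modes=row_modes,
        fixed_one=fixed_one,
        fixed_zero=fz,
        conflicts=conflicts,
    )


def add_exclusion(problem: BLPProblem, previous: SolutionRecord) -> BLPProblem:
    """Exclude one solution and all of its supersets from future solves.

    Over the deletion-decision vector z (``problem.deletion_vars``), adds
    ``sum_{i in B} z_i <= |B| - 1`` (the kept set B may not recur in full:
    no subsets of the previous deletion set) and ``sum_{i in N} z_i >= 1``
    (at least one previously deleted variable must be kept: no supersets).
    """
    values = _deletion_values(problem, previous)
    B = [v for v in problem.deletion_vars if values[v] == 1]
    N = [v for v in problem.deletion_vars if values[v] == 0]
    if not N:
        raise ValueError("previous solution deleted nothing; there is nothing to exclude")
    problem.add_constraint(
        LinearConstraint.from_mapping({v: 1 for v in B}, upper=len(B) - 1,
                                      tag="exclusion")
    )
    problem.add_constraint(
        LinearConstraint.from_mapping({v: 1 for v in N}, lower=1, tag="exclusion")
    )
    return problem


def _deletion_values(problem: BLPProblem, record: SolutionRecord) -> Dict[str, int]:
    if record.raw_assignment:
        return record.raw_assignment
    values: Dict[str, int] = {}
    for v in problem.deletion_vars:
        kind, label = v.split(":", 1)
        if kind == "x":
            values[v] = record.x_assignment[label]
        else:
            values[v] = record.y_assignment[label]
    return values


def add_survivor_indicators(problem: BLPProblem,
                            helper: Sequence[BinaryEM]) -> BLPProblem:
    """Attach one binary survivor indicator p per helper mode.

    The pair ``e^T x >= ||e|| * p`` and ``e^T x <= p + ||e|| - 1`` forces
    ``p = 1`` exactly when the mode's full support is kept and ``p = 0`` as
    soon as any contributing reaction is knocked out.
    """
    for em in helper:
        pv = pvar(em.mode_id)
        problem.add_variable(pv, "survivor")
        coeffs = {xvar(problem.reaction_ids[i]): 1 for i in em.active_indices()}
        problem.add_constraint(
            LinearConstraint.from_mapping(
                {**coeffs, pv: -em.norm}, lower=0, tag="survivor"
            )
        )
        problem.add_constraint(
            LinearConstraint.from_mapping(
                {**coeffs, pv: -1}, upper=em.norm - 1, tag="survivor"
            )
        )
    return problem


def add_side_constraint(problem: BLPProblem,
                        expression: LinearConstraint) -> BLPProblem:
    """Append a raw linear side constraint, resolving bare reaction/gene names.

    Coefficients may reference variables either by their internal name
    (``x:R1``) or by the bare reaction/gene identifier; bare names are
    resolved against declared reaction variables first, then gene variables.
    """
    resolved: Dict[str, float] = {}
    for name, coef in expression.coefficients:
        if name in problem.variables:
            var = name
        elif xvar(name) in problem.variables:
            var = xvar(name)
        elif yvar(name) in problem.variables:
            var = yvar(name)
        else:
            raise ValueError(f"side constraint references unknown variable {name!r}")
        resolved[var] = resolved.get(var, 0) + coef
    problem.add_constraint(
        LinearConstraint.from_mapping(
            resolved, lower=expression.lower, upper=expression.upper, tag="side"
        )
    )
    return problem
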