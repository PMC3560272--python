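"""Exact 0/1 solvers and minimal-cut-set enumeration.

The built-in solver is a depth-first branch-and-bound over the binary
variables with unit propagation on the two-sided linear constraints and an
additive optimistic bound for pruning.  Variables are branched in declaration
(input) order with value 1 tried first, which favors keeping reactions and
makes the returned optimum deterministic.  It is dependency-free and adequate
for desk-scale problems; an external MILP backend (HiGHS via
``scipy.optimize.milp``) is available behind the same contract and must agree
on the enumerated solution sets.

Enumeration alternates solve / record / add-exclusion until the program turns
infeasible, which yields every minimal intervention set exactly once, in
non-increasing objective order.
"""

from __future__ import annotations

import math
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .binarize import support_contains
from .builder import (
    WeightsLike,
    add_exclusion,
    add_side_constraint,
    build_base_problem,
    reduce_to_hitting_set,
)
from .core import (
    BLPProblem,
    EMPartition,
    GeneRule,
    LinearConstraint,
    MCSResult,
    SolutionRecord,
    xvar,
)
from .regulation import attach_regulation

OBJ_EPS = 1e-6  # objective comparison tolerance when ranking solutions
_FEAS_EPS = 1e-7

BACKENDS = ("builtin", "highs")


class SolverError(RuntimeError):
    """The backend failed on a well-formed problem (not plain infeasibility)."""


def solve(problem: BLPProblem, backend: str = "builtin") -> Optional[SolutionRecord]:
    """Solve one BLP to proven optimality.

    Returns a classified :class:`SolutionRecord`, or ``None`` when the
    program is infeasible (signalled distinctly from solver errors, which
    raise).  Deterministic for the built-in backend given the input order.
    """
    if backend not in BACKENDS:
        raise ValueError(f"unknown backend {backend!r}; choose from {BACKENDS}")
    optimizer = _optimize_builtin if backend == "builtin" else _optimize_highs
    out = optimizer(problem)
    if out is None:
        return None
    assignment, objective = out
    return _record_from_assignment(problem, assignment, objective)


# --------------------------------------------------------------------------
# built-in implicit enumeration
# --------------------------------------------------------------------------

def _optimize_builtin(problem: BLPProblem) -> Optional[Tuple[Dict[str, int], float]]:
    names = list(problem.variables)
    nv = len(names)
    pos = {v: i for i, v in enumerate(names)}
    sign = 1.0 if problem.sense == "max" else -1.0
    c = [sign * problem.objective.get(v, 0.0) for v in names]

    rows_idx: List[List[int]] = []
    rows_coef: List[List[float]] = []
    rows_lo: List[float] = []
    rows_hi: List[float] = []
    var_rows: List[List[Tuple[int, float]]] = [[] for _ in range(nv)]
    for con in problem.constraints:
        r = len(rows_idx)
        idx = [pos[v] for v, _ in con.coefficients]
        coef = [float(co) for _, co in con.coefficients]
        rows_idx.append(idx)
        rows_coef.append(coef)
        rows_lo.append(-math.inf if con.lower is None else float(con.lower))
        rows_hi.append(math.inf if con.upper is None else float(con.upper))
        for j, co in zip(idx, coef):
            var_rows[j].append((r, co))

    nr = len(rows_idx)
    val = [-1] * nv
    minact = [sum(min(0.0, co) for co in rows_coef[r]) for r in range(nr)]
    maxact = [sum(max(0.0, co) for co in rows_coef[r]) for r in range(nr)]

    state = {"obj": 0.0, "best": -math.inf, "best_assign": None}

    def assign(j: int, v: int, trail: List[int]) -> bool:
        """Set variable j := v; returns False on immediate row infeasibility."""
        val[j] = v
        trail.append(j)
        state["obj"] += c[j] * v
        ok = True
        for r, co in var_rows[j]:
            minact[r] += co * v - min(0.0, co)
            maxact[r] += co * v - max(0.0, co)
            if minact[r] > rows_hi[r] + _FEAS_EPS or maxact[r] < rows_lo[r] - _FEAS_EPS:
                ok = False
        return ok

    def undo(trail: List[int]) -> None:
        for j in reversed(trail):
            v = val[j]
            state["obj"] -= c[j] * v
            for r, co in var_rows[j]:
                minact[r] -= co * v - min(0.0, co)
                maxact[r] -= co * v - max(0.0, co)
            val[j] = -1

    def propagate(rows: List[int], trail: List[int]) -> bool:
        """Unit propagation over a worklist of constraint rows."""
        queue = list(rows)
        while queue:
            r = queue.pop()
            if minact[r] > rows_hi[r] + _FEAS_EPS or maxact[r] < rows_lo[r] - _FEAS_EPS:
                return False
            for j, co in zip(rows_idx[r], rows_coef[r]):
                if val[j] != -1:
                    continue
                lo_j, hi_j = min(0.0, co), max(0.0, co)
                ok1 = (minact[r] - lo_j + co <= rows_hi[r] + _FEAS_EPS
                       and maxact[r] - hi_j + co >= rows_lo[r] - _FEAS_EPS)
                ok0 = (minact[r] - lo_j <= rows_hi[r] + _FEAS_EPS
                       and maxact[r] - hi_j >= rows_lo[r] - _FEAS_EPS)
                if not ok1 and not ok0:
                    return False
                if ok1 != ok0:
                    forced = 1 if ok1 else 0
                    if not assign(j, forced, trail):
                        return False
                    queue.extend(rr for rr, _ in var_rows[j])
        return True

    def dfs(start: int) -> None:
        bound = state["obj"] + sum(max(0.0, c[j]) for j in range(nv) if val[j] == -1)
        if bound <= state["best"] + 1e-9:
            return
        j = start
        while j < nv and val[j] != -1:
            j += 1
        if j == nv:
            if state["obj"] > state["best"] + 1e-9:
                state["best"] = state["obj"]
                state["best_assign"] = list(val)
            return
        for v in (1, 0):  # branch value 1 first: favors keeping
            trail: List[int] = []
            if assign(j, v, trail) and propagate([r for r, _ in var_rows[j]], trail):
                dfs(j + 1)
            undo(trail)

    root_trail: List[int] = []
    if propagate(list(range(nr)), root_trail):
        dfs(0)
    undo(root_trail)

    if state["best_assign"] is None:
        return None
    assignment = {v: state["best_assign"][pos[v]] for v in names}
    return assignment, problem.evaluate_objective(assignment)


# --------------------------------------------------------------------------
# external backend: HiGHS through scipy
# --------------------------------------------------------------------------

def _optimize_highs(problem: BLPProblem) -> Optional[Tuple[Dict[str, int], float]]:
    from scipy.optimize import Bounds, milp
    from scipy.optimize import LinearConstraint as SciLinearConstraint

    names = list(problem.variables)
    nv = len(names)
    pos = {v: i for i, v in enumerate(names)}
    sign = -1.0 if problem.sense == "max" else 1.0
    c = np.array([sign * problem.objective.get(v, 0.0) for v in names])
    constraints = []
    if problem.constraints:
        A = np.zeros((len(problem.constraints), nv))
        lb = np.full(len(problem.constraints), -np.inf)
        ub = np.full(len(problem.constraints), np.inf)
        for i, con in enumerate(problem.constraints):
            for v, co in con.coefficients:
                A[i, pos[v]] += float(co)
            if con.lower is not None:
                lb[i] = float(con.lower)
            if con.upper is not None:
                ub[i] = float(con.upper)
        constraints = [SciLinearConstraint(A, lb, ub)]
    res = milp(
        c=c,
        constraints=constraints,
        integrality=np.ones(nv),
        bounds=Bounds(0, 1),
    )
    if res.status == 2:  # proven infeasible
        return None
    if not res.success:
        raise SolverError(f"HiGHS backend failed: {res.message}")
    assignment = {v: int(round(res.x[pos[v]])) for v in names}
    return assignment, problem.evaluate_objective(assignment)


# --------------------------------------------------------------------------
# solution classification
# --------------------------------------------------------------------------

def _record_from_assignment(problem: BLPProblem, assignment: Dict[str, int],
                            objective: float) -> SolutionRecord:
    rids = problem.reaction_ids
    x_assign = {r: assignment[xvar(r)] for r in rids}
    y_assign = {
        v.split(":", 1)[1]: assignment[v] for v in problem.vars_of_kind("gene")
    }
    gene_deletions = frozenset(g for g, v in y_assign.items() if v == 0)
    reaction_deletions = set()
    forced_off = set()
    for r in rids:
        if x_assign[r] == 1:
            continue
        rule = problem.rule_map.get(r)
        if rule is None:
            reaction_deletions.add(r)
        else:
            # off via a deleted (plain-literal) gene is a gene-deletion effect;
            # off with all plain genes expressed is pure regulation
            plain_deleted = any(
                (not neg) and y_assign[g] == 0 for g, neg in rule.literals
            )
            if not plain_deleted:
                forced_off.add(r)
    return SolutionRecord(
        objective_value=objective,
        x_assignment=x_assign,
        y_assignment=y_assign,
        reaction_deletions=frozenset(reaction_deletions),
        gene_deletions=gene_deletions,
        regulation_forced_off=frozenset(forced_off),
        kept_reactions=frozenset(r for r in rids if x_assign[r] == 1),
        raw_assignment=assignment,
    )


# --------------------------------------------------------------------------
# enumeration
# --------------------------------------------------------------------------

def enumerate_mcs(partition: EMPartition, weights: WeightsLike,
                  rules: Optional[Sequence[GeneRule]] = None,
                  side_constraints: Optional[Sequence[LinearConstraint]] = None,
                  gene_weights: Optional[Mapping[str, float]] = None,
                  max_solutions: int = 10_000,
                  min_objective: Optional[float] = None,
                  include_helper_rows: bool = False,
                  backend: str = "builtin") -> MCSResult:
    """Enumerate all minimal intervention sets for a partition.

    Repeats solve -> record -> exclude until infeasible (or a cap is hit, in
    which case ``exhausted`` is False).  With all weights positive every
    emitted deletion pattern is minimal and the patterns form an antichain
    under set inclusion; objective values are non-increasing with rank.  An
    initially infeasible design returns an empty result carrying the
    irreducible-conflict report from the hitting-set reduction.
    """
    problem = build_base_problem(partition, weights, include_helper_rows)
    if rules:
        attach_regulation(problem, rules, gene_weights)
    for sc in side_constraints or ():
        add_side_constraint(problem, sc)

    solutions: List[SolutionRecord] = []
    exhausted = True
    while True:
        if len(solutions) >= max_solutions:
            exhausted = False
            break
        sol = solve(problem, backend=backend)
        if sol is None:
            break
        if min_objective is not None and sol.objective_value < min_objective - OBJ_EPS:
            exhausted = False
            break
        sol.rank = len(solutions) + 1
        sol.n_surviving_helpers = sum(
            1 for em in partition.helper
            if support_contains([sol.x_assignment[r] for r in partition.reaction_ids], em)
        )
        solutions.append(sol)
        if not sol.interventions:
            # the empty deletion set is the unique minimal solution
            break
        add_exclusion(problem, sol)

    conflicts: List[str] = []
    if not solutions:
        conflicts = reduce_to_hitting_set(partition).conflicts
    dmin = (
        min(len(s.interventions) for s in solutions) if solutions else None
    )
    return MCSResult(
        delta_min=dmin, solutions=solutions, exhausted=exhausted, conflicts=conflicts
    )


def delta_min(result: MCSResult, n: int) -> int:
    """Minimum number of deletions ``n - ||x||`` over the enumerated optima.

    For an unweighted (uniform-weight) run this is determined by the
    top-ranked solution, which keeps the most reactions.
    """
    if not result.solutions:
        raise ValueError("empty result: no solutions to measure")
    return n - max(len(s.kept_reactions) for s in result.solutions)
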