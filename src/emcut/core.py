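"""Domain types for elementary-mode based cut-set design.

A metabolic network's steady-state capabilities decompose into elementary
modes (EMs): minimal, indivisible pathways.  Knocking out any reaction of an
EM disables the whole mode.  Strain design by *minimal cut sets* partitions
the binarized EMs into three classes:

* **goal** modes (rows of G) — desired functionality that every design must
  retain in full,
* **kill** modes (rows of K) — unwanted functionality; every design must
  remove at least one reaction from each of their supports,
* **helper** modes (rows of H) — indifferent to the design criterion.

All quantities here are binary supports; flux magnitudes play no role after
binarization.  The optimization itself lives in :mod:`emcut.builder` and
:mod:`emcut.solver`; this module only holds the containers and their
invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

Number = Union[int, float, Fraction]

# Binary decision variables are namespaced by kind so that a reaction and a
# gene sharing a name can never collide inside one problem.


def xvar(reaction_id: str) -> str:
    """Name of the binary reaction-presence variable for ``reaction_id``."""
    return "x:" + reaction_id


def yvar(gene_id: str) -> str:
    """Name of the binary gene-expression variable for ``gene_id``."""
    return "y:" + gene_id


def pvar(mode_id: str) -> str:
    """Name of the binary survivor indicator for helper mode ``mode_id``."""
    return "p:" + mode_id


def var_label(var_name: str) -> str:
    """Strip the kind prefix from a variable name (``"x:R1"`` -> ``"R1"``)."""
    return var_name.split(":", 1)[1]


class InvariantError(ValueError):
    """A domain type was constructed with an invariant violation."""


@dataclass(frozen=True)
class NetworkModel:
    """A tiny stoichiometric network (used only by the EM oracle).

    Parameters
    ----------
    reaction_ids : ordered reaction names (columns of S).
    metabolite_ids : ordered *internal* metabolite names (rows of S).
    stoichiometry : mapping ``(metabolite, reaction) -> Fraction`` holding the
        nonzero entries of S.  External metabolites carry no row.
    reversible : per-reaction reversibility flags.
    external_metabolites : names excluded from the steady-state condition.
    """

    reaction_ids: Tuple[str, ...]
    metabolite_ids: Tuple[str, ...]
    stoichiometry: Mapping[Tuple[str, str], Fraction]
    reversible: Tuple[bool, ...]
    external_metabolites: frozenset

    def __post_init__(self):
        if len(self.reaction_ids) < 1:
            raise InvariantError("reaction_ids: need at least one reaction")
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            raise InvariantError("reaction_ids: duplicate reaction names")
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise InvariantError("metabolite_ids: duplicate metabolite names")
        if len(self.reversible) != len(self.reaction_ids):
            raise InvariantError("reversible: length must match reaction_ids")
        mets = set(self.metabolite_ids)
        rxns = set(self.reaction_ids)
        for (met, rxn) in self.stoichiometry:
            if met not in mets:
                raise InvariantError(f"stoichiometry: undeclared metabolite {met!r}")
            if rxn not in rxns:
                raise InvariantError(f"stoichiometry: undeclared reaction {rxn!r}")

    @property
    def n(self) -> int:
        return len(self.reaction_ids)

    @property
    def m(self) -> int:
        return len(self.metabolite_ids)


@dataclass(frozen=True)
class BinaryEM:
    """Binary support vector of one elementary mode.

    ``support[i]`` is 1 iff reaction ``i`` carries (forward or backward) flux
    in the mode; ``norm`` is the number of active reactions.
    """

    mode_id: str
    support: Tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "support", tuple(int(v) for v in self.support))
        if any(v not in (0, 1) for v in self.support):
            raise InvariantError("support: entries must be 0 or 1")

    @property
    def norm(self) -> int:
        """Support size ||e|| (count of ones)."""
        return sum(self.support)

    def active_indices(self) -> Tuple[int, ...]:
        return tuple(i for i, v in enumerate(self.support) if v)

    def active_reactions(self, reaction_ids: Sequence[str]) -> frozenset:
        return frozenset(reaction_ids[i] for i in self.active_indices())


def _collapse_duplicates(modes: Sequence[BinaryEM]) -> Tuple[BinaryEM, ...]:
    # Duplicate supports within one class are pure redundancy for the BLP;
    # collapse them to one row with merged mode ids.
    out: List[BinaryEM] = []
    seen: Dict[Tuple[int, ...], int] = {}
    for em in modes:
        if em.support in seen:
            i = seen[em.support]
            out[i] = BinaryEM(out[i].mode_id + "+" + em.mode_id, em.support)
        else:
            seen[em.support] = len(out)
            out.append(em)
    return tuple(out)


@dataclass
class EMPartition:
    """Goal / kill / helper partition of a set of binarized EMs.

    Reaction order is fixed by ``reaction_ids`` (input-file order); every
    support vector uses that order.  Duplicate supports *within* one class are
    collapsed on construction; duplicates *across* classes are left in place
    and reported by :func:`validate_partition`.
    """

    reaction_ids: Tuple[str, ...]
    goal: Tuple[BinaryEM, ...] = ()
    kill: Tuple[BinaryEM, ...] = ()
    helper: Tuple[BinaryEM, ...] = ()

    def __post_init__(self):
        self.reaction_ids = tuple(self.reaction_ids)
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            raise InvariantError("reaction_ids: duplicate reaction names")
        n = len(self.reaction_ids)
        if n < 1:
            raise InvariantError("reaction_ids: need at least one reaction")
        for cls in ("goal", "kill", "helper"):
            modes = tuple(getattr(self, cls))
            for em in modes:
                if len(em.support) != n:
                    raise InvariantError(
                        f"{cls}: support length {len(em.support)} of {em.mode_id!r} "
                        f"does not match {n} reactions"
                    )
            setattr(self, cls, _collapse_duplicates(modes))

    @property
    def n(self) -> int:
        return len(self.reaction_ids)

    @property
    def r(self) -> int:
        return len(self.goal)

    @property
    def s(self) -> int:
        return len(self.helper)

    @property
    def t(self) -> int:
        return len(self.kill)

    @property
    def q(self) -> int:
        return self.r + self.s + self.t

    def all_modes(self) -> Tuple[Tuple[str, BinaryEM], ...]:
        return tuple(
            (cls, em)
            for cls in ("goal", "kill", "helper")
            for em in getattr(self, cls)
        )

    def goal_union(self) -> frozenset:
        """Union of all goal supports, as reaction ids."""
        out = set()
        for em in self.goal:
            out.update(em.active_reactions(self.reaction_ids))
        return frozenset(out)


def validate_partition(partition: EMPartition) -> List[str]:
    """Diagnostic check of a partition; returns human-readable violations.

    An empty list means the partition is well formed.  Reported issues:
    identical supports appearing in two classes, zero-norm modes, and a
    partition with neither goal nor kill modes (nothing to optimize).
    """
    diags: List[str] = []
    seen: Dict[Tuple[int, ...], Tuple[str, str]] = {}
    for cls, em in partition.all_modes():
        if em.norm == 0:
            diags.append(f"zero-norm mode {em.mode_id!r} in {cls}")
        if em.support in seen:
            other_cls, other_id = seen[em.support]
            if other_cls != cls:
                diags.append(
                    f"duplicate support: mode {em.mode_id!r} ({cls}) matches "
                    f"{other_id!r} ({other_cls})"
                )
        else:
            seen[em.support] = (cls, em.mode_id)
    if not partition.goal and not partition.kill:
        diags.append("nothing to optimize: goal and kill classes are both empty")
    return diags


@dataclass(frozen=True)
class ReactionMeta:
    """Experimental-feasibility metadata for one reaction.

    ``is_uptake`` marks substrate import (deletable via medium composition);
    ``is_annotated`` whether a gene-enzyme mapping exists; ``n_isoenzymes``
    counts independent enzymes/enzyme complexes catalyzing the reaction in
    parallel; ``weight`` is an optional explicit override of the suggested
    objective weight.
    """

    reaction_id: str
    is_uptake: bool = False
    is_annotated: bool = True
    n_isoenzymes: int = 1
    weight: Optional[float] = None

    def __post_init__(self):
        if self.n_isoenzymes < 0:
            raise InvariantError("n_isoenzymes: must be nonnegative")
        if self.n_isoenzymes == 0 and self.is_annotated:
            raise InvariantError(
                "n_isoenzymes: 0 isoenzymes allowed only for non-annotated reactions"
            )
        if self.weight is not None and not self.weight > 0:
            raise InvariantError("weight: must be positive when present")


@dataclass(frozen=True)
class GeneRule:
    """One boolean gene-protein-reaction / regulatory rule targeting a reaction.

    ``literals`` are ``(gene_id, negated)`` pairs combined with a single
    operator: IDENTITY (one literal), AND, or OR (two or more literals each).
    Nested or mixed expressions are not representable; introduce intermediate
    pseudo-genes instead.
    """

    target: str
    operator: str
    literals: Tuple[Tuple[str, bool], ...]

    def __post_init__(self):
        if self.operator not in ("AND", "OR", "IDENTITY"):
            raise InvariantError(f"operator: unknown operator {self.operator!r}")
        if self.operator == "IDENTITY" and len(self.literals) != 1:
            raise InvariantError("literals: IDENTITY requires exactly one literal")
        if self.operator in ("AND", "OR") and len(self.literals) < 2:
            raise InvariantError(
                f"literals: {self.operator} requires at least two literals"
            )

    def genes(self) -> Tuple[str, ...]:
        return tuple(g for g, _ in self.literals)

    def evaluate(self, gene_values: Mapping[str, int]) -> int:
        """Boolean value of the rule expression under a total gene assignment."""
        vals = [
            (1 - gene_values[g]) if neg else gene_values[g]
            for g, neg in self.literals
        ]
        if self.operator == "IDENTITY":
            return vals[0]
        if self.operator == "AND":
            return int(all(vals))
        return int(any(vals))


@dataclass(frozen=True)
class LinearConstraint:
    """Two-sided linear constraint ``lower <= sum(coef * var) <= upper``.

    A uniform container for EM rows, exclusion cuts, compiled regulation,
    survivor-indicator links and raw user side constraints; ``tag`` records
    provenance.  Bounds are exact (int/Fraction) wherever they originate from
    the model; ``None`` means unbounded on that side.
    """

    coefficients: Tuple[Tuple[str, Number], ...]
    lower: Optional[Number] = None
    upper: Optional[Number] = None
    tag: str = "side"

    def __post_init__(self):
        coeffs = tuple((str(v), c) for v, c in dict(self.coefficients).items())
        object.__setattr__(self, "coefficients", coeffs)
        if self.lower is None and self.upper is None:
            raise InvariantError("bounds: at least one bound must be finite")

    @classmethod
    def from_mapping(cls, coeffs: Mapping[str, Number], lower=None, upper=None,
                     tag: str = "side") -> "LinearConstraint":
        return cls(tuple(coeffs.items()), lower, upper, tag)

    def variables(self) -> Tuple[str, ...]:
        return tuple(v for v, _ in self.coefficients)

    def evaluate(self, assignment: Mapping[str, int]) -> Number:
        return sum(c * assignment[v] for v, c in self.coefficients)

    def satisfied_by(self, assignment: Mapping[str, int], eps: float = 1e-9) -> bool:
        val = float(self.evaluate(assignment))
        if self.lower is not None and val < float(self.lower) - eps:
            return False
        if self.upper is not None and val > float(self.upper) + eps:
            return False
        return True


class BLPProblem:
    """A binary linear program over reaction (x), gene (y) and survivor (p) vars.

    Variables are kept in declaration order; the built-in solver branches in
    that order, which makes enumeration deterministic for a fixed input.
    ``deletion_vars`` names the deletion-decision vector used by exclusion
    cuts: gene variables for GPR-mapped reactions plus reaction variables for
    unmapped reactions (all reaction variables when no regulation is
    attached).
    """

    def __init__(self, sense: str = "max"):
        if sense not in ("max", "min"):
            raise InvariantError(f"sense: unknown sense {sense!r}")
        self.sense = sense
        self.variables: Dict[str, str] = {}  # name -> kind
        self.constraints: List[LinearConstraint] = []
        self.objective: Dict[str, float] = {}
        self.deletion_vars: List[str] = []
        self.rule_map: Dict[str, GeneRule] = {}
        self.reaction_ids: Tuple[str, ...] = ()

    # -- construction -----------------------------------------------------
    def add_variable(self, name: str, kind: str) -> None:
        if kind not in ("reaction", "gene", "survivor"):
            raise InvariantError(f"variable kind: unknown kind {kind!r}")
        if name in self.variables:
            raise InvariantError(f"variable {name!r} declared twice")
        self.variables[name] = kind

    def add_constraint(self, constraint: LinearConstraint) -> None:
        for v in constraint.variables():
            if v not in self.variables:
                raise InvariantError(
                    f"constraint references undeclared variable {v!r}"
                )
        self.constraints.append(constraint)

    def set_objective_coeff(self, name: str, coeff: float) -> None:
        if name not in self.variables:
            raise InvariantError(f"objective references undeclared variable {name!r}")
        self.objective[name] = float(coeff)

    def copy(self) -> "BLPProblem":
        clone = BLPProblem(self.sense)
        clone.variables = dict(self.variables)
        clone.constraints = list(self.constraints)
        clone.objective = dict(self.objective)
        clone.deletion_vars = list(self.deletion_vars)
        clone.rule_map = dict(self.rule_map)
        clone.reaction_ids = self.reaction_ids
        return clone

    # -- queries -----------------------------------------------------------
    def evaluate_objective(self, assignment: Mapping[str, int]) -> float:
        return float(sum(c * assignment.get(v, 0) for v, c in self.objective.items()))

    def vars_of_kind(self, kind: str) -> List[str]:
        return [v for v, k in self.variables.items() if k == kind]


@dataclass
class SolutionRecord:
    """One intervention set returned by the solver.

    ``reaction_deletions`` holds only directly deletable reactions (those
    without a GPR rule); reactions switched off by deleting their genes are
    implied by ``gene_deletions``; ``regulation_forced_off`` lists reactions
    that are zero purely because of regulation (an inhibiting gene that the
    design keeps expressed), not because of any deletion.
    """

    objective_value: float
    x_assignment: Dict[str, int]
    y_assignment: Dict[str, int]
    reaction_deletions: frozenset
    gene_deletions: frozenset
    regulation_forced_off: frozenset
    kept_reactions: frozenset
    rank: int = 0
    n_surviving_helpers: Optional[int] = None
    raw_assignment: Dict[str, int] = field(default_factory=dict, repr=False)

    @property
    def interventions(self) -> frozenset:
        """Deleted genes plus directly deleted reactions (the decision vector N)."""
        return self.gene_deletions | self.reaction_deletions

    @property
    def reaction_pattern(self) -> frozenset:
        """All reactions absent from the design, regardless of cause."""
        return frozenset(r for r, v in self.x_assignment.items() if v == 0)


@dataclass
class MCSResult:
    """Full enumeration output: all (constrained) minimal cut sets found.

    ``delta_min`` is the minimum number of interventions over the enumerated
    solutions; ``exhausted`` is True when enumeration ran to infeasibility
    rather than stopping at a cap; ``conflicts`` carries the irreducible
    kill-mode conflicts when the initial problem was infeasible (the remedy is
    to shift modes out of the goal class).
    """

    delta_min: Optional[int]
    solutions: List[SolutionRecord]
    exhausted: bool
    conflicts: List[str] = field(default_factory=list)

    def deletion_patterns(self) -> List[frozenset]:
        return [sol.interventions for sol in self.solutions]
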