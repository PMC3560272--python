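"""Boolean gene-protein-reaction and regulatory rules, compiled to linear
constraints over binary gene (y) and reaction (x) variables.

Rule grammar (one statement per line, ``#`` comments)::

    [NOT] GENE {AND|OR [NOT] GENE}* -> REACTION
    constraint: [+|-] [coef] NAME {+|- [coef] NAME}* (<=|>=|=) RATIONAL

A rule uses a single operator kind; nested or mixed boolean expressions are
rejected (introduce intermediate pseudo-genes instead).  The ``constraint:``
form carries raw linear side constraints, e.g. mutual exclusion of two
reactions (``constraint: R_GG1 + R_GLB1 <= 1``).

Compilation: with each literal contributing ``y`` (plain) or ``1 - y``
(negated) and ``k`` literals in total,

* IDENTITY:  ``sum(t) - x = 0``  (``y - x = 0`` plain, ``y + x = 1`` negated),
* OR:        ``-(k-1) <= sum(t) - k*x <= 0``,
* AND:       ``0 <= sum(t) - k*x <= k-1``,

with the negation constants folded into the bounds.  Every compiled form is
exact: it admits precisely the assignments where the reaction value equals
the boolean value of the expression (see :func:`truth_table_check`).
"""

from __future__ import annotations

import itertools
import re
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .core import BLPProblem, GeneRule, LinearConstraint, xvar, yvar


class RuleSyntaxError(ValueError):
    """A rule file line could not be parsed."""


class RegulationConflict(ValueError):
    """A fixed assignment contradicts the compiled regulatory constraints."""


_IDENT = re.compile(r"^[A-Za-z_][A-Za-z0-9_.\-]*$")


def _check_ident(token: str, lineno: Optional[int]) -> str:
    if not _IDENT.match(token):
        where = f" (line {lineno})" if lineno else ""
        raise RuleSyntaxError(f"invalid identifier {token!r}{where}")
    return token


def parse_rule_line(line: str, lineno: Optional[int] = None) -> GeneRule:
    """Parse a single ``[NOT] GENE {AND|OR [NOT] GENE}* -> REACTION`` rule."""
    where = f" (line {lineno})" if lineno else ""
    if "->" not in line:
        raise RuleSyntaxError(f"missing '->' in rule{where}: {line!r}")
    lhs, _, target = line.rpartition("->")
    target = _check_ident(target.strip(), lineno)
    tokens = lhs.split()
    if not tokens:
        raise RuleSyntaxError(f"empty left-hand side{where}: {line!r}")
    literals: List[Tuple[str, bool]] = []
    operators: Set[str] = set()
    i = 0
    expect_literal = True
    while i < len(tokens):
        tok = tokens[i]
        if expect_literal:
            negated = False
            if tok.upper() == "NOT":
                negated = True
                i += 1
                if i >= len(tokens):
                    raise RuleSyntaxError(f"dangling NOT{where}: {line!r}")
                tok = tokens[i]
            literals.append((_check_ident(tok, lineno), negated))
            expect_literal = False
        else:
            op = tok.upper()
            if op not in ("AND", "OR"):
                raise RuleSyntaxError(f"expected AND/OR, got {tok!r}{where}")
            operators.add(op)
            expect_literal = True
        i += 1
    if expect_literal:
        raise RuleSyntaxError(f"rule ends with an operator{where}: {line!r}")
    if len(operators) > 1:
        raise RuleSyntaxError(
            f"mixed AND/OR in one rule is unsupported{where}: {line!r}; "
            "introduce an intermediate pseudo-gene"
        )
    operator = operators.pop() if operators else "IDENTITY"
    return GeneRule(target=target, operator=operator, literals=tuple(literals))


def parse_side_constraint(line: str, lineno: Optional[int] = None) -> LinearConstraint:
    """Parse ``constraint: <±coef name ...> <=|>=|= <rational>``.

    Variable names are left unresolved (bare reaction/gene ids); resolution
    against a concrete problem happens in :func:`emcut.builder.add_side_constraint`.
    """
    where = f" (line {lineno})" if lineno else ""
    body = line.split(":", 1)[1].strip()
    m = re.search(r"(<=|>=|=)", body)
    if not m:
        raise RuleSyntaxError(f"missing relational operator{where}: {line!r}")
    op = m.group(1)
    lhs, rhs = body[: m.start()], body[m.end():]
    try:
        bound = Fraction(rhs.strip())
    except (ValueError, ZeroDivisionError) as exc:
        raise RuleSyntaxError(f"bad right-hand side {rhs.strip()!r}{where}") from exc
    tokens = lhs.replace("+", " + ").replace("-", " - ").split()
    coeffs: Dict[str, Fraction] = {}
    sign = Fraction(1)
    pending: Optional[Fraction] = None
    for tok in tokens:
        if tok == "+":
            sign, pending = Fraction(1), None
        elif tok == "-":
            sign, pending = Fraction(-1), None
        else:
            try:
                pending = sign * Fraction(tok)
                continue
            except (ValueError, ZeroDivisionError):
                pass
            name = _check_ident(tok, lineno)
            coef = pending if pending is not None else sign
            coeffs[name] = coeffs.get(name, Fraction(0)) + coef
            sign, pending = Fraction(1), None
    if not coeffs:
        raise RuleSyntaxError(f"no variables in side constraint{where}: {line!r}")
    lower = bound if op in (">=", "=") else None
    upper = bound if op in ("<=", "=") else None
    return LinearConstraint.from_mapping(coeffs, lower=lower, upper=upper, tag="side")


def parse_rules(text: str) -> List[GeneRule]:
    """Parse a rule file; returns the boolean rules, rejecting duplicate targets."""
    rules, _ = parse_rule_file(text)
    return rules


def parse_rule_file(text: str) -> Tuple[List[GeneRule], List[LinearConstraint]]:
    """Parse a rule file into (boolean rules, raw side constraints)."""
    rules: List[GeneRule] = []
    side: List[LinearConstraint] = []
    targets: Set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("constraint:"):
            side.append(parse_side_constraint(line, lineno))
            continue
        rule = parse_rule_line(line, lineno)
        if rule.target in targets:
            raise RuleSyntaxError(
                f"duplicate rule target {rule.target!r} (line {lineno})"
            )
        targets.add(rule.target)
        rules.append(rule)
    return rules, side


def compile_rule(rule: GeneRule) -> List[LinearConstraint]:
    """Compile one boolean rule into exact linear constraints on x/y variables."""
    x = xvar(rule.target)
    coeffs: Dict[str, int] = {}
    const = 0
    for gene, negated in rule.literals:
        yv = yvar(gene)
        if negated:
            const += 1
            coeffs[yv] = coeffs.get(yv, 0) - 1
        else:
            coeffs[yv] = coeffs.get(yv, 0) + 1
    k = len(rule.literals)
    if rule.operator == "IDENTITY":
        lo, hi = -const, -const
        coeffs[x] = -1
    elif rule.operator == "OR":
        lo, hi = -(k - 1) - const, -const
        coeffs[x] = -k
    else:  # AND
        lo, hi = -const, (k - 1) - const
        coeffs[x] = -k
    return [LinearConstraint.from_mapping(coeffs, lower=lo, upper=hi, tag="regulation")]


def truth_table_check(rule: GeneRule) -> bool:
    """Exhaustively verify that a compiled rule encodes its boolean function.

    Evaluates all ``2^(k+1)`` assignments of (literal genes, target reaction)
    and checks the compiled constraints admit exactly the rows where the
    reaction value equals the boolean value of the expression.
    """
    constraints = compile_rule(rule)
    genes = sorted(set(rule.genes()))
    for bits in itertools.product((0, 1), repeat=len(genes) + 1):
        gene_values = dict(zip(genes, bits[:-1]))
        target_value = bits[-1]
        assignment = {yvar(g): v for g, v in gene_values.items()}
        assignment[xvar(rule.target)] = target_value
        admitted = all(c.satisfied_by(assignment) for c in constraints)
        expected = rule.evaluate(gene_values) == target_value
        if admitted != expected:
            return False
    return True


def attach_regulation(problem: BLPProblem, rules: Sequence[GeneRule],
                      gene_weights: Optional[Mapping[str, float]] = None,
                      ) -> BLPProblem:
    """Declare gene variables, add compiled rule constraints, extend objective.

    Genes get variables in order of first appearance across the rules (only
    genes referenced by some rule — the "involved genes").  The deletion-
    decision vector becomes: gene variables, then reaction variables of
    reactions without a rule.  The objective gains one unit (or the given
    weight) per gene, so maximization keeps genes expressed unless a deletion
    is needed.
    """
    known_reactions = set(problem.reaction_ids)
    gene_order: List[str] = []
    for rule in rules:
        if rule.target not in known_reactions:
            raise ValueError(
                f"rule targets unknown reaction {rule.target!r}; "
                "gene->gene regulation must be expressed via side constraints"
            )
        if rule.target in problem.rule_map:
            raise ValueError(f"duplicate rule target {rule.target!r}")
        problem.rule_map[rule.target] = rule
        for g in rule.genes():
            if g not in gene_order:
                gene_order.append(g)
    for g in gene_order:
        problem.add_variable(yvar(g), "gene")
    for rule in rules:
        for c in compile_rule(rule):
            problem.add_constraint(c)
    regulated_objective(problem, gene_weights)
    problem.deletion_vars = [yvar(g) for g in gene_order] + [
        xvar(r) for r in problem.reaction_ids if r not in problem.rule_map
    ]
    return problem


def regulated_objective(problem: BLPProblem,
                        gene_weights: Optional[Mapping[str, float]] = None,
                        ) -> BLPProblem:
    """Set objective to ``sum(w_i x_i) + sum(u_j y_j)`` with default u_j = 1."""
    for v in problem.vars_of_kind("gene"):
        gene = v.split(":", 1)[1]
        u = 1.0 if gene_weights is None else float(gene_weights.get(gene, 1.0))
        if not u > 0:
            raise ValueError(f"gene weight for {gene!r} must be positive, got {u}")
        problem.set_objective_coeff(v, u)
    return problem


def forced_suppressions(rules: Sequence[GeneRule],
                        fixed_genes: Mapping[str, int],
                        fixed_reactions: Optional[Mapping[str, int]] = None,
                        ) -> Set[str]:
    """Reactions whose x is implied 0 by the rules under a partial gene fixing.

    A reaction is forced off when its rule expression evaluates to 0 for
    *every* completion of the unfixed genes (e.g. an inhibiting gene fixed to
    expressed).  If ``fixed_reactions`` pins a reaction in contradiction with
    the implied value, a :class:`RegulationConflict` is raised.
    """
    known_genes = {g for rule in rules for g in rule.genes()}
    unknown = set(fixed_genes) - known_genes
    if unknown:
        raise ValueError(f"fixed_genes references unknown genes {sorted(unknown)}")
    fixed_reactions = fixed_reactions or {}
    forced: Set[str] = set()
    for rule in rules:
        free = [g for g in dict.fromkeys(rule.genes()) if g not in fixed_genes]
        values = set()
        for bits in itertools.product((0, 1), repeat=len(free)):
            gv = dict(fixed_genes)
            gv.update(zip(free, bits))
            values.add(rule.evaluate(gv))
            if len(values) == 2:
                break
        if values == {0}:
            if fixed_reactions.get(rule.target) == 1:
                raise RegulationConflict(
                    f"reaction {rule.target!r} is fixed on but regulation forces it off"
                )
            forced.add(rule.target)
        elif values == {1} and fixed_reactions.get(rule.target) == 0:
            raise RegulationConflict(
                f"reaction {rule.target!r} is fixed off but regulation forces it on"
            )
    return forced
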