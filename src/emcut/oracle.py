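"""Independent brute-force reference implementations for testing.

Everything here trades speed for transparency: minimal hitting sets by
exhaustive subset search, deletion survival by direct support checks, and
elementary-mode enumeration for tiny networks by exact rational nullspaces.
The BLP machinery is never consulted, so these functions serve as oracles
against which the solver's output is compared.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

from sympy import Matrix, Rational

from .core import BinaryEM, EMPartition, NetworkModel


def brute_force_mcs(partition: EMPartition,
                    forced_zero: Sequence[str] = ()) -> Set[FrozenSet[str]]:
    """All minimal deletion sets, by exhaustive subset enumeration.

    Subsets of non-goal reactions are scanned in order of increasing size;
    a subset is kept when it intersects every kill support, contains no goal
    reaction, and no kept proper subset already has that property.  Returns
    ``{frozenset()}`` when nothing needs cutting and the empty set when the
    design is infeasible.  Intended for n <= 20.
    """
    rids = partition.reaction_ids
    bit = {r: 1 << i for i, r in enumerate(rids)}
    goal_mask = 0
    for em in partition.goal:
        for r in em.active_reactions(rids):
            goal_mask |= bit[r]
    fz_mask = 0
    for r in forced_zero:
        fz_mask |= bit[r]

    rows: List[int] = []
    for em in partition.kill:
        mask = 0
        for r in em.active_reactions(rids):
            mask |= bit[r]
        mask &= ~goal_mask
        if mask == 0:
            return set()  # irreducible conflict: this kill mode cannot be cut
        if mask & fz_mask:
            continue
        rows.append(mask)
    if not rows:
        return {frozenset()}

    union = 0
    for m in rows:
        union |= m
    candidates = [i for i in range(len(rids)) if union >> i & 1]
    found_masks: List[int] = []
    for size in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            mask = 0
            for i in combo:
                mask |= 1 << i
            if any(f & mask == f for f in found_masks):
                continue  # superset of an already-minimal hitting set
            if all(row & mask for row in rows):
                found_masks.append(mask)
    return {
        frozenset(r for r in rids if mask & bit[r]) for mask in found_masks
    }


def simulate_deletion(partition: EMPartition,
                      deletions: Sequence[str]) -> Dict[str, List[str]]:
    """Surviving mode ids per class after deleting a set of reactions.

    A mode survives iff its support is disjoint from the deletions (knocking
    out any contributing reaction excludes the whole mode).
    """
    dels = set(deletions)
    unknown = dels - set(partition.reaction_ids)
    if unknown:
        raise ValueError(f"deletions reference unknown reactions {sorted(unknown)}")
    out: Dict[str, List[str]] = {"goal": [], "kill": [], "helper": []}
    for cls, em in partition.all_modes():
        if not (em.active_reactions(partition.reaction_ids) & dels):
            out[cls].append(em.mode_id)
    return out


def enumerate_ems_bruteforce(network: NetworkModel,
                             ) -> List[Tuple[str, Tuple[Fraction, ...], BinaryEM]]:
    """Enumerate all elementary modes of a tiny network exactly.

    For every candidate support subset T (increasing size) the steady-state
    system restricted to T is solved in rational arithmetic: T carries an EM
    iff the nullspace of S[:, T] is one-dimensional, its generator has no
    zero entry, and the generator (or its negation) respects every
    irreversibility.  Support-minimality follows from the rank condition;
    reversible modes are reported once with the canonical sign (first nonzero
    flux positive when both orientations are admissible).

    Exponential in n; refuses networks with more than 12 reactions.
    """
    n = network.n
    if n > 12:
        raise ValueError(f"brute-force EM enumeration is limited to n <= 12, got {n}")
    S = Matrix(
        [
            [
                Rational(network.stoichiometry.get((met, rxn), 0))
                for rxn in network.reaction_ids
            ]
            for met in network.metabolite_ids
        ]
    ) if network.metabolite_ids else Matrix(0, n, [])

    results: List[Tuple[str, Tuple[Fraction, ...], BinaryEM]] = []
    found_supports: List[Set[int]] = []
    counter = 0
    for size in range(1, n + 1):
        for subset in itertools.combinations(range(n), size):
            sub = set(subset)
            if any(fs <= sub for fs in found_supports):
                continue  # contains a smaller EM support: not minimal
            M = S[:, list(subset)]
            nullspace = M.nullspace()
            if len(nullspace) != 1:
                continue
            gen = nullspace[0]
            if any(gen[i] == 0 for i in range(size)):
                continue  # generator support smaller than the subset
            irr = [
                i for i, col in enumerate(subset) if not network.reversible[col]
            ]
            ok_pos = all(gen[i] > 0 for i in irr)
            ok_neg = all(gen[i] < 0 for i in irr)
            if ok_pos and ok_neg:  # fully reversible mode: canonical sign
                v = gen if gen[0] > 0 else -gen
            elif ok_pos:
                v = gen
            elif ok_neg:
                v = -gen
            else:
                continue  # sign-infeasible: no valid orientation
            counter += 1
            flux = [Fraction(0)] * n
            for i, col in enumerate(subset):
                flux[col] = Fraction(int(v[i].p), int(v[i].q))
            support = tuple(1 if j in sub else 0 for j in range(n))
            em = BinaryEM(mode_id=f"EM{counter}", support=support)
            results.append((em.mode_id, tuple(flux), em))
            found_supports.append(sub)
    return results
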