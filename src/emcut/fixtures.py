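"""Embedded desk-scale fixtures.

Two classic illustrations ship with the package so that the full pipeline is
runnable (and testable) without any external files:

* a 12-reaction, 9-mode toy network for converting substrate A into product
  P, with its goal/kill/helper partition, reaction metadata, the
  experimentally motivated feasibility weight vector, and boolean GPR/regulatory
  rules (R5 needs an enzyme complex of two genes, R7 has two isoenzymes, R10
  is inhibited whenever the gene behind R1 is expressed);
* a 6-reaction, 3-mode network used to demonstrate survivor (functionality)
  optimization.

The 12-reaction stoichiometry itself is not part of the fixture — the design
problem needs only the binary mode supports, which are embedded directly.
The flux-valued matrix (used by the yield classifier) is included as
published; note its EM2 row lists R8 as flux-free while the binary support
includes R8 — the binary representation is authoritative here.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .core import BinaryEM, EMPartition, ReactionMeta
from .io import EMTable
from .regulation import parse_rule_file

TOY_REACTIONS: Tuple[str, ...] = (
    "R1", "R2", "R3", "R4", "R5", "R6", "R7", "R8", "R9", "R10", "R11", "R12",
)

# binary supports (authoritative) of the nine modes
_TOY_BINARY: Tuple[Tuple[str, Tuple[int, ...]], ...] = (
    ("EM1", (1, 0, 0, 1, 0, 0, 1, 1, 0, 0, 0, 1)),
    ("EM2", (1, 0, 0, 1, 1, 0, 1, 1, 1, 0, 1, 1)),
    ("EM3", (1, 0, 0, 1, 0, 1, 0, 0, 1, 1, 0, 1)),
    ("EM4", (1, 1, 0, 1, 0, 0, 0, 1, 0, 0, 0, 0)),
    ("EM5", (1, 1, 0, 1, 1, 0, 0, 0, 1, 0, 1, 0)),
    ("EM6", (1, 1, 0, 1, 0, 1, 1, 0, 1, 1, 0, 0)),
    ("EM7", (0, 0, 1, 1, 0, 0, 0, 1, 0, 0, 0, 0)),
    ("EM8", (0, 0, 1, 1, 1, 0, 0, 0, 1, 0, 1, 0)),
    ("EM9", (0, 0, 1, 1, 0, 1, 1, 0, 1, 1, 0, 0)),
)

# flux-valued modes (R7 is the only reversible reaction; negative = backward)
_TOY_FLUX: Tuple[Tuple[str, Tuple[float, ...]], ...] = (
    ("EM1", (1.0, 0.0, 0.0, 1.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0, 0.0, 1.0)),
    ("EM2", (1.0, 0.0, 0.0, 0.5, 1.0, 0.0, 1.0, 0.0, 0.5, 0.0, 1.0, 1.0)),
    ("EM3", (1.0, 0.0, 0.0, 0.5, 0.0, 1.0, 0.0, 0.0, 0.5, 1.0, 0.0, 1.0)),
    ("EM4", (0.5, 1.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0)),
    ("EM5", (0.5, 1.0, 0.0, 0.5, 1.0, 0.0, 0.0, 0.0, 0.5, 0.0, 1.0, 0.0)),
    ("EM6", (0.5, 1.0, 0.0, 0.5, 0.0, 1.0, -1.0, 0.0, 0.5, 1.0, 0.0, 0.0)),
    ("EM7", (0.0, 0.0, 1.0, 1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0)),
    ("EM8", (0.0, 0.0, 1.0, 0.5, 1.0, 0.0, 0.0, 0.0, 0.5, 0.0, 1.0, 0.0)),
    ("EM9", (0.0, 0.0, 1.0, 0.5, 0.0, 1.0, -1.0, 0.0, 0.5, 1.0, 0.0, 0.0)),
)

TOY_ASSIGNMENT: Dict[str, str] = {
    "EM1": "goal",
    "EM2": "kill", "EM3": "kill", "EM4": "kill", "EM5": "kill", "EM6": "kill",
    "EM7": "helper", "EM8": "helper", "EM9": "helper",
}

# GPR and regulatory rules; R3, R4, R6, R9, R12 have no gene mapping
TOY_RULES_TEXT = """\
# gene-protein-reaction and regulatory rules for the 12-reaction network
GR1 -> R1
GR2 -> R2
GR5a AND GR5b -> R5        # enzyme complex: both genes required
GR7a OR GR7b -> R7         # two independent isoenzymes
GR8 -> R8
NOT GR1 AND GR10 -> R10    # R10 is inhibited while GR1 is expressed
GR11 -> R11
"""

# experimentally motivated weights: uptakes 0.1, non-annotated 99,
# two isoenzymes -> 2, everything else 1
TOY_FEASIBILITY_WEIGHTS: Dict[str, float] = {
    "R1": 0.1, "R2": 0.1, "R3": 0.1, "R4": 99.0, "R5": 1.0, "R6": 99.0,
    "R7": 2.0, "R8": 1.0, "R9": 99.0, "R10": 1.0, "R11": 1.0, "R12": 99.0,
}


def toy_binary_table() -> EMTable:
    """The nine binary mode supports of the 12-reaction example."""
    return EMTable(
        reaction_ids=TOY_REACTIONS,
        modes=[(m, tuple(float(v) for v in vec)) for m, vec in _TOY_BINARY],
        binary=True,
    )


def toy_flux_table() -> EMTable:
    """The flux-valued modes (for binarization / yield-classification demos)."""
    return EMTable(
        reaction_ids=TOY_REACTIONS,
        modes=[(m, vec) for m, vec in _TOY_FLUX],
        binary=False,
    )


def toy_partition() -> EMPartition:
    """Goal = EM1, kill = EM2..EM6, helper = EM7..EM9 over the binary supports."""
    classes: Dict[str, List[BinaryEM]] = {"goal": [], "kill": [], "helper": []}
    for mode_id, vec in _TOY_BINARY:
        classes[TOY_ASSIGNMENT[mode_id]].append(BinaryEM(mode_id, vec))
    return EMPartition(
        reaction_ids=TOY_REACTIONS,
        goal=tuple(classes["goal"]),
        kill=tuple(classes["kill"]),
        helper=tuple(classes["helper"]),
    )


def toy_metadata() -> List[ReactionMeta]:
    """Uptakes R1-R3; complex-catalyzed R5; two isoenzymes for R7;
    R4/R6/R9/R12 (and uptake R3) lack gene annotation."""
    def m(rid, up=False, ann=True, iso=1):
        return ReactionMeta(rid, is_uptake=up, is_annotated=ann, n_isoenzymes=iso)

    return [
        m("R1", up=True),
        m("R2", up=True),
        m("R3", up=True, ann=False, iso=0),
        m("R4", ann=False, iso=0),
        m("R5"),
        m("R6", ann=False, iso=0),
        m("R7", iso=2),
        m("R8"),
        m("R9", ann=False, iso=0),
        m("R10"),
        m("R11"),
        m("R12", ann=False, iso=0),
    ]


def toy_rules():
    """Parsed GPR/regulatory rules of the toy network (9 involved genes)."""
    rules, _ = parse_rule_file(TOY_RULES_TEXT)
    return rules


def toy_feasibility_weights() -> Dict[str, float]:
    return dict(TOY_FEASIBILITY_WEIGHTS)


def uniform_weights(reaction_ids=TOY_REACTIONS) -> Dict[str, float]:
    return {r: 1.0 for r in reaction_ids}


# --------------------------------------------------------------------------
# 6-reaction survivor-optimization example
# --------------------------------------------------------------------------

# A --R2--> B with A fed by R1; a second substrate enters as C (R5),
# C --R4--> B, and R6 shunts A -> C.  Three modes result.
SURVIVOR_NETWORK_TEXT = """\
@ext A_ext B_ext C_ext
R1 : A_ext -> A
R2 : A -> B
R3 : B -> B_ext
R4 : C -> B
R5 : C_ext -> C
R6 : A -> C
"""

SURVIVOR_REACTIONS: Tuple[str, ...] = ("R1", "R2", "R3", "R4", "R5", "R6")


def survivor_partition() -> EMPartition:
    """Goal = R1-R2-R3, kill = R1-R6-R4-R3, helper = R5-R4-R3."""
    def em(mode_id, active):
        return BinaryEM(
            mode_id, tuple(1 if r in active else 0 for r in SURVIVOR_REACTIONS)
        )

    return EMPartition(
        reaction_ids=SURVIVOR_REACTIONS,
        goal=(em("goal", {"R1", "R2", "R3"}),),
        kill=(em("bypass", {"R1", "R6", "R4", "R3"}),),
        helper=(em("side", {"R5", "R4", "R3"}),),
    )
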