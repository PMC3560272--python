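"""File formats, result reporting and synthetic instance generation.

All tabular formats are UTF-8 tab-separated text with ``#`` comments;
reaction columns are matched by name, never by position, and the EM matrix
header fixes the canonical reaction order.  Results are written as JSON (and
a TSV mirror) with a stable field order so files round-trip bit-identically.
"""

from __future__ import annotations

import csv
import io as _stdio
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .binarize import DEFAULT_TOL, binarize_flux_vector
from .core import (
    BinaryEM,
    EMPartition,
    MCSResult,
    NetworkModel,
    ReactionMeta,
)

PathLike = Union[str, Path]
CLASS_LABELS = ("goal", "kill", "helper")


class FormatError(ValueError):
    """A file violated its format contract (message carries the line number)."""


def _read_rows(source: Union[PathLike, str], *, is_text: bool = False,
               ) -> List[Tuple[int, List[str]]]:
    """Tab-split non-comment lines of a TSV, keeping 1-based line numbers."""
    if is_text:
        text = source
    else:
        text = Path(source).read_text(encoding="utf-8")
    rows: List[Tuple[int, List[str]]] = []
    reader = csv.reader(_stdio.StringIO(text), delimiter="\t")
    for lineno, fields in enumerate(reader, start=1):
        if not fields:
            continue
        if fields[0].lstrip().startswith("#"):
            continue
        if all(not f.strip() for f in fields):
            continue
        rows.append((lineno, [f.strip() for f in fields]))
    return rows


# --------------------------------------------------------------------------
# EM matrices
# --------------------------------------------------------------------------

@dataclass
class EMTable:
    """Parsed EM matrix: reaction header plus one (mode id, values) row per EM."""

    reaction_ids: Tuple[str, ...]
    modes: List[Tuple[str, Tuple[float, ...]]]
    binary: bool

    def to_binary(self, tol: float = DEFAULT_TOL) -> List[BinaryEM]:
        if self.binary:
            return [
                BinaryEM(mode_id, tuple(int(v) for v in values))
                for mode_id, values in self.modes
            ]
        return [
            binarize_flux_vector(values, tol=tol, mode_id=mode_id)
            for mode_id, values in self.modes
        ]

    def mode_ids(self) -> List[str]:
        return [m for m, _ in self.modes]


def read_em_matrix(source: Union[PathLike, str], binary: bool = False,
                   tol: float = DEFAULT_TOL, *, is_text: bool = False) -> EMTable:
    """Read a modes-by-reactions TSV (header: reaction ids; col 1: mode id)."""
    rows = _read_rows(source, is_text=is_text)
    if not rows:
        raise FormatError("empty EM matrix: no header row found")
    header_line, header = rows[0]
    if len(header) < 2:
        raise FormatError(f"line {header_line}: header needs at least one reaction column")
    reaction_ids = tuple(header[1:])
    if len(set(reaction_ids)) != len(reaction_ids):
        raise FormatError(f"line {header_line}: duplicate reaction ids in header")
    modes: List[Tuple[str, Tuple[float, ...]]] = []
    seen: Dict[str, int] = {}
    for lineno, fields in rows[1:]:
        if len(fields) != len(header):
            raise FormatError(
                f"line {lineno}: expected {len(header)} columns, got {len(fields)}"
            )
        mode_id = fields[0]
        if mode_id in seen:
            raise FormatError(
                f"line {lineno}: duplicate mode id {mode_id!r} "
                f"(first seen on line {seen[mode_id]})"
            )
        seen[mode_id] = lineno
        values: List[float] = []
        for col, cell in zip(reaction_ids, fields[1:]):
            try:
                v = float(cell)
            except ValueError as exc:
                raise FormatError(
                    f"line {lineno}: non-numeric value {cell!r} in column {col!r}"
                ) from exc
            if binary and v not in (0.0, 1.0):
                raise FormatError(
                    f"line {lineno}: non-binary value {cell!r} in column {col!r} "
                    "(matrix declared binary)"
                )
            values.append(v)
        modes.append((mode_id, tuple(values)))
    if not modes:
        raise FormatError("EM matrix contains a header but no modes")
    return EMTable(reaction_ids=reaction_ids, modes=modes, binary=binary)


def write_em_matrix(table: EMTable, path: PathLike) -> None:
    lines = ["mode\t" + "\t".join(table.reaction_ids)]
    for mode_id, values in table.modes:
        cells = [
            str(int(v)) if table.binary else format(v, "g") for v in values
        ]
        lines.append(mode_id + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# partitions
# --------------------------------------------------------------------------

def read_partition(source: Union[PathLike, str], *, is_text: bool = False,
                   ) -> Dict[str, str]:
    """Read a two-column mode-id -> {goal|kill|helper} assignment."""
    rows = _read_rows(source, is_text=is_text)
    assignment: Dict[str, str] = {}
    for lineno, fields in rows:
        if len(fields) != 2:
            raise FormatError(f"line {lineno}: expected 2 columns, got {len(fields)}")
        mode_id, label = fields
        label_lc = label.lower()
        if label_lc not in CLASS_LABELS:
            raise FormatError(
                f"line {lineno}: unknown class label {label!r} "
                f"(use one of {', '.join(CLASS_LABELS)})"
            )
        if mode_id in assignment:
            raise FormatError(f"line {lineno}: duplicate mode id {mode_id!r}")
        assignment[mode_id] = label_lc
    return assignment


def write_partition_file(assignment: Mapping[str, str], path: PathLike) -> None:
    lines = [f"{mode}\t{label}" for mode, label in assignment.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def build_partition(table: EMTable, assignment: Mapping[str, str],
                    tol: float = DEFAULT_TOL) -> EMPartition:
    """Combine an EM table and a class assignment into a partition.

    Modes absent from the assignment default to the helper class — modes
    indifferent to the design may simply be left unlisted.
    """
    known = set(table.mode_ids())
    unknown = set(assignment) - known
    if unknown:
        raise FormatError(
            f"partition references unknown modes {sorted(unknown)}"
        )
    classes: Dict[str, List[BinaryEM]] = {c: [] for c in CLASS_LABELS}
    for em in table.to_binary(tol):
        label = assignment.get(em.mode_id, "helper")
        classes[label].append(em)
    return EMPartition(
        reaction_ids=table.reaction_ids,
        goal=tuple(classes["goal"]),
        kill=tuple(classes["kill"]),
        helper=tuple(classes["helper"]),
    )


# --------------------------------------------------------------------------
# reaction metadata
# --------------------------------------------------------------------------

_BOOL = {"1": True, "0": False, "true": True, "false": False,
         "yes": True, "no": False}


def read_reaction_meta(source: Union[PathLike, str], *, is_text: bool = False,
                       ) -> List[ReactionMeta]:
    """Read reaction metadata: id, is_uptake, is_annotated, n_isoenzymes[, weight]."""
    rows = _read_rows(source, is_text=is_text)
    if not rows:
        raise FormatError("empty metadata file")
    header_line, header = rows[0]
    expected = ["reaction_id", "is_uptake", "is_annotated", "n_isoenzymes"]
    if [h.lower() for h in header[:4]] != expected:
        raise FormatError(
            f"line {header_line}: metadata header must start with {expected}"
        )
    has_weight = len(header) > 4 and header[4].lower() == "weight"
    metas: List[ReactionMeta] = []
    for lineno, fields in rows[1:]:
        if len(fields) != len(header):
            raise FormatError(
                f"line {lineno}: expected {len(header)} columns, got {len(fields)}"
            )
        rid, up, ann, iso = fields[:4]
        try:
            is_uptake = _BOOL[up.lower()]
            is_annotated = _BOOL[ann.lower()]
        except KeyError as exc:
            raise FormatError(f"line {lineno}: bad boolean {exc.args[0]!r}") from None
        try:
            n_iso = int(iso)
        except ValueError:
            raise FormatError(f"line {lineno}: bad isoenzyme count {iso!r}") from None
        weight = None
        if has_weight and fields[4]:
            try:
                weight = float(fields[4])
            except ValueError:
                raise FormatError(
                    f"line {lineno}: bad weight {fields[4]!r}"
                ) from None
        metas.append(
            ReactionMeta(
                reaction_id=rid, is_uptake=is_uptake, is_annotated=is_annotated,
                n_isoenzymes=n_iso, weight=weight,
            )
        )
    return metas


def write_reaction_meta(metas: Sequence[ReactionMeta], path: PathLike) -> None:
    lines = ["reaction_id\tis_uptake\tis_annotated\tn_isoenzymes\tweight"]
    for m in metas:
        w = "" if m.weight is None else format(m.weight, "g")
        lines.append(
            f"{m.reaction_id}\t{int(m.is_uptake)}\t{int(m.is_annotated)}"
            f"\t{m.n_isoenzymes}\t{w}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# yield-based mode classification
# --------------------------------------------------------------------------

def classify_by_yield(table: EMTable, substrates: Sequence[str],
                      products: Sequence[str],
                      rel_tol: float = 1e-6) -> Dict[str, str]:
    """Assign goal/kill/helper labels from product-per-substrate yields.

    Per mode, yield = sum(|product fluxes|) / sum(|substrate fluxes|).
    Substrate-consuming modes within ``rel_tol`` of the maximum yield become
    goal, the remaining consumers kill, and non-consuming modes helper.
    Requires flux-valued (not binary) modes.
    """
    if table.binary:
        raise ValueError("classification by yield requires flux values, not supports")
    for col in list(substrates) + list(products):
        if col not in table.reaction_ids:
            raise ValueError(f"reaction column {col!r} absent from the EM matrix")
    idx = {r: i for i, r in enumerate(table.reaction_ids)}
    s_idx = [idx[r] for r in substrates]
    p_idx = [idx[r] for r in products]
    yields: Dict[str, Optional[float]] = {}
    for mode_id, values in table.modes:
        s = sum(abs(values[i]) for i in s_idx)
        if s <= 0:
            yields[mode_id] = None
        else:
            yields[mode_id] = sum(abs(values[i]) for i in p_idx) / s
    consuming = [y for y in yields.values() if y is not None]
    best = max(consuming) if consuming else 0.0
    out: Dict[str, str] = {}
    for mode_id, y in yields.items():
        if y is None:
            out[mode_id] = "helper"
        elif y >= best * (1 - rel_tol):
            out[mode_id] = "goal"
        else:
            out[mode_id] = "kill"
    return out


# --------------------------------------------------------------------------
# synthetic instances
# --------------------------------------------------------------------------

@dataclass
class RandomInstance:
    """A reproducible random partition plus uniform metadata for testing."""

    partition: EMPartition
    meta: List[ReactionMeta]
    feasible: bool
    seed: int


def generate_random_instance(n_reactions: int, n_modes: int,
                             support_size_range: Tuple[int, int] = (2, 6),
                             seed: int = 0) -> RandomInstance:
    """Draw a random partition: distinct random supports, one goal mode, a
    random nonempty kill subset, the rest helpers.

    The instance is flagged infeasible when some kill support is contained in
    the goal support (no cut can separate them); callers decide whether to
    keep or reject such draws.  Identical seeds give identical instances.
    """
    lo, hi = support_size_range
    if not (1 <= lo <= hi <= n_reactions):
        raise ValueError(
            f"support_size_range {support_size_range} incompatible with "
            f"{n_reactions} reactions"
        )
    rng = np.random.default_rng(seed)
    rids = tuple(f"R{i + 1}" for i in range(n_reactions))
    supports: List[Tuple[int, ...]] = []
    seen = set()
    attempts = 0
    while len(supports) < n_modes and attempts < 100 * n_modes:
        attempts += 1
        size = int(rng.integers(lo, hi + 1))
        active = rng.choice(n_reactions, size=size, replace=False)
        vec = tuple(1 if i in set(active.tolist()) else 0 for i in range(n_reactions))
        if vec not in seen:
            seen.add(vec)
            supports.append(vec)
    while len(supports) < n_modes:
        # too few distinct supports exist in the requested size range; fill
        # with duplicates (they collapse within a class and conflict across)
        size = int(rng.integers(lo, hi + 1))
        active = rng.choice(n_reactions, size=size, replace=False)
        supports.append(
            tuple(1 if i in set(active.tolist()) else 0 for i in range(n_reactions))
        )
    modes = [BinaryEM(f"EM{i + 1}", vec) for i, vec in enumerate(supports)]
    goal_idx = int(rng.integers(len(modes)))
    rest = [i for i in range(len(modes)) if i != goal_idx]
    n_kill = int(rng.integers(1, len(rest) + 1)) if rest else 0
    kill_idx = set(
        rng.choice(rest, size=n_kill, replace=False).tolist()
    ) if n_kill else set()
    goal = (modes[goal_idx],)
    kill = tuple(modes[i] for i in sorted(kill_idx))
    helper = tuple(
        modes[i] for i in range(len(modes)) if i != goal_idx and i not in kill_idx
    )
    partition = EMPartition(reaction_ids=rids, goal=goal, kill=kill, helper=helper)
    goal_set = set(goal[0].active_indices())
    feasible = all(
        set(em.active_indices()) - goal_set for em in kill
    )
    meta = [ReactionMeta(reaction_id=r) for r in rids]
    return RandomInstance(partition=partition, meta=meta, feasible=feasible, seed=seed)


# --------------------------------------------------------------------------
# result reporting
# --------------------------------------------------------------------------

def result_records(result: MCSResult,
                   meta: Optional[Sequence[ReactionMeta]] = None,
                   ) -> List[Dict[str, object]]:
    """Flatten an MCSResult into JSON-ready records with a stable field order.

    ``feasible_flag`` is True when no non-annotated reaction appears among the
    direct reaction deletions (the experimentally implementable solutions).
    """
    non_annotated = (
        {m.reaction_id for m in meta if not m.is_annotated and not m.is_uptake}
        if meta is not None
        else set()
    )
    records = []
    for sol in result.solutions:
        records.append(
            {
                "rank": sol.rank,
                "objective": round(sol.objective_value, 6),
                "reaction_deletions": sorted(sol.reaction_deletions),
                "gene_deletions": sorted(sol.gene_deletions),
                "regulation_forced_off": sorted(sol.regulation_forced_off),
                "n_surviving_helpers": sol.n_surviving_helpers,
                "feasible_flag": not (sol.reaction_deletions & non_annotated),
            }
        )
    return records


def write_results(result: MCSResult, path: PathLike, format: str = "json",
                  meta: Optional[Sequence[ReactionMeta]] = None) -> None:
    """Write enumeration results as JSON or a TSV mirror (lists comma-joined)."""
    records = result_records(result, meta)
    path = Path(path)
    if format == "json":
        payload = {
            "delta_min": result.delta_min,
            "exhausted": result.exhausted,
            "conflicts": list(result.conflicts),
            "solutions": records,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    elif format == "tsv":
        cols = ["rank", "objective", "reaction_deletions", "gene_deletions",
                "regulation_forced_off", "n_surviving_helpers", "feasible_flag"]
        lines = ["\t".join(cols)]
        for rec in records:
            cells = []
            for c in cols:
                v = rec[c]
                if isinstance(v, list):
                    cells.append(",".join(v))
                elif isinstance(v, bool):
                    cells.append(str(int(v)))
                elif v is None:
                    cells.append("")
                else:
                    cells.append(format_cell(v))
            lines.append("\t".join(cells))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown result format {format!r} (use json or tsv)")


def format_cell(v) -> str:
    if isinstance(v, float):
        return format(v, "g")
    return str(v)


def read_results(path: PathLike) -> Dict[str, object]:
    """Read back a JSON results file (round-trip counterpart of write_results)."""
    return json.loads(Path(path).read_text(encoding="utf-8"))


# --------------------------------------------------------------------------
# tiny-network text format (EM oracle input)
# --------------------------------------------------------------------------

def _parse_species(side: str, lineno: int) -> List[Tuple[Fraction, str]]:
    terms: List[Tuple[Fraction, str]] = []
    side = side.strip()
    if not side:
        return terms
    for chunk in side.split("+"):
        parts = chunk.split()
        if not parts:
            raise FormatError(f"line {lineno}: empty species term")
        if len(parts) == 1:
            coef, name = Fraction(1), parts[0]
        elif len(parts) == 2:
            try:
                coef = Fraction(parts[0])
            except (ValueError, ZeroDivisionError):
                raise FormatError(
                    f"line {lineno}: bad stoichiometric coefficient {parts[0]!r}"
                ) from None
            name = parts[1]
        else:
            raise FormatError(f"line {lineno}: cannot parse species term {chunk!r}")
        terms.append((coef, name))
    return terms


def read_network(source: Union[PathLike, str], *, is_text: bool = False,
                 ) -> NetworkModel:
    """Parse the tiny-network format.

    One reaction per line, ``ID : 2 A + B -> C [rev]``; metabolites declared
    external in a leading ``@ext`` block are excluded from the steady-state
    condition.  Either reaction side may be empty (pure uptake/excretion).
    """
    text = source if is_text else Path(source).read_text(encoding="utf-8")
    externals: set = set()
    reaction_ids: List[str] = []
    reversible: List[bool] = []
    stoich: Dict[Tuple[str, str], Fraction] = {}
    metabolites: List[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("@ext"):
            externals.update(line.split()[1:])
            continue
        if ":" not in line:
            raise FormatError(f"line {lineno}: missing ':' after reaction id")
        rid, body = (part.strip() for part in line.split(":", 1))
        if rid in reaction_ids:
            raise FormatError(f"line {lineno}: duplicate reaction id {rid!r}")
        rev = False
        if body.endswith("[rev]"):
            rev = True
            body = body[: -len("[rev]")].strip()
        if "->" not in body:
            raise FormatError(f"line {lineno}: missing '->' in reaction {rid!r}")
        lhs, rhs = body.split("->", 1)
        reaction_ids.append(rid)
        reversible.append(rev)
        for sign, side in ((Fraction(-1), lhs), (Fraction(1), rhs)):
            for coef, met in _parse_species(side, lineno):
                if met in externals:
                    continue
                if met not in metabolites:
                    metabolites.append(met)
                key = (met, rid)
                stoich[key] = stoich.get(key, Fraction(0)) + sign * coef
    stoich = {k: v for k, v in stoich.items() if v != 0}
    return NetworkModel(
        reaction_ids=tuple(reaction_ids),
        metabolite_ids=tuple(metabolites),
        stoichiometry=stoich,
        reversible=tuple(reversible),
        external_metabolites=frozenset(externals),
    )


def write_network(network: NetworkModel, path: PathLike) -> None:
    lines = []
    if network.external_metabolites:
        lines.append("@ext " + " ".join(sorted(network.external_metabolites)))
    for j, rid in enumerate(network.reaction_ids):
        lhs, rhs = [], []
        for met in network.metabolite_ids:
            coef = network.stoichiometry.get((met, rid), Fraction(0))
            if coef < 0:
                lhs.append(f"{-coef} {met}" if coef != -1 else met)
            elif coef > 0:
                rhs.append(f"{coef} {met}" if coef != 1 else met)
        arrow = " -> ".join([" + ".join(lhs), " + ".join(rhs)])
        suffix = " [rev]" if network.reversible[j] else ""
        lines.append(f"{rid} : {arrow}{suffix}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
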