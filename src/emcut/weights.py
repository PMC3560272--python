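"""Weight vectors encoding experimental feasibility of interventions.

The enumeration objective maximizes the weighted kept-reaction sum, so cheap
weights are deleted first.  The weighting guidelines:

* uptake reactions get a small weight (substrates are removed from the
  medium, not engineered) — the *sum* of all uptake weights must stay below
  the smallest non-uptake weight;
* annotated reactions are weighted by the number of independent enzymes or
  enzyme complexes catalyzing them in parallel (an enzyme complex counts
  once, however many genes encode it);
* reactions without gene annotation are effectively undeletable and get a
  weight larger than the sum of all deletable weights, so every solution
  touching them ranks below every fully implementable one.
"""

from __future__ import annotations

import math
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .core import ReactionMeta

DEFAULT_UPTAKE_WEIGHT = 0.1


def suggest_weights(meta: Sequence[ReactionMeta],
                    uptake_weight: float = DEFAULT_UPTAKE_WEIGHT,
                    undeletable_factor: float = 1.0,
                    undeletable_weight: Optional[float] = None,
                    ) -> Dict[str, float]:
    """Construct a weight vector from reaction metadata.

    Uptake reactions get ``uptake_weight``; annotated non-uptake reactions
    get ``max(1, n_isoenzymes)``; non-annotated non-uptake reactions get
    ``undeletable_weight`` if given, else ``ceil(sum of deletable weights) *
    undeletable_factor`` (bumped if necessary so it strictly exceeds that
    sum).  An explicit ``ReactionMeta.weight`` override always wins.
    """
    if not uptake_weight > 0:
        raise ValueError(f"uptake_weight must be positive, got {uptake_weight}")
    if not undeletable_factor > 0:
        raise ValueError(
            f"undeletable_factor must be positive, got {undeletable_factor}"
        )
    base: Dict[str, float] = {}
    deletable_sum = 0.0
    undeletable: List[str] = []
    for m in meta:
        if m.weight is not None:
            base[m.reaction_id] = float(m.weight)
            if m.is_uptake or m.is_annotated:
                deletable_sum += float(m.weight)
            continue
        if m.is_uptake:
            base[m.reaction_id] = uptake_weight
            deletable_sum += uptake_weight
        elif m.is_annotated:
            w = float(max(1, m.n_isoenzymes))
            base[m.reaction_id] = w
            deletable_sum += w
        else:
            undeletable.append(m.reaction_id)
    if undeletable:
        if undeletable_weight is None:
            w_u = math.ceil(deletable_sum) * undeletable_factor
            if not w_u > deletable_sum:
                w_u = math.floor(deletable_sum) + 1.0
        else:
            w_u = float(undeletable_weight)
        for r in undeletable:
            base[r] = w_u
    return base


def validate_weights(weights: Mapping[str, float],
                     meta: Sequence[ReactionMeta]) -> List[str]:
    """Check a weight vector against the feasibility guidelines.

    Returns named violations (empty list when valid): (i) the sum of uptake
    weights must be smaller than the smallest non-uptake weight; (ii) every
    non-annotated non-uptake weight must exceed the sum of all deletable
    (uptake + annotated) weights.
    """
    missing = [m.reaction_id for m in meta if m.reaction_id not in weights]
    if missing:
        raise ValueError(f"weights missing for reactions {missing}")
    diags: List[str] = []
    uptake_sum = sum(float(weights[m.reaction_id]) for m in meta if m.is_uptake)
    non_uptake = [float(weights[m.reaction_id]) for m in meta if not m.is_uptake]
    if non_uptake and any(m.is_uptake for m in meta):
        smallest = min(non_uptake)
        if not uptake_sum < smallest:
            diags.append(
                f"uptake rule: sum of uptake weights {uptake_sum:g} is not smaller "
                f"than the smallest non-uptake weight {smallest:g}"
            )
    deletable_sum = sum(
        float(weights[m.reaction_id]) for m in meta if m.is_uptake or m.is_annotated
    )
    for m in meta:
        if m.is_uptake or m.is_annotated:
            continue
        w = float(weights[m.reaction_id])
        if not w > deletable_sum:
            diags.append(
                f"undeletable rule: weight {w:g} of non-annotated reaction "
                f"{m.reaction_id!r} does not exceed the deletable sum {deletable_sum:g}"
            )
    return diags


def jitter_weights(weights: Mapping[str, float], seed: int,
                   rel: float = 0.2) -> Dict[str, float]:
    """Multiply each weight by Uniform(1 - rel, 1 + rel), reproducibly.

    Supports robustness experiments: re-enumerating under jittered weights
    shows whether the top-ranked solutions are stable against weight
    uncertainty.
    """
    if not 0 <= rel < 1:
        raise ValueError(f"rel must lie in [0, 1), got {rel}")
    rng = np.random.default_rng(seed)
    items = list(weights.items())
    factors = rng.uniform(1 - rel, 1 + rel, size=len(items))
    return {r: float(w) * float(f) for (r, w), f in zip(items, factors)}
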