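"""Binarization of real-valued EM flux vectors and support containment.

A reaction counts as active in a mode if it carries flux in forward *or*
backward direction, so supports are taken on absolute values.  Containment of
mode ``e`` in a flux pattern ``v`` is the inner-product test
``e^T v == ||e||``.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence, Union

from .core import BinaryEM

DEFAULT_TOL = 1e-9


def binarize_flux_vector(flux: Sequence[float], tol: float = DEFAULT_TOL,
                         mode_id: str = "") -> BinaryEM:
    """Convert a real-valued flux vector to its binary support.

    ``support[i] = 1`` iff ``|flux[i]| > tol``.  EM tools emit near-zero
    float noise, hence the tolerance; a warning is raised for entries whose
    magnitude falls within a decade of ``tol`` (ambiguous zeros).

    Raises
    ------
    ValueError
        If ``tol`` is not positive or any entry is NaN/inf.
    """
    if not tol > 0:
        raise ValueError(f"tol must be positive, got {tol}")
    values = [float(v) for v in flux]
    for i, v in enumerate(values):
        if not math.isfinite(v):
            raise ValueError(f"non-finite flux value {v!r} at position {i}")
    ambiguous = [i for i, v in enumerate(values) if tol / 10 < abs(v) < tol * 10]
    if ambiguous:
        warnings.warn(
            f"flux magnitudes near the binarization tolerance {tol:g} at "
            f"positions {ambiguous}; support may be tolerance-sensitive",
            stacklevel=2,
        )
    support = tuple(1 if abs(v) > tol else 0 for v in values)
    return BinaryEM(mode_id=mode_id, support=support)


def support_contains(container: Union[BinaryEM, Sequence[int]],
                     mode: BinaryEM) -> bool:
    """True iff every active reaction of ``mode`` is active in ``container``.

    Implements the inner-product test ``e^T v == ||e||``: the containing
    pattern may be another mode's support or any 0/1 flux pattern.
    """
    vec = container.support if isinstance(container, BinaryEM) else tuple(container)
    if len(vec) != len(mode.support):
        raise ValueError(
            f"length mismatch: container has {len(vec)} entries, "
            f"mode {mode.mode_id!r} has {len(mode.support)}"
        )
    dot = sum(e * int(v) for e, v in zip(mode.support, vec))
    return dot == mode.norm
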