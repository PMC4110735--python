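"""Expression-profile preprocessing: angles and regulation signs per edge.

An *edge* is the segment between two consecutive expression values of one
gene; a profile over M conditions has M-1 edges.  Each edge is summarised
by two numbers:

* the **regulation pattern**, +1 for an upward step and -1 for a downward
  step, and
* the **degree of fluctuation**, the angular deviation of the edge on the
  180-degree plane obtained from the two-argument arctangent of the bounding
  values: ``a = |atan2(next, prev)|`` in degrees, replaced by ``180 - a``
  when the step goes down.

The arctangent is taken of the raw expression values (not of the step), so
the representation depends only on the direction of the point
(prev, next) in the plane — it is invariant to multiplying a profile by a
positive constant.  Angles are kept at full floating-point precision;
rounding to whole degrees is purely presentational.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .containers import EdgeRepresentation, ExpressionMatrix
from .errors import ValidationError

__all__ = ["compute_regulation", "compute_fluctuation", "transform_matrix"]


def compute_regulation(prev: float, next: float) -> int:
    """Sign of the step from ``prev`` to ``next``: +1 up, -1 down.

    A tie (prev == next) is assigned +1: ties have measure zero in
    continuous expression data and a deterministic choice keeps the
    two-letter {-1, +1} alphabet.
    """
    if not (math.isfinite(prev) and math.isfinite(next)):
        raise ValidationError(f"non-finite expression values ({prev}, {next})")
    return -1 if prev > next else 1


def compute_fluctuation(prev: float, next: float) -> float:
    """Degree of fluctuation of the edge (prev -> next), in [0, 180] degrees.

    Computed as ``|atan2(next, prev)|`` in degrees, mapped to
    ``180 - |atan2(next, prev)|`` for a downward step.  The degenerate
    (0, 0) edge yields angle 0 (the atan2 convention) with a warning.
    """
    if not (math.isfinite(prev) and math.isfinite(next)):
        raise ValidationError(f"non-finite expression values ({prev}, {next})")
    if prev == 0.0 and next == 0.0:
        warnings.warn("degenerate (0, 0) edge: angle defined as 0", stacklevel=2)
    angle = abs(math.degrees(math.atan2(next, prev)))
    if next < prev:
        return 180.0 - angle
    return angle


def transform_matrix(em: ExpressionMatrix) -> EdgeRepresentation:
    """Transform an expression matrix into its edge representation.

    Column k of the result describes the edge between conditions k and k+1;
    both output matrices have shape N x (M-1).
    """
    if em.n_conditions < 2:
        raise ValidationError("at least two conditions required to form edges")
    prev = em.values[:, :-1]
    nxt = em.values[:, 1:]
    if np.any((prev == 0.0) & (nxt == 0.0)):
        warnings.warn("degenerate (0, 0) edge(s): angle defined as 0", stacklevel=2)
    angles = np.abs(np.degrees(np.arctan2(nxt, prev)))
    angles = np.where(nxt < prev, 180.0 - angles, angles)
    regulations = np.where(prev > nxt, -1, 1)
    return EdgeRepresentation(
        gene_ids=list(em.gene_ids), angles=angles, regulations=regulations
    )
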