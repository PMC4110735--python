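"""Per-edge pattern similarity and one-pass pair-support counting.

Two genes' k-th edges match **positively** when they step the same way and
their angles differ by less than tau, and **negatively** when they step
opposite ways and the sum of their angles is within tau of 180 degrees
(a perfect mirror pair (a, 180-a) sums to exactly 180).  Support is the
fraction of a pair's M-1 edges that match, counted separately for the two
polarities.

``build_correlogram`` accumulates these counts for all N*(N-1)/2 unordered
pairs in a single pass over the transposed edge table: each edge column is
visited exactly once and all pair comparisons for that column happen inside
the visit.
"""

from __future__ import annotations

import numpy as np

from .containers import CorrelogramMatrix, EdgeRepresentation
from .errors import ParameterError, ValidationError

__all__ = [
    "pos_sim",
    "neg_sim",
    "build_correlogram",
    "pos_support",
    "neg_support",
    "support_table",
]

#: Default angle threshold tau in degrees (useful range roughly 15-25).
DEFAULT_TAU = 20.0


def _check_tau(tau: float) -> None:
    if not 0.0 < tau < 180.0:
        raise ParameterError(f"tau must be in (0, 180) degrees, got {tau}")


def pos_sim(angle_i: float, reg_i: int, angle_j: float, reg_j: int,
            tau: float = DEFAULT_TAU) -> int:
    """1 iff the edges share their regulation sign and |angle_i - angle_j| < tau."""
    _check_tau(tau)
    return int(reg_i == reg_j and abs(angle_i - angle_j) < tau)


def neg_sim(angle_i: float, reg_i: int, angle_j: float, reg_j: int,
            tau: float = DEFAULT_TAU) -> int:
    """1 iff the edges have opposite regulation signs and the sum of their
    angles is within tau of 180 degrees."""
    _check_tau(tau)
    return int(reg_i == -reg_j and abs(180.0 - (angle_i + angle_j)) < tau)


def build_correlogram(er: EdgeRepresentation, tau: float = DEFAULT_TAU) -> CorrelogramMatrix:
    """Accumulate positive/negative match counts for every unordered gene pair.

    Single pass over the M-1 edge columns; per column, the pairwise
    comparisons are evaluated vectorised over the condensed upper triangle.
    """
    _check_tau(tau)
    n = er.n_genes
    if n < 2:
        raise ValidationError("need at least two genes to build a correlogram")
    iu, ju = np.triu_indices(n, k=1)
    pos = np.zeros(iu.shape[0], dtype=np.int64)
    neg = np.zeros(iu.shape[0], dtype=np.int64)
    for k in range(er.n_edges):  # the one pass: each edge column visited once
        a = er.angles[:, k]
        r = er.regulations[:, k]
        same_reg = r[iu] == r[ju]
        pos += same_reg & (np.abs(a[iu] - a[ju]) < tau)
        neg += ~same_reg & (np.abs(180.0 - (a[iu] + a[ju])) < tau)
    return CorrelogramMatrix(
        gene_ids=list(er.gene_ids), pos_counts=pos, neg_counts=neg, n_edges=er.n_edges
    )


def pos_support(cm: CorrelogramMatrix, i: int, j: int) -> float:
    """Fraction of edges on which genes i and j match positively."""
    return cm.pos_counts[cm.pair_index(i, j)] / cm.n_edges


def neg_support(cm: CorrelogramMatrix, i: int, j: int) -> float:
    """Fraction of edges on which genes i and j match negatively."""
    return cm.neg_counts[cm.pair_index(i, j)] / cm.n_edges


def support_table(cm: CorrelogramMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Condensed (pos_support, neg_support) arrays over all unordered pairs."""
    return cm.pos_counts / cm.n_edges, cm.neg_counts / cm.n_edges
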