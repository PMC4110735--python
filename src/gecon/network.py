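"""Signed network construction and module extraction.

A gene pair is *strongly connected* when its combined support
pos + neg strictly exceeds the threshold theta.  The edge carries sign +1
when the positive support alone exceeds theta and -1 when the negative
support does; when theta < 0.5 a pair can pass on combined support with
neither component above theta, in which case the sign of the larger
component is used (ties +1).  With the recommended theta >= 0.5 that
fallback branch is unreachable.

Modules are the connected components of the nonzero adjacency
(sign-agnostic reachability); isolated genes belong to no module.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .containers import CorrelogramMatrix, ModulePartition, SignedNetwork
from .errors import ContractError, ParameterError
from .support import support_table

__all__ = [
    "is_strongly_connected",
    "edge_sign",
    "build_network",
    "extract_modules",
]

#: Default support-fraction threshold theta.
DEFAULT_THETA = 0.5


def _check_theta(theta: float) -> None:
    if not 0.0 <= theta < 1.0:
        raise ParameterError(f"theta must be in [0, 1), got {theta}")


def is_strongly_connected(pos: float, neg: float, theta: float = DEFAULT_THETA) -> bool:
    """True iff pos + neg > theta (strict)."""
    _check_theta(theta)
    return pos + neg > theta


def edge_sign(pos: float, neg: float, theta: float = DEFAULT_THETA) -> int:
    """Sign of a strongly connected pair's edge: +1 positive co-regulation,
    -1 negative.  Must only be called on strongly connected pairs."""
    _check_theta(theta)
    if pos + neg <= theta:
        raise ContractError("edge_sign called on a pair that is not strongly connected")
    if pos > theta:
        return 1
    if neg > theta:
        return -1
    # combined support passed but neither component alone did (theta < 0.5)
    return 1 if pos >= neg else -1


def build_network(cm: CorrelogramMatrix, theta: float = DEFAULT_THETA) -> SignedNetwork:
    """Threshold the correlogram into a signed adjacency matrix.

    Walks the condensed pair structure once, calling the connection and
    sign predicates per unordered pair.
    """
    _check_theta(theta)
    n = cm.n_genes
    pos_s, neg_s = support_table(cm)
    adjacency = np.zeros((n, n), dtype=np.int8)
    edge_scores: dict[tuple[int, int], float] = {}
    idx = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            p, q = pos_s[idx], neg_s[idx]
            idx += 1
            if is_strongly_connected(p, q, theta):
                s = edge_sign(p, q, theta)
                adjacency[i, j] = adjacency[j, i] = s
                edge_scores[(i, j)] = p + q
    return SignedNetwork(gene_ids=list(cm.gene_ids), adjacency=adjacency,
                         edge_scores=edge_scores)


def extract_modules(net: SignedNetwork, min_module_size: int = 2) -> ModulePartition:
    """Connected components of the nonzero adjacency as gene modules.

    Components smaller than ``min_module_size`` are dropped; with the
    default of 2 this only removes isolated genes.  Modules are ordered by
    decreasing size, then by lexicographically smallest member.
    """
    g = nx.Graph()
    g.add_nodes_from(net.gene_ids)
    for a, b, _sign, _score in net.iter_edges():
        g.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) >= min_module_size]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return ModulePartition(modules=comps)
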