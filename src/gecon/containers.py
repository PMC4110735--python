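"""Core data containers for signed co-expression network reconstruction.

The pipeline moves through four representations: an expression matrix
(genes x conditions), its edge representation (per-gene angular deviations
and regulation signs over the M-1 segments between consecutive conditions),
a correlogram of per-pair positive/negative match counts, and the final
signed network.  All containers validate their invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "ExpressionMatrix",
    "EdgeRepresentation",
    "CorrelogramMatrix",
    "SignedNetwork",
    "ModulePartition",
    "GoldStandard",
    "RankedPrediction",
    "EvalScores",
    "condensed_index",
]


def condensed_index(i: int, j: int, n: int) -> int:
    """Index of unordered pair (i, j), i < j, in a condensed upper-triangular
    array of length n*(n-1)/2 (same layout as scipy's pdist)."""
    if i > j:
        i, j = j, i
    if i == j:
        raise ValidationError(f"self-pair ({i},{i}) has no condensed index")
    return n * i - i * (i + 1) // 2 + (j - i - 1)


@dataclass
class ExpressionMatrix:
    """Real-valued expression values with gene and condition identifiers.

    Values are in the input's expression units (typically log-ratio or
    intensity); the method downstream is insensitive to their absolute scale.
    """

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.shape
        if n < 1 or m < 2:
            raise ValidationError(
                f"expression matrix must have >=1 gene and >=2 conditions, got {n}x{m}"
            )
        if len(self.gene_ids) != n or len(self.condition_ids) != m:
            raise ValidationError("identifier lists do not match matrix shape")
        if len(set(self.gene_ids)) != n:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene identifiers: {dupes}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value at gene '{self.gene_ids[i]}', "
                f"condition '{self.condition_ids[j]}'"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]


@dataclass
class EdgeRepresentation:
    """Per-gene transform of a profile into M-1 edge descriptors.

    ``angles`` holds the degree of fluctuation of each edge in [0, 180]
    degrees at full floating-point precision; ``regulations`` holds the
    up/down step sign in {-1, +1}.
    """

    gene_ids: list[str]
    angles: np.ndarray
    regulations: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.regulations = np.asarray(self.regulations, dtype=np.int8)
        if self.angles.shape != self.regulations.shape:
            raise ValidationError("angles and regulations must have identical shape")
        if self.angles.shape[0] != len(self.gene_ids):
            raise ValidationError("gene_ids length does not match row count")
        if self.angles.ndim != 2 or self.angles.shape[1] < 1:
            raise ValidationError("edge representation needs at least one edge column")
        if np.any((self.angles < 0) | (self.angles > 180)):
            raise ValidationError("angles must lie in [0, 180] degrees")
        if not np.all(np.isin(self.regulations, (-1, 1))):
            raise ValidationError("regulations must be -1 or +1")

    @property
    def n_genes(self) -> int:
        return self.angles.shape[0]

    @property
    def n_edges(self) -> int:
        return self.angles.shape[1]


@dataclass
class CorrelogramMatrix:
    """Condensed upper-triangular pair-count structure.

    For each unordered gene pair, the number of edges (out of ``n_edges``)
    on which the pair matched positively resp. negatively.  Stored as two
    flat arrays of length N*(N-1)/2, accumulated in a single pass over the
    transposed edge table.
    """

    gene_ids: list[str]
    pos_counts: np.ndarray
    neg_counts: np.ndarray
    n_edges: int

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        expected = n * (n - 1) // 2
        self.pos_counts = np.asarray(self.pos_counts, dtype=np.int64)
        self.neg_counts = np.asarray(self.neg_counts, dtype=np.int64)
        if self.pos_counts.shape != (expected,) or self.neg_counts.shape != (expected,):
            raise ValidationError(
                f"condensed count arrays must have length {expected} for {n} genes"
            )
        if np.any(self.pos_counts < 0) or np.any(self.neg_counts < 0):
            raise ValidationError("pair counts must be non-negative")
        if np.any(self.pos_counts + self.neg_counts > self.n_edges):
            raise ValidationError("pos + neg counts exceed the number of edges")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def pair_index(self, i: int, j: int) -> int:
        return condensed_index(i, j, self.n_genes)


@dataclass
class SignedNetwork:
    """Symmetric signed adjacency with per-edge combined-support scores.

    ``adjacency[i, j]`` is +1 for a positively co-regulated pair, -1 for a
    negatively co-regulated pair, 0 for no edge.  ``edge_scores`` maps each
    nonzero unordered index pair (i < j) to pos_support + neg_support.
    """

    gene_ids: list[str]
    adjacency: np.ndarray
    edge_scores: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.int8)
        n = len(self.gene_ids)
        if self.adjacency.shape != (n, n):
            raise ValidationError("adjacency must be square over gene_ids")
        if np.any(self.adjacency != self.adjacency.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValidationError("adjacency diagonal must be zero")
        if not np.all(np.isin(self.adjacency, (-1, 0, 1))):
            raise ValidationError("adjacency entries must be in {-1, 0, +1}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edge_scores)

    def iter_edges(self):
        """Yield (gene_a, gene_b, sign, score) for each edge, i < j order."""
        for (i, j), score in sorted(self.edge_scores.items()):
            yield self.gene_ids[i], self.gene_ids[j], int(self.adjacency[i, j]), score


@dataclass
class ModulePartition:
    """Disjoint gene modules: connected components of the signed network.

    Modules are ordered by decreasing size, ties broken by lexicographically
    smallest member; genes inside a module are sorted.  Isolated genes are
    unassigned.
    """

    modules: list[list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mod in self.modules:
            for g in mod:
                if g in seen:
                    raise ValidationError(f"gene '{g}' assigned to two modules")
                seen.add(g)

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def labels(self) -> dict[str, int]:
        return {g: k for k, mod in enumerate(self.modules) for g in mod}


@dataclass
class GoldStandard:
    """Undirected gold-standard network: a positive pair set over a gene universe.

    Pairs are stored as sorted identifier tuples; every pair of universe
    genes not in ``positives`` is implicitly a negative.
    """

    gene_ids: list[str]
    positives: set[tuple[str, str]]

    def __post_init__(self) -> None:
        universe = set(self.gene_ids)
        for a, b in self.positives:
            if a == b:
                raise ValidationError(f"self-pair ('{a}', '{a}') in gold standard")
            if a > b:
                raise ValidationError(f"pair ('{a}', '{b}') not in sorted order")
            if a not in universe or b not in universe:
                raise ValidationError(f"pair ('{a}', '{b}') outside gene universe")

    @property
    def n_positives(self) -> int:
        return len(self.positives)


@dataclass
class RankedPrediction:
    """Unordered gene pairs with finite confidence scores, for curve drawing."""

    pairs: list[tuple[str, str]]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.pairs) != len(self.scores):
            raise ValidationError("pairs and scores length mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("confidence scores must be finite")
        if len(set(map(tuple, self.pairs))) != len(self.pairs):
            raise ValidationError("duplicate pairs in ranked prediction")


@dataclass
class EvalScores:
    """Summary accuracies of a predicted network against a gold standard."""

    aupr: float
    auroc: float
    f_beta_max: float
    f_beta_avg: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("aupr", "auroc", "f_beta_max", "f_beta_avg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
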