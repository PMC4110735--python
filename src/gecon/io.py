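"""Readers and writers for the package's plain-text formats.

* expression matrix — tab-separated table, first row condition IDs, first
  column gene IDs;
* gold standard — three tab-separated columns ``regulator  target  {0,1}``
  (the DREAM-challenge dialect); directed entries are symmetrised and
  duplicates collapsed by logical OR;
* signed edge list — ``geneA  geneB  sign  support`` with a header row,
  one line per unordered pair in lexicographic order;
* module table — ``gene  module_id``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .containers import (ExpressionMatrix, GoldStandard, ModulePartition,
                         SignedNetwork)
from .errors import ParseError, ValidationError

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gold_edgelist",
    "write_gold_edgelist",
    "read_signed_edgelist",
    "write_signed_edgelist",
    "write_module_table",
    "write_scores_report",
]

EDGELIST_HEADER = ["gene_a", "gene_b", "sign", "support"]


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Parse a tab-separated expression matrix, locating any bad cell."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: cannot parse expression table: {exc}") from exc
    if df.shape[0] < 1 or df.shape[1] < 2:
        raise ValidationError(
            f"{path}: need >=1 gene row and >=2 condition columns, got {df.shape}"
        )
    gene_ids = [str(g) for g in df.index]
    dupes = sorted(df.index[df.index.duplicated()].unique())
    if dupes:
        raise ValidationError(f"{path}: duplicate gene identifiers: {list(map(str, dupes))}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = next(zip(*bad.to_numpy().nonzero()))
        raise ValidationError(
            f"{path}: non-numeric or missing value at gene '{gene_ids[r]}', "
            f"condition '{df.columns[c]}'"
        )
    return ExpressionMatrix(
        gene_ids=gene_ids,
        condition_ids=[str(c) for c in df.columns],
        values=numeric.to_numpy(dtype=float),
    )


def write_expression_tsv(em: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(em.values, index=em.gene_ids, columns=em.condition_ids)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_gold_edgelist(path: str | Path) -> GoldStandard:
    """Parse a DREAM-dialect edge list into an undirected gold standard.

    Gene universe = every identifier mentioned in the file.  A pair is
    positive iff any line labels it 1 in either direction; self-edges are
    dropped with a warning.
    """
    path = Path(path)
    genes: set[str] = set()
    positives: set[tuple[str, str]] = set()
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(parts)}"
                )
            a, b, label = parts
            if label not in ("0", "1"):
                raise ParseError(f"{path}:{lineno}: label must be 0 or 1, got '{label}'")
            if a == b:
                warnings.warn(f"{path}:{lineno}: self-edge '{a}' dropped", stacklevel=2)
                continue
            n_lines += 1
            genes.update((a, b))
            if label == "1":
                positives.add(tuple(sorted((a, b))))
    if n_lines == 0:
        warnings.warn(f"{path}: empty gold standard", stacklevel=2)
    return GoldStandard(gene_ids=sorted(genes), positives=positives)


def write_gold_edgelist(gold: GoldStandard, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(gold.positives):
            fh.write(f"{a}\t{b}\t1\n")


def write_signed_edgelist(net: SignedNetwork, path: str | Path) -> None:
    """Write ``geneA geneB sign support`` rows, lexicographic pair order."""
    rows = sorted(
        (min(a, b), max(a, b), sign, score)
        for a, b, sign, score in net.iter_edges()
    )
    with open(path, "w") as fh:
        fh.write("\t".join(EDGELIST_HEADER) + "\n")
        for a, b, sign, score in rows:
            fh.write(f"{a}\t{b}\t{sign:+d}\t{score:.6f}\n")


def read_signed_edgelist(path: str | Path) -> tuple[list[tuple[str, str, int, float]], list[str]]:
    """Read a signed edge list; returns (edges, gene_ids seen)."""
    path = Path(path)
    edges: list[tuple[str, str, int, float]] = []
    genes: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != EDGELIST_HEADER:
            raise ParseError(f"{path}:1: unexpected header {header}")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            a, b, sign_s, support_s = parts
            try:
                sign = int(sign_s)
                support = float(support_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad sign/support") from exc
            if sign not in (-1, 1):
                raise ParseError(f"{path}:{lineno}: sign must be -1 or +1")
            edges.append((a, b, sign, support))
            genes.update((a, b))
    return edges, sorted(genes)


def write_module_table(partition: ModulePartition, path: str | Path) -> None:
    """``gene<TAB>module_id``; module IDs follow the partition's ordering
    (decreasing size, then lexicographic smallest member)."""
    with open(path, "w") as fh:
        fh.write("gene\tmodule_id\n")
        for mid, module in enumerate(partition.modules, start=1):
            for g in module:
                fh.write(f"{g}\t{mid}\n")


def write_scores_report(scores: dict[str, float], path: str | Path) -> None:
    """Tab-separated key-value report."""
    with open(path, "w") as fh:
        for key, value in scores.items():
            fh.write(f"{key}\t{value:.6f}\n")
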