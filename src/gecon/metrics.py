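"""Network-prediction accuracy: precision-recall, ROC, their areas, F_beta.

The predicted network is scored against an undirected gold standard over a
common gene universe.  Because the method's output is a thresholded network
rather than a full edge ranking, the combined support pos + neg of each
retained edge serves as its confidence; every pair without an edge gets
confidence 0.  The edge *sign* is ignored for scoring — the gold standard
labels pairs as interacting or not, without polarity.

Curves are generated by sweeping a decision threshold over the distinct
confidence values in descending order (ties enter together).  The PR curve
is anchored at (recall 0, precision of the top threshold) so that a
degenerate all-tied ranking integrates to the positive prevalence; the ROC
curve is anchored at (0, 0).  Areas use trapezoidal integration.

F_beta is the weighted harmonic mean (1+b^2) P R / (b^2 P + R); beta < 1
weighs precision higher, and the default beta = 0.5 reflects that in
network inference false positives are usually costlier than misses.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np

from .containers import EvalScores, GoldStandard, RankedPrediction, SignedNetwork
from .errors import ParameterError, ReconciliationError, ValidationError

__all__ = [
    "f_beta",
    "pr_curve",
    "roc_curve",
    "auc",
    "evaluate",
    "prediction_from_network",
]

DEFAULT_BETA = 0.5


def f_beta(precision: float, recall: float, beta: float = DEFAULT_BETA) -> float:
    """Weighted harmonic mean of precision and recall.

    Defined as 0 (with a warning) when precision = recall = 0.
    """
    if beta < 0:
        raise ParameterError(f"beta must be >= 0, got {beta}")
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ParameterError("precision and recall must lie in [0, 1]")
    if precision == 0.0 and recall == 0.0:
        warnings.warn("F_beta undefined at precision = recall = 0; returning 0",
                      stacklevel=2)
        return 0.0
    b2 = beta * beta
    return (1 + b2) * precision * recall / (b2 * precision + recall)


def _confusion_sweep(pred: RankedPrediction, gold: GoldStandard):
    """Cumulative TP/FP at each distinct confidence threshold, descending.

    Pairs of the gold universe absent from ``pred`` are appended with
    confidence 0.  Returns (tp, fp, n_pos, n_neg) where tp/fp are arrays
    with one entry per distinct threshold.
    """
    universe = {tuple(sorted(p)) for p in combinations(gold.gene_ids, 2)}
    listed = {tuple(sorted(p)) for p in pred.pairs}
    stray = sorted(listed - universe)
    if stray:
        raise ReconciliationError(
            f"predicted pairs outside the gold gene universe: {stray[:10]}"
        )
    if gold.n_positives == 0:
        raise ValidationError("gold standard has no positive pairs; recall undefined")

    scores = dict(zip((tuple(sorted(p)) for p in pred.pairs), pred.scores))
    all_pairs = sorted(universe)
    s = np.array([scores.get(p, 0.0) for p in all_pairs])
    y = np.array([p in gold.positives for p in all_pairs], dtype=int)

    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    # indices of the last element of each tie group = points of the sweep
    last_in_group = np.nonzero(np.diff(s, append=s[-1] - 1.0))[0]
    tp = np.cumsum(y)[last_in_group]
    fp = np.cumsum(1 - y)[last_in_group]
    return tp, fp, int(y.sum()), int((1 - y).sum())


def pr_curve(pred: RankedPrediction, gold: GoldStandard) -> tuple[np.ndarray, np.ndarray]:
    """Precision-recall points (recall ascending), anchored at recall 0."""
    tp, fp, n_pos, _ = _confusion_sweep(pred, gold)
    precision = tp / (tp + fp)
    recall = tp / n_pos
    recall = np.concatenate(([0.0], recall))
    precision = np.concatenate(([precision[0]], precision))
    return recall, precision


def roc_curve(pred: RankedPrediction, gold: GoldStandard) -> tuple[np.ndarray, np.ndarray]:
    """ROC points (FPR ascending), anchored at (0, 0)."""
    tp, fp, n_pos, n_neg = _confusion_sweep(pred, gold)
    if n_neg == 0:
        raise ValidationError("gold standard has no negative pairs; FPR undefined")
    fpr = np.concatenate(([0.0], fp / n_neg))
    tpr = np.concatenate(([0.0], tp / n_pos))
    return fpr, tpr


def auc(x: np.ndarray, y: np.ndarray) -> float:
    """Trapezoidal area under a curve given by points with x non-decreasing."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("need at least two curve points with matching shapes")
    if np.any(np.diff(x) < 0):
        raise ValidationError("x coordinates must be non-decreasing")
    return float(np.trapezoid(y, x))


def prediction_from_network(net: SignedNetwork) -> RankedPrediction:
    """Rank the network's edges by combined support (sign discarded)."""
    pairs, scores = [], []
    for a, b, _sign, score in net.iter_edges():
        pairs.append((a, b))
        scores.append(score)
    return RankedPrediction(pairs=pairs, scores=np.array(scores, dtype=float))


def evaluate(net: SignedNetwork, gold: GoldStandard,
             beta: float = DEFAULT_BETA) -> EvalScores:
    """Score a signed network against a gold standard.

    The gene universe is the gold standard's; any predicted-edge gene
    missing from it raises a reconciliation error naming the offenders.
    ``f_beta_max`` (and ``f_beta_avg``) summarise F_beta over the threshold
    sweep of the PR curve.
    """
    missing = sorted(
        {g for (i, j) in net.edge_scores
         for g in (net.gene_ids[i], net.gene_ids[j])} - set(gold.gene_ids)
    )
    if missing:
        raise ReconciliationError(
            f"predicted-edge genes absent from gold universe: {missing[:10]}"
        )
    pred = prediction_from_network(net)
    recall, precision = pr_curve(pred, gold)
    fpr, tpr = roc_curve(pred, gold)
    # sweep points only (drop the recall-0 anchor) for the F summaries
    fbs = [f_beta(p, r, beta) for p, r in zip(precision[1:], recall[1:])
           if not (p == 0.0 and r == 0.0)]
    if not fbs:
        fbs = [0.0]
    return EvalScores(
        aupr=auc(recall, precision),
        auroc=auc(fpr, tpr),
        f_beta_max=float(max(fbs)),
        f_beta_avg=float(np.mean(fbs)),
        beta=beta,
    )
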