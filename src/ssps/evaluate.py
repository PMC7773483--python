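"""Scoring predicted networks.

Edge recovery is treated as probabilistic binary classification over all
ordered vertex pairs and scored with AUCPR, estimated by average precision
(the trapezoidal PR estimate is optimistic; average precision is not).
Average precision suits sparse graphs: true edges grow linearly with |V|
while candidate edges grow quadratically, so prevalence shrinks and ROC-style
metrics become insensitive.

Differential performance against the prior-knowledge baseline (which simply
reports the confidence matrix C as its prediction) is summarized by a paired
t-statistic over replicate datasets.

For benchmarks scored on causal reach rather than individual edges, a
predicted *descendant set* is obtained by thresholding edge probabilities and
taking graph reachability from a source vertex; sweeping the threshold gives
a ROC curve against a gold descendant set, integrated by the trapezoidal
rule.  Repeat-run score ranges are compared with a strict *dominance* rule:
a stochastic method dominates a deterministic one only when its minimum score
beats the other's score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.metrics import average_precision_score

__all__ = [
    "ScoredPrediction",
    "average_precision",
    "aucpr_of_prediction",
    "paired_t_statistic",
    "descendant_set",
    "descendant_auroc",
    "dominance",
]


@dataclass
class ScoredPrediction:
    """Edge confidence scores paired with the binary ground truth."""

    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have matching shapes")
        uniq = set(np.unique(self.labels).tolist())
        if not uniq <= {0, 1}:
            raise ValueError("labels must be binary")
        self.labels = self.labels.astype(int)


def average_precision(scores, labels) -> float:
    """Average precision: sum over descending score thresholds of
    (recall step) x (precision), tied scores entering as one block.

    Requires at least one positive label.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.sum() == 0:
        raise ValueError("average precision is undefined without positive labels")
    return float(average_precision_score(labels, scores))


def aucpr_of_prediction(pred: ScoredPrediction, include_diagonal: bool = True) -> float:
    """AUCPR of a matrix-shaped prediction; optionally masks self-edges."""
    scores, labels = pred.scores, pred.labels
    if not include_diagonal:
        if scores.ndim != 2 or scores.shape[0] != scores.shape[1]:
            raise ValueError("diagonal masking requires a square matrix")
        mask = ~np.eye(scores.shape[0], dtype=bool)
        scores, labels = scores[mask], labels[mask]
    return average_precision(scores, labels)


def paired_t_statistic(method_scores, baseline_scores) -> float:
    """Paired t-statistic of method minus baseline over K replicates.

    ``t = mean(d) / (sd(d) / sqrt(K))`` with the K-1 denominator in sd.
    Zero-variance differences give ±inf with the sign of the mean (0.0 when
    the mean is also zero).
    """
    x = np.asarray(method_scores, dtype=float)
    y = np.asarray(baseline_scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors with K >= 2")
    d = x - y
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0 if mean == 0 else math.copysign(math.inf, mean)
    return float(mean / (sd / math.sqrt(d.size)))


def _digraph_at_threshold(edge_probs: np.ndarray, threshold: float) -> nx.DiGraph:
    g = nx.DiGraph()
    v = edge_probs.shape[0]
    g.add_nodes_from(range(v))
    ii, jj = np.nonzero(edge_probs >= threshold)
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return g


def descendant_set(edge_probs, source: int, threshold: float) -> set[int]:
    """Vertices reachable from ``source`` through edges with probability
    >= ``threshold`` (the source itself excluded)."""
    probs = np.asarray(edge_probs, dtype=float)
    if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
        raise ValueError("edge probabilities must form a square matrix")
    if not 0 <= source < probs.shape[0]:
        raise KeyError(f"unknown source vertex {source}")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    return set(nx.descendants(_digraph_at_threshold(probs, threshold), source))


def descendant_auroc(edge_probs, source: int, gold_descendants) -> float:
    """Trapezoidal AUCROC of predicted vs. gold descendant sets.

    Thresholds sweep the unique edge probabilities plus sentinels (0 and just
    above the maximum); at each, the predicted descendant set yields one
    (FPR, TPR) point.
    """
    probs = np.asarray(edge_probs, dtype=float)
    v = probs.shape[0]
    gold = set(int(g) for g in gold_descendants)
    universe = set(range(v)) - {int(source)}
    if not gold or not gold <= universe or gold == universe:
        raise ValueError("gold descendant set must be a non-empty proper subset "
                         "of the non-source vertices")
    negatives = universe - gold
    thresholds = np.unique(probs)
    thresholds = np.concatenate([[0.0], thresholds, [thresholds.max() + 1.0]])
    pts = []
    for th in thresholds:
        # above the maximum probability nothing is predicted
        pred = descendant_set(probs, source, th) if th <= 1.0 else set()
        tpr = len(pred & gold) / len(gold)
        fpr = len(pred & negatives) / len(negatives)
        pts.append((fpr, tpr))
    pts = sorted(set(pts))
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    return float(np.trapezoid(tpr, fpr))


def dominance(ssps_scores, other_score: float) -> str:
    """Compare a stochastic method's repeat-run scores with a deterministic
    method's single score: 'dominates', 'dominated' or 'neither'."""
    x = np.asarray(ssps_scores, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("need at least one score")
    if x.min() > other_score:
        return "dominates"
    if other_score > x.max():
        return "dominated"
    return "neither"
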