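"""Ranking-based evaluation of candidate-pair scores.

Two evaluation modes are supported. Cross-validation mode scores every
unordered pair outside the training MST and treats the held-out test edges
as positives. Whole-network-recovery mode scores every pair and treats all
original edges (training included) as positives. Ties are handled by rank
averaging, so the ROC area equals the Mann-Whitney U statistic; the
precision-recall area uses step-wise interpolation, which is unbiased under
the heavy class skew of candidate pair sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn import metrics


@dataclass(frozen=True)
class EvalResult:
    auc_roc: float
    auc_pr: float
    roc_points: np.ndarray   # (k, 2) FPR, TPR; starts (0,0), ends (1,1)
    pr_points: np.ndarray    # (k, 2) recall, precision
    n_pos: int
    n_neg: int
    mode: str = "cross_validation"

    def to_dict(self) -> dict:
        return {"auc_roc": self.auc_roc, "auc_pr": self.auc_pr,
                "n_pos": self.n_pos, "n_neg": self.n_neg, "mode": self.mode}


def _labels_scores(scores: dict, positives: frozenset,
                   candidates) -> tuple[np.ndarray, np.ndarray]:
    cand = list(candidates)
    if not positives <= set(cand):
        raise ValueError("positives must be a subset of the candidates")
    y = np.fromiter((p in positives for p in cand), dtype=bool,
                    count=len(cand))
    s = np.fromiter((scores[p] for p in cand), dtype=float, count=len(cand))
    return y, s


def evaluate_ranking(y_true: np.ndarray, y_score: np.ndarray,
                     mode: str = "cross_validation") -> EvalResult:
    """ROC and PR curves and areas for a labelled score vector."""
    y_true = np.asarray(y_true, dtype=bool)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = int(y_true.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    auc = float(metrics.roc_auc_score(y_true, y_score))
    fpr, tpr, _ = metrics.roc_curve(y_true, y_score)
    prec, rec, _ = metrics.precision_recall_curve(y_true, y_score)
    aucpr = float(metrics.average_precision_score(y_true, y_score))
    return EvalResult(auc_roc=auc, auc_pr=aucpr,
                      roc_points=np.column_stack([fpr, tpr]),
                      pr_points=np.column_stack([rec, prec])[::-1],
                      n_pos=n_pos, n_neg=n_neg, mode=mode)


def auc_roc(scores: dict, positives: frozenset, candidates,
            mode: str = "cross_validation") -> EvalResult:
    """Rank candidates by score against the positive set.

    ``scores`` maps each candidate pair to its confidence; the AUC equals
    the probability that a random positive outranks a random negative, with
    ties rank-averaged.
    """
    y, s = _labels_scores(scores, positives, candidates)
    return evaluate_ranking(y, s, mode=mode)


def auc_pr(scores: dict, positives: frozenset, candidates,
           mode: str = "cross_validation") -> EvalResult:
    """Same sweep as :func:`auc_roc`; provided for symmetry of the API."""
    return auc_roc(scores, positives, candidates, mode=mode)


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on matched AUC vectors.

    Degenerate cases: identically zero differences give p = 1 (nothing to
    distinguish); zero-variance nonzero differences give p = 0 (certainty).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least two paired observations")
    d = a - b
    if np.allclose(d.var(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return np.inf * np.sign(d.mean()), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
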