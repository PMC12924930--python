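"""Probability ensembling, ROC metrics, and DeLong tests.

The ensemble prediction is ``(1 - w) * p_clinical + w * p_graph`` scanned
over 100 evenly spaced weights in [0, 1] (both endpoints included); AUC is
the Mann-Whitney pair probability, and correlated-AUC comparisons use
DeLong's fast placement-value formulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return y


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(s+ > s-) + 0.5 P(s+ = s-) over all pairs."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    from scipy.stats import rankdata

    ranks = rankdata(s)
    m = int(y.sum())
    n = len(y) - m
    return float((ranks[y == 1].sum() - m * (m + 1) / 2) / (m * n))


def roc_points(scores, labels) -> np.ndarray:
    """(fpr, tpr) pairs at every distinct threshold, ends included."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr])


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------

def placement_values(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """Structural components: for each positive, the fraction of negatives it
    outranks (ties half); for each negative, the fraction of positives it is
    outranked by (ties half)."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    v_pos = (np.sum(pos[:, None] > neg[None, :], axis=1)
             + 0.5 * np.sum(pos[:, None] == neg[None, :], axis=1)) / len(neg)
    v_neg = (np.sum(pos[:, None] > neg[None, :], axis=0)
             + 0.5 * np.sum(pos[:, None] == neg[None, :], axis=0)) / len(pos)
    return v_pos, v_neg


def _delong_cov(score_list, labels):
    """AUCs and the DeLong covariance matrix for k correlated models."""
    y = _check_labels(labels)
    v_pos, v_neg = [], []
    aucs = []
    for s in score_list:
        vp, vn = placement_values(s, y)
        v_pos.append(vp)
        v_neg.append(vn)
        aucs.append(vp.mean())
    v_pos = np.asarray(v_pos)
    v_neg = np.asarray(v_neg)
    m = v_pos.shape[1]
    n = v_neg.shape[1]
    s10 = np.cov(v_pos) if m > 1 else np.zeros((len(score_list),) * 2)
    s01 = np.cov(v_neg) if n > 1 else np.zeros((len(score_list),) * 2)
    cov = np.atleast_2d(s10) / m + np.atleast_2d(s01) / n
    return np.asarray(aucs), cov


def delong_test(scores_a, scores_b, labels):
    """Two-sided DeLong comparison of paired ROC curves.

    Returns ``(auc_a, auc_b, delta, variance, p_value)``.
    """
    aucs, cov = _delong_cov([np.asarray(scores_a, dtype=float),
                             np.asarray(scores_b, dtype=float)], labels)
    delta = aucs[0] - aucs[1]
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        if delta == 0:
            return aucs[0], aucs[1], 0.0, 0.0, 1.0
        warnings.warn("zero DeLong variance with nonzero AUC difference",
                      stacklevel=2)
        return aucs[0], aucs[1], float(delta), 0.0, 0.0
    z = delta / np.sqrt(var)
    p = float(2 * norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), float(delta), float(var), p


def auc_variance(scores, labels) -> float:
    """DeLong variance of a single AUC."""
    _, cov = _delong_cov([np.asarray(scores, dtype=float)], labels)
    return float(cov[0, 0])


def auc_confidence_interval(scores, labels, level: float = 0.95):
    """Normal-approximation interval on the DeLong variance, truncated to [0, 1]."""
    auc = roc_auc(scores, labels)
    var = auc_variance(scores, labels)
    if var <= 0:
        return auc, auc
    z = norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


# ---------------------------------------------------------------------------
# Metric panel
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    prevalence: float
    accuracy: float
    precision: float
    f1: float
    sensitivity_pct: float
    specificity_pct: float
    auc: float
    auc_ci: tuple
    threshold: float
    roc: np.ndarray = field(repr=False, default=None)
    confusion: tuple = (0, 0, 0, 0)  # tp, fp, tn, fn

    def as_dict(self) -> dict:
        return {
            "prevalence": self.prevalence, "accuracy": self.accuracy,
            "precision": self.precision, "f1": self.f1,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "auc": self.auc, "auc_ci": list(self.auc_ci),
            "threshold": self.threshold,
            "confusion": {k: int(v) for k, v in
                          zip(("tp", "fp", "tn", "fn"), self.confusion)},
        }


def metric_panel(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Confusion-matrix metrics at ``score >= threshold`` plus AUC and CI."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())

    def ratio(num, den, what):
        if den == 0:
            warnings.warn(f"{what} undefined (zero denominator)", stacklevel=3)
            return np.nan
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if np.isfinite(precision) and np.isfinite(sensitivity)
          and (precision + sensitivity) > 0 else np.nan)
    return EvalReport(
        prevalence=float(y.mean()),
        accuracy=(tp + tn) / len(y),
        precision=float(precision),
        f1=float(f1),
        sensitivity_pct=float(sensitivity * 100),
        specificity_pct=float(specificity * 100),
        auc=roc_auc(s, y),
        auc_ci=auc_confidence_interval(s, y),
        threshold=threshold,
        roc=roc_points(s, y),
        confusion=(tp, fp, tn, fn),
    )


# ---------------------------------------------------------------------------
# Ensemble weight scan
# ---------------------------------------------------------------------------

def ensemble_probabilities(clinical_probs, graph_probs, weight: float) -> np.ndarray:
    p_c = np.asarray(clinical_probs, dtype=float)
    p_g = np.asarray(graph_probs, dtype=float)
    if p_c.shape != p_g.shape:
        raise ValueError("probability vectors are misaligned")
    return (1.0 - weight) * p_c + weight * p_g


def ensemble_scan(clinical_probs, graph_probs, labels, grid_size: int = 100):
    """AUC over ``grid_size`` evenly spaced weights in [0, 1] (endpoints
    included). Returns (best_weight, weights, aucs); ties go to the smaller
    weight. Weight 0 is the clinical model, weight 1 the graph model."""
    y = _check_labels(labels)
    weights = np.linspace(0.0, 1.0, grid_size)
    aucs = np.array([
        roc_auc(ensemble_probabilities(clinical_probs, graph_probs, w), y)
        for w in weights
    ])
    best = float(weights[int(np.argmax(aucs))])
    return best, weights, aucs
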