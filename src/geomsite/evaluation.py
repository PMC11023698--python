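"""Binding-site evaluation metrics and protein-level scores.

Residue-level predictions are scored with the usual binary-classification
suite: threshold-free AUC (Mann-Whitney: ties count one half) and AUPR
(average precision with grouped-tie steps), plus recall, precision,
accuracy, F1 and MCC at a calibrated threshold. Whole-protein binding
propensity is the mean of the top-k residue probabilities, k = 5 for
metal ions and 10 for larger ligands; surface residues are those with
relative solvent accessibility above 5%.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .structure_io import METAL_LIGANDS
from .residue_features import StructuralProperties


class UndefinedMetricError(ValueError):
    """Metric has no value (e.g. a single-class label vector)."""


@dataclass
class MetricReport:
    recall: float
    precision: float
    accuracy: float
    f1: float
    mcc: float
    auc: float
    aupr: float
    tp: int
    fp: int
    tn: int
    fn: int
    n_pos: int
    n_neg: int
    degenerate_precision: bool = False  # no predicted positives; precision/F1 set to 0

    def to_dict(self) -> dict:
        return asdict(self)


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    return labels


def roc_auc(scores, labels) -> float:
    """Probability that a random positive outranks a random negative
    (ties count one half)."""
    labels = _check_binary(labels)
    if labels.min() == labels.max():
        raise UndefinedMetricError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def pr_auc(scores, labels) -> float:
    """Average precision (step-wise PR area; equal scores grouped)."""
    labels = _check_binary(labels)
    if labels.sum() == 0:
        raise UndefinedMetricError("AUPR undefined without positives")
    return float(average_precision_score(labels, np.asarray(scores, float)))


def confusion_metrics(scores, labels, threshold: float) -> MetricReport:
    """Thresholded metrics (binarize by score >= threshold) plus AUC/AUPR.

    Degenerate conventions: precision and F1 are 0 (flagged) when nothing
    is predicted positive; MCC is 0 when any marginal count is zero; AUC
    and AUPR are NaN when undefined.
    """
    scores = np.asarray(scores, float)
    labels = _check_binary(labels)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    n_pos, n_neg = tp + fn, fp + tn
    recall = tp / n_pos if n_pos else 0.0
    degenerate = (tp + fp) == 0
    precision = tp / (tp + fp) if not degenerate else 0.0
    accuracy = (tp + tn) / max(len(labels), 1)
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    mcc = matthews_corrcoef(tp, fp, tn, fn)
    try:
        auc = roc_auc(scores, labels)
    except UndefinedMetricError:
        auc = float("nan")
    try:
        aupr = pr_auc(scores, labels)
    except UndefinedMetricError:
        aupr = float("nan")
    return MetricReport(recall=recall, precision=precision, accuracy=accuracy,
                        f1=f1, mcc=mcc, auc=auc, aupr=aupr,
                        tp=tp, fp=fp, tn=tn, fn=fn, n_pos=n_pos, n_neg=n_neg,
                        degenerate_precision=degenerate)


def matthews_corrcoef(tp: int, fp: int, tn: int, fn: int) -> float:
    """Four-count MCC; 0 when any denominator factor vanishes."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def protein_level_score(residue_scores, ligand_type: str) -> float:
    """Mean of the k largest residue scores; k = 5 for metal ions
    (ZN/CA/MG/MN), 10 otherwise. Proteins shorter than k use all residues."""
    scores = np.asarray(residue_scores, float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    k = 5 if ligand_type.upper() in METAL_LIGANDS else 10
    k = min(k, scores.size)
    top = np.sort(scores)[-k:]
    return float(top.mean())


def surface_mask(properties: StructuralProperties) -> np.ndarray:
    """Boolean mask of surface residues: RSA strictly greater than 5%."""
    return np.asarray(properties.rsa) > 0.05
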