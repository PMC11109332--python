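"""Classification metrics, including the as-printed weighted aggregates.

The report follows the evaluation protocol of the original study: one-vs-rest
confusion counts per class, then

    Precision = (1/N) * sum_i n_i*TP_i / (n_i*TP_i + FP_i)
    Recall    = (1/N) * sum_i n_i*TP_i / (n_i*TP_i + FN_i)
    F1        = 2 * Precision * Recall / (Precision + Recall)
    Accuracy  = (1/N) * sum_i (TP_i + TN_i) / (TP_i + FP_i + TN_i + FN_i)

with N the number of classes and n_i the true element count of class i. The
n_i weighting inside the Precision/Recall fractions differs from the
conventional weighted mean, so the conventional support-weighted variants are
computed alongside for interoperability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .annotations import AnnotationSet

__all__ = [
    "MetricsReport",
    "confusion_counts",
    "metrics_as_printed",
    "count_concordance",
]


@dataclass
class MetricsReport:
    """Per-class one-vs-rest counts plus aggregate scores in [0, 1]."""

    per_class: pd.DataFrame  # index: class; columns n, tp, fp, fn, tn
    precision: float
    recall: float
    f1: float
    accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    n_classes: int = field(default=0)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "n_classes": self.n_classes,
            "per_class": self.per_class.to_dict(orient="index"),
        }


def _truth_mapping(truth: Union[AnnotationSet, Mapping[int, int]]) -> dict[int, int]:
    if isinstance(truth, AnnotationSet):
        return {oid: cls for (_, oid), (cls, _) in truth.records.items()}
    return {int(k): int(v) for k, v in truth.items()}


def confusion_counts(
    truth: Union[AnnotationSet, Mapping[int, int]], pred: pd.DataFrame
) -> pd.DataFrame:
    """One-vs-rest TP/FP/FN/TN per class from truth and a prediction table.

    Truth and predictions must cover exactly the same objects.
    """
    truth_map = _truth_mapping(truth)
    pred_map = {int(r.object_id): int(r["class"]) for _, r in pred.iterrows()}
    missing = sorted(set(truth_map) - set(pred_map))
    if missing:
        raise ValueError(f"objects in truth missing from predictions: {missing[:20]}")
    extra = sorted(set(pred_map) - set(truth_map))
    if extra:
        raise ValueError(f"predictions for objects absent from truth: {extra[:20]}")
    oids = sorted(truth_map)
    t = np.array([truth_map[o] for o in oids])
    p = np.array([pred_map[o] for o in oids])
    classes = sorted(set(t.tolist()) | set(p.tolist()))
    total = len(oids)
    rows = {}
    for cls in classes:
        tp = int(np.sum((t == cls) & (p == cls)))
        fp = int(np.sum((t != cls) & (p == cls)))
        fn = int(np.sum((t == cls) & (p != cls)))
        rows[cls] = dict(n=int(np.sum(t == cls)), tp=tp, fp=fp, fn=fn,
                         tn=total - tp - fp - fn)
    return pd.DataFrame.from_dict(rows, orient="index")


def _safe_term(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; term counted as 0", stacklevel=3)
        return 0.0
    return num / den


def metrics_as_printed(counts: pd.DataFrame) -> MetricsReport:
    """Aggregate the per-class counts with the study's displayed formulas,
    plus conventional support-weighted variants."""
    N = len(counts)
    prec_terms, rec_terms, acc_terms = [], [], []
    std_prec, std_rec, std_f1 = [], [], []
    for cls, row in counts.iterrows():
        n_i, tp, fp, fn, tn = (float(row[c]) for c in ("n", "tp", "fp", "fn", "tn"))
        prec_terms.append(_safe_term(n_i * tp, n_i * tp + fp, f"Precision term of class {cls}"))
        rec_terms.append(_safe_term(n_i * tp, n_i * tp + fn, f"Recall term of class {cls}"))
        acc_terms.append(_safe_term(tp + tn, tp + fp + tn + fn, f"Accuracy term of class {cls}"))
        p_i = _safe_term(tp, tp + fp, f"standard precision of class {cls}")
        r_i = _safe_term(tp, tp + fn, f"standard recall of class {cls}")
        std_prec.append(p_i)
        std_rec.append(r_i)
        std_f1.append(_safe_term(2 * p_i * r_i, p_i + r_i, f"standard F1 of class {cls}"))
    precision = sum(prec_terms) / N
    recall = sum(rec_terms) / N
    f1 = _safe_term(2 * precision * recall, precision + recall, "F1-Score")
    accuracy = sum(acc_terms) / N
    support = counts["n"].to_numpy(dtype=float)
    w = support / support.sum() if support.sum() > 0 else np.zeros(N)
    return MetricsReport(
        per_class=counts.copy(),
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        weighted_precision=float(np.dot(w, std_prec)),
        weighted_recall=float(np.dot(w, std_rec)),
        weighted_f1=float(np.dot(w, std_f1)),
        n_classes=N,
    )


def count_concordance(pred_counts, manual_counts) -> float:
    """Coefficient of determination R^2 between automated and manual
    per-image counts (predictions treated as estimates of the manual
    reference)."""
    p = np.asarray(pred_counts, dtype=float).ravel()
    m = np.asarray(manual_counts, dtype=float).ravel()
    if p.shape != m.shape:
        raise ValueError(f"count vectors differ in length: {p.shape} vs {m.shape}")
    if p.size < 2:
        raise ValueError("R^2 needs at least 2 images")
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("manual counts are constant; R^2 is undefined")
    ss_res = float(np.sum((m - p) ** 2))
    return 1.0 - ss_res / ss_tot
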