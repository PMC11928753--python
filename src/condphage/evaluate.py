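"""Evaluation metrics for binary phage identification.

Phage is the positive class throughout. Threshold-free metrics (AUROC,
AUPRC) are computed from the continuous phage scores; threshold-dependent
metrics (accuracy, F1, MCC) from the discrete calls. AUPRC uses the
interpolation-free average-precision convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    confusion_matrix,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)

from .finetune import CLASS_ORDER, ParadoxSample
from .predict import ClassScores, aggregate_scores

POSITIVE_CLASS = "phage"
NEGATIVE_CLASS = "bacteria"


@dataclass(frozen=True)
class MetricReport:
    """Binary classification metrics with phage as the positive class.

    ``auroc``/``auprc`` are NaN when the truth contains a single class.
    """

    auroc: float
    auprc: float
    accuracy: float
    f1: float
    mcc: float
    counts: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["auroc", "auprc", "accuracy", "f1", "mcc"],
                "value": [self.auroc, self.auprc, self.accuracy, self.f1, self.mcc],
            }
        )


def compute_metrics(
    phage_scores: Sequence[float],
    calls: Sequence[str],
    truth: Sequence[str],
) -> MetricReport:
    """Score per-contig predictions against per-contig truth (aligned order)."""
    scores = np.asarray(phage_scores, dtype=float)
    calls = np.asarray(calls)
    truth = np.asarray(truth)
    if not (len(scores) == len(calls) == len(truth)):
        raise ValueError("phage_scores, calls and truth must be aligned")
    y_true = (truth == POSITIVE_CLASS).astype(int)
    y_call = (calls == POSITIVE_CLASS).astype(int)
    counts = {
        NEGATIVE_CLASS: int((y_true == 0).sum()),
        POSITIVE_CLASS: int((y_true == 1).sum()),
    }
    if len(set(y_true.tolist())) < 2:
        auroc = float("nan")
        auprc = float("nan")
    else:
        auroc = float(roc_auc_score(y_true, scores))
        auprc = float(average_precision_score(y_true, scores))
    return MetricReport(
        auroc=auroc,
        auprc=auprc,
        accuracy=float(accuracy_score(y_true, y_call)),
        f1=float(f1_score(y_true, y_call, zero_division=0.0)),
        mcc=float(matthews_corrcoef(y_true, y_call)),
        counts=counts,
    )


@dataclass(frozen=True)
class ThreeLabelConfusion:
    """3×3 count matrix, rows = predicted class, columns = true class,
    both over (bacteria, phage, paradox)."""

    matrix: np.ndarray

    def __post_init__(self):
        if self.matrix.shape != (3, 3):
            raise ValueError("matrix must be 3x3")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=[f"pred_{c}" for c in CLASS_ORDER],
            columns=[f"true_{c}" for c in CLASS_ORDER],
        )


def three_label_confusion(
    samples: Sequence[ParadoxSample],
    predictions: Sequence[str],
) -> ThreeLabelConfusion:
    """Confusion matrix of argmax 3-class predictions on paradox samples."""
    if len(samples) != len(predictions):
        raise ValueError("samples and predictions must be aligned")
    for cls in predictions:
        if cls not in CLASS_ORDER:
            raise ValueError(f"unknown predicted class {cls!r}")
    y_true = [s.target_class for s in samples]
    mat = confusion_matrix(y_true, list(predictions), labels=list(CLASS_ORDER))
    # sklearn rows are truth; our convention is rows = predicted
    return ThreeLabelConfusion(matrix=mat.T)


def aggregated_confusion(
    score_pairs: Sequence[tuple[ClassScores, ClassScores]],
    truth: Sequence[str],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Collapse per-segment dual-tokenization triples to the 2×2 matrix.

    Each pair holds the [BAC]- and [PHA]-attached triples of one segment;
    its binary phage score is the equal-weight mean of the two aggregated
    phage scores, thresholded like a contig call.
    """
    if len(score_pairs) != len(truth):
        raise ValueError("score_pairs and truth must be aligned")
    calls = []
    for pair in score_pairs:
        phage = float(np.mean([aggregate_scores(s).b_pha for s in pair]))
        calls.append(POSITIVE_CLASS if phage > threshold else NEGATIVE_CLASS)
    labels = [NEGATIVE_CLASS, POSITIVE_CLASS]
    mat = confusion_matrix(list(truth), calls, labels=labels).T
    return pd.DataFrame(
        mat,
        index=[f"pred_{c}" for c in labels],
        columns=[f"true_{c}" for c in labels],
    )
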