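"""Evaluation metrics.

Regression: RMSE, MAE, R².  Classification: AUROC (rank statistic), AUPRC as
average precision (step-wise, no linear interpolation — under this estimator
a constant-score classifier scores exactly the positive prevalence, the
no-skill baseline), and point precision/recall at threshold 0.5.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import (average_precision_score, precision_score,
                             recall_score, roc_auc_score)

from .losses import DegenerateTargetError


def regression_metrics(y, y_hat) -> dict[str, float]:
    """RMSE, MAE and R² = 1 − SS_res/SS_tot.

    R² is NaN (flagged, not raised) when the targets are constant.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    resid = y - y_hat
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return {
        "rmse": float(np.sqrt(np.mean(resid ** 2))),
        "mae": float(np.mean(np.abs(resid))),
        "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
    }


def classification_metrics(y, scores, threshold: float = 0.5) -> dict[str, float]:
    """AUROC, AUPRC (average precision) and precision/recall at ``threshold``."""
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(y)) < 2:
        raise DegenerateTargetError("both classes must be present to score a classifier")
    pred = (scores >= threshold).astype(int)
    return {
        "auroc": float(roc_auc_score(y, scores)),
        "auprc": float(average_precision_score(y, scores)),
        "precision": float(precision_score(y, pred, zero_division=0)),
        "recall": float(recall_score(y, pred, zero_division=0)),
    }


def auprc_baseline(y) -> float:
    """The no-skill AUPRC: the positive-class prevalence."""
    y = np.asarray(y).astype(int)
    return float(y.mean())
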