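"""Prediction-accuracy metrics: Pearson correlation and AUC.

AUC is computed as the Mann-Whitney concordance probability
P(score_case > score_control) + 1/2 P(tie), via midranks; it is therefore
invariant under any strictly increasing transform of the scores.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


class UndefinedMetricError(ValueError):
    """Metric is undefined on this input (constant vector, one class)."""


def pearson(pred, obs) -> float:
    """Product-moment correlation between predictions and observations."""
    pred = np.asarray(pred, dtype=np.float64)
    obs = np.asarray(obs, dtype=np.float64)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be 1-d vectors of equal length")
    if pred.size < 3:
        raise UndefinedMetricError("need at least 3 pairs for a correlation")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise UndefinedMetricError("correlation undefined for a constant vector")
    return float(stats.pearsonr(pred, obs).statistic)


def auc(pred, labels) -> float:
    """Area under the ROC curve with midrank tie handling.

    ``labels`` are 0/1 with label 1 the case class; higher ``pred`` must mean
    more case-like (negate scores beforehand if the trait runs the other way).
    """
    pred = np.asarray(pred, dtype=np.float64)
    labels = np.asarray(labels)
    if pred.shape != labels.shape or pred.ndim != 1:
        raise ValueError("pred and labels must be 1-d vectors of equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUC undefined with a single class present")
    ranks = stats.rankdata(pred)  # midranks
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))
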