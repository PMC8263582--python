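"""ROC curves, AUC with Mann-Whitney tie handling, and box-plot summaries.

The AUC is computed from the rank (Mann-Whitney) formulation with ties
counted as 1/2:

    AUC = [ sum of positive ranks - n_pos (n_pos + 1) / 2 ] / (n_pos n_neg)

which equals the probability that a random positive outscores a random
negative, ties counted half, and equals the trapezoidal area under the ROC
curve swept over score thresholds (a property the test suite checks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohorts import SigauditError


@dataclass
class RocResult:
    """Scores, labels, the swept ROC curve and its AUC."""

    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    @property
    def curve(self) -> list[tuple[float, float]]:
        """Ordered (false-positive rate, true-positive rate) points."""
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))

    def trapezoid_area(self) -> float:
        """Trapezoidal area under the stored curve (cross-check for auc)."""
        return float(np.trapezoid(self.tpr, self.fpr))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with the 1/2 tie convention."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # average ranks on ties
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


def compute_roc(scores, labels) -> RocResult:
    """ROC curve and AUC for continuous scores against 0/1 labels.

    Raises
    ------
    SigauditError
        If only one class is present (AUC undefined) or any score is
        non-finite.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise SigauditError("scores and labels must be 1-d vectors of equal length")
    if not np.isfinite(scores).all():
        raise SigauditError("non-finite scores")
    if not np.isin(labels, (0, 1)).all():
        raise SigauditError("labels must be 0/1")
    if len(np.unique(labels)) < 2:
        raise SigauditError("AUC undefined: only one class present in labels")

    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(
        scores=scores,
        labels=labels,
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=rank_auc(scores, labels),
    )


@dataclass(frozen=True)
class BoxSummary:
    """Five-number summary plus mean and 1.5-IQR whiskers.

    Quartiles use linear interpolation between order statistics (the
    numpy default).  Whiskers extend to the most extreme observed values
    within 1.5 interquartile ranges of the quartiles, so they are always
    actual data values, matching the usual box-plot convention.
    """

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    mean: float
    whisker_low: float
    whisker_high: float

    def to_dict(self) -> dict[str, float]:
        return {
            "min": self.minimum,
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
            "max": self.maximum,
            "mean": self.mean,
            "whisker_low": self.whisker_low,
            "whisker_high": self.whisker_high,
        }


def auc_summary(auc_values) -> BoxSummary:
    """Box-plot summary of a vector of AUC values."""
    values = np.asarray(auc_values, dtype=float)
    if values.size == 0:
        raise SigauditError("auc_summary: empty input")
    if not np.isfinite(values).all():
        raise SigauditError("auc_summary: non-finite values")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    in_lo = values[values >= lo_fence]
    in_hi = values[values <= hi_fence]
    return BoxSummary(
        minimum=float(values.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(values.max()),
        mean=float(values.mean()),
        whisker_low=float(in_lo.min()) if in_lo.size else float(values.min()),
        whisker_high=float(in_hi.max()) if in_hi.size else float(values.max()),
    )
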