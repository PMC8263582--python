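"""Nearest-centroid gene-signature classifier with a continuous ROC score.

The classifier standardizes each signature gene with the *training*
cohort's mean and standard deviation (over all training samples, not per
class), averages the standardized profiles within each class to form a
responder and a non-responder centroid, and scores a sample by its
normalized distance difference

    s = (d_neg - d_pos) / (d_neg + d_pos + eps)

so that s in [-1, 1] and s > 0 means the sample lies nearer the responder
centroid.  Any monotone function of relative proximity yields the same
ROC ordering; this one is bounded and symmetric.  Test cohorts are always
standardized with the frozen training parameters — never with their own
statistics — so no test information leaks into scoring.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .cohorts import ExpressionCohort, GeneSignature, SigauditError

logger = logging.getLogger(__name__)

#: guards the 0/0 case when a sample coincides with both centroids
EPSILON = 1e-12

METRICS = ("euclidean", "correlation")


def _distances(x: np.ndarray, centroid: np.ndarray, metric: str) -> np.ndarray:
    """Distance of each column of x (genes x samples) to a centroid."""
    if metric == "euclidean":
        return np.sqrt(((x - centroid[:, None]) ** 2).sum(axis=0))
    if metric == "correlation":
        xc = x - x.mean(axis=0, keepdims=True)
        cc = centroid - centroid.mean()
        denom = np.sqrt((xc**2).sum(axis=0)) * np.sqrt((cc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc * cc[:, None]).sum(axis=0) / denom
        r = np.where(np.isfinite(r), r, 0.0)  # flat profiles: undefined corr -> 0
        return 1.0 - r
    raise SigauditError(f"unknown distance metric {metric!r}; use one of {METRICS}")


@dataclass
class CentroidClassifierResults:
    """A fitted nearest-centroid model, frozen at training time.

    Holds the gene subset actually used (signature ∩ training cohort, in
    signature order), the training standardization parameters, and one
    centroid per class in standardized space.
    """

    genes_used: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    centroid_pos: np.ndarray
    centroid_neg: np.ndarray
    distance_metric: str
    training_cohort_name: str
    genes_dropped_zero_sd: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.genes_used) == 0:
            raise SigauditError("fitted model retains no genes")
        k = len(self.genes_used)
        for name in ("means", "sds", "centroid_pos", "centroid_neg"):
            if getattr(self, name).shape != (k,):
                raise SigauditError(f"{name} length does not match genes_used")
        if not (self.sds > 0).all():
            raise SigauditError("standardization sd must be > 0 for retained genes")

    def score(self, cohort: ExpressionCohort) -> np.ndarray:
        """Continuous responder score per sample of *cohort*.

        Samples are standardized with the training parameters.  Model
        genes absent from the test cohort are dropped from both centroids
        and the sample vectors (with a logged warning); if none remain an
        error is raised.  Labels of *cohort* are never read.
        """
        lookup = {g: i for i, g in enumerate(cohort.genes)}
        present = np.array([g in lookup for g in self.genes_used])
        n_missing = int((~present).sum())
        if n_missing == len(self.genes_used):
            raise SigauditError(
                f"cohort {cohort.name!r} shares no genes with the model trained "
                f"on {self.training_cohort_name!r}"
            )
        if n_missing:
            msg = (
                f"{n_missing} of {len(self.genes_used)} model genes absent from "
                f"cohort {cohort.name!r}; dropped from centroids for scoring"
            )
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
        rows = [lookup[g] for g, p in zip(self.genes_used, present) if p]
        x = cohort.values[rows, :]
        z = (x - self.means[present, None]) / self.sds[present, None]
        d_pos = _distances(z, self.centroid_pos[present], self.distance_metric)
        d_neg = _distances(z, self.centroid_neg[present], self.distance_metric)
        return (d_neg - d_pos) / (d_neg + d_pos + EPSILON)

    def predict(self, cohort: ExpressionCohort) -> np.ndarray:
        """Hard class call: 1 where score > 0, else 0 (ties to non-responder)."""
        return (self.score(cohort) > 0).astype(int)

    def summary(self) -> str:
        lines = [
            "Nearest-centroid classifier",
            "===========================",
            f"training cohort : {self.training_cohort_name}",
            f"distance metric : {self.distance_metric}",
            f"genes used      : {len(self.genes_used)}",
            f"zero-sd dropped : {len(self.genes_dropped_zero_sd)}",
            f"|centroid_pos|  : {np.linalg.norm(self.centroid_pos):.4f}",
            f"|centroid_neg|  : {np.linalg.norm(self.centroid_neg):.4f}",
        ]
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "format": "sigaudit-centroid-model",
            "schema_version": 1,
            "training_cohort_name": self.training_cohort_name,
            "distance_metric": self.distance_metric,
            "genes_used": list(self.genes_used),
            "genes_dropped_zero_sd": list(self.genes_dropped_zero_sd),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "centroid_pos": self.centroid_pos.tolist(),
            "centroid_neg": self.centroid_neg.tolist(),
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CentroidClassifierResults":
        doc = json.loads(text)
        if doc.get("format") != "sigaudit-centroid-model":
            raise SigauditError("not a sigaudit centroid-model document")
        return cls(
            genes_used=tuple(doc["genes_used"]),
            means=np.asarray(doc["means"], dtype=float),
            sds=np.asarray(doc["sds"], dtype=float),
            centroid_pos=np.asarray(doc["centroid_pos"], dtype=float),
            centroid_neg=np.asarray(doc["centroid_neg"], dtype=float),
            distance_metric=doc["distance_metric"],
            training_cohort_name=doc["training_cohort_name"],
            genes_dropped_zero_sd=tuple(doc.get("genes_dropped_zero_sd", ())),
        )


class CentroidClassifier:
    """Model object: a signature applied to one training cohort.

    ``fit()`` returns a frozen :class:`CentroidClassifierResults`.
    """

    def __init__(
        self,
        cohort: ExpressionCohort,
        signature: GeneSignature,
        distance_metric: str = "euclidean",
    ) -> None:
        if distance_metric not in METRICS:
            raise SigauditError(
                f"unknown distance metric {distance_metric!r}; use one of {METRICS}"
            )
        self.cohort = cohort
        self.signature = signature
        self.distance_metric = distance_metric

    def fit(self) -> CentroidClassifierResults:
        cohort, signature = self.cohort, self.signature
        genes_used = signature.intersect(cohort.genes)
        if not genes_used:
            raise SigauditError(
                f"signature {signature.name!r} shares no genes with cohort "
                f"{cohort.name!r}"
            )
        if cohort.n_responders == 0 or cohort.n_responders == cohort.n_samples:
            raise SigauditError(
                f"cohort {cohort.name!r}: a class has zero samples; cannot fit"
            )
        rows = cohort.gene_index(genes_used)
        x = cohort.values[rows, :]
        means = x.mean(axis=1)
        sds = x.std(axis=1, ddof=1)

        nonzero = sds > 0
        dropped = tuple(g for g, ok in zip(genes_used, nonzero) if not ok)
        if dropped:
            logger.warning(
                "cohort %s: dropping %d zero-variance signature genes at fit time",
                cohort.name,
                len(dropped),
            )
            genes_used = tuple(g for g, ok in zip(genes_used, nonzero) if ok)
            if not genes_used:
                raise SigauditError(
                    f"cohort {cohort.name!r}: every signature gene has zero "
                    "training variance"
                )
            x, means, sds = x[nonzero], means[nonzero], sds[nonzero]

        z = (x - means[:, None]) / sds[:, None]
        pos = cohort.labels == 1
        return CentroidClassifierResults(
            genes_used=tuple(genes_used),
            means=means,
            sds=sds,
            centroid_pos=z[:, pos].mean(axis=1),
            centroid_neg=z[:, ~pos].mean(axis=1),
            distance_metric=self.distance_metric,
            training_cohort_name=cohort.name,
            genes_dropped_zero_sd=dropped,
        )


def fit(
    cohort: ExpressionCohort,
    signature: GeneSignature,
    distance_metric: str = "euclidean",
) -> CentroidClassifierResults:
    """Convenience wrapper: ``CentroidClassifier(...).fit()``."""
    return CentroidClassifier(cohort, signature, distance_metric).fit()


def score(model: CentroidClassifierResults, cohort: ExpressionCohort) -> np.ndarray:
    """Convenience wrapper: ``model.score(cohort)``."""
    return model.score(cohort)
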