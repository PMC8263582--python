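"""Signature-validation audits.

Two procedures expose how a nearest-centroid signature classifier can look
far better than it is:

* :class:`RandomSignatureNull` — the random-signature resubstitution null.
  Draw size-matched random gene sets, fit on a cohort and score the *same*
  cohort, and record the AUC distribution.  With many more genes than
  samples, these training (resubstitution) AUCs are systematically
  inflated, so a high same-cohort AUC for a real signature carries little
  evidence by itself.

* :class:`CrossCohortAudit` — the leave-one-cohort-out generalization
  audit.  Fit once on a training cohort, freeze the model (standardization
  parameters included), and score every other cohort.  The training
  resubstitution ROC is reported alongside so the inflation is visible
  side by side.

``full_audit`` runs both for every cohort and returns a single report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centroid import CentroidClassifier, CentroidClassifierResults
from .cohorts import ExpressionCohort, GeneSignature, SigauditError
from .roc import BoxSummary, RocResult, auc_summary, compute_roc

DEFAULT_N_DRAWS = 50  # draws of random gene sets per cohort


def size_matched_signature_size(
    signature: GeneSignature, cohort: ExpressionCohort
) -> int:
    """Number of signature genes present in the cohort.

    This is the per-cohort matched size for the random-signature null: a
    fixed signature matches a slightly different gene count in every
    cohort when the gene universes only partially overlap.  Zero is a
    valid return; callers must reject it before auditing.
    """
    return len(signature.intersect(cohort.genes))


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass
class RandomSignatureAudit:
    """Results of the random-signature resubstitution null on one cohort."""

    cohort_name: str
    signature_size: int
    n_draws: int
    seed: int | None
    auc_values: np.ndarray
    box: BoxSummary

    def __post_init__(self) -> None:
        if self.auc_values.shape != (self.n_draws,):
            raise SigauditError("one AUC per draw required")
        if ((self.auc_values < 0) | (self.auc_values > 1)).any():
            raise SigauditError("AUC values outside [0, 1]")

    @property
    def summary_record(self) -> BoxSummary:
        return self.box

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per random draw."""
        return pd.DataFrame(
            {
                "cohort": self.cohort_name,
                "draw": np.arange(1, self.n_draws + 1),
                "signature_size": self.signature_size,
                "auc": self.auc_values,
            }
        )

    def summary(self) -> str:
        b = self.box
        return "\n".join(
            [
                f"Random-signature resubstitution null — cohort {self.cohort_name}",
                f"  draws={self.n_draws}  signature_size={self.signature_size}",
                f"  AUC median={b.median:.3f}  IQR=[{b.q1:.3f}, {b.q3:.3f}]  "
                f"range=[{b.minimum:.3f}, {b.maximum:.3f}]  mean={b.mean:.3f}",
            ]
        )


class RandomSignatureNull:
    """Model object for the random-signature training-AUC null on one cohort.

    Each of ``n_draws`` draws samples ``signature_size`` genes uniformly
    without replacement from the cohort's gene list, fits the centroid
    classifier on the full cohort, scores the same cohort
    (resubstitution — deliberately, that is the flaw being audited) and
    records the AUC.  Per-draw random substreams are spawned from the
    master seed, so each draw is reproducible in isolation.
    """

    def __init__(
        self,
        cohort: ExpressionCohort,
        signature_size: int,
        n_draws: int = DEFAULT_N_DRAWS,
        seed: int | np.random.SeedSequence = 0,
        distance_metric: str = "euclidean",
    ) -> None:
        if signature_size < 1:
            raise SigauditError("signature_size must be >= 1")
        if signature_size > cohort.n_genes:
            raise SigauditError(
                f"signature_size {signature_size} exceeds the {cohort.n_genes} "
                f"genes of cohort {cohort.name!r}"
            )
        if n_draws < 1:
            raise SigauditError("n_draws must be >= 1")
        self.cohort = cohort
        self.signature_size = signature_size
        self.n_draws = n_draws
        self.seed = seed
        self.distance_metric = distance_metric

    def fit(self) -> RandomSignatureAudit:
        cohort = self.cohort
        children = _as_seedseq(self.seed).spawn(self.n_draws)
        genes = np.asarray(cohort.genes, dtype=object)
        aucs = np.empty(self.n_draws)
        for i, child in enumerate(children):
            rng = np.random.default_rng(child)
            picked = genes[rng.choice(cohort.n_genes, self.signature_size, replace=False)]
            sig = GeneSignature(f"random_{i + 1}", picked.tolist())
            model = CentroidClassifier(cohort, sig, self.distance_metric).fit()
            aucs[i] = compute_roc(model.score(cohort), cohort.labels).auc
        return RandomSignatureAudit(
            cohort_name=cohort.name,
            signature_size=self.signature_size,
            n_draws=self.n_draws,
            seed=self.seed if isinstance(self.seed, int) else None,
            auc_values=aucs,
            box=auc_summary(aucs),
        )


def random_signature_null(
    cohort: ExpressionCohort,
    signature_size: int,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int | np.random.SeedSequence = 0,
    distance_metric: str = "euclidean",
) -> RandomSignatureAudit:
    """Convenience wrapper: ``RandomSignatureNull(...).fit()``."""
    return RandomSignatureNull(
        cohort, signature_size, n_draws, seed, distance_metric
    ).fit()


@dataclass
class CrossCohortResults:
    """Frozen-model transfer results for one training cohort."""

    train_cohort: str
    signature_name: str
    model: CentroidClassifierResults
    training_resubstitution: RocResult
    test_results: dict[str, RocResult] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.train_cohort in self.test_results:
            raise SigauditError("test cohorts must exclude the training cohort")

    @property
    def test_aucs(self) -> dict[str, float]:
        return {name: r.auc for name, r in self.test_results.items()}

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per train/test pair (resubstitution included)."""
        rows = [
            {
                "train": self.train_cohort,
                "test": self.train_cohort,
                "kind": "resubstitution",
                "n_genes_used": len(self.model.genes_used),
                "auc": self.training_resubstitution.auc,
            }
        ]
        for name in sorted(self.test_results):
            rows.append(
                {
                    "train": self.train_cohort,
                    "test": name,
                    "kind": "transfer",
                    "n_genes_used": len(self.model.genes_used),
                    "auc": self.test_results[name].auc,
                }
            )
        for name in sorted(self.failures):
            rows.append(
                {
                    "train": self.train_cohort,
                    "test": name,
                    "kind": "failed",
                    "n_genes_used": len(self.model.genes_used),
                    "auc": np.nan,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Cross-cohort audit — trained on {self.train_cohort} "
            f"(signature {self.signature_name!r}, "
            f"{len(self.model.genes_used)} genes)",
            f"  resubstitution AUC = {self.training_resubstitution.auc:.3f}",
        ]
        for name, auc in sorted(self.test_aucs.items()):
            lines.append(f"  test on {name}: AUC = {auc:.3f}")
        for name, reason in sorted(self.failures.items()):
            lines.append(f"  test on {name}: FAILED ({reason})")
        return "\n".join(lines)


class CrossCohortAudit:
    """Model object for the leave-one-cohort-out generalization audit.

    The classifier is fitted once on the training cohort and completely
    frozen: held-out cohorts are standardized with the training
    parameters, and genes absent from a test cohort are dropped from the
    frozen centroids at scoring time.  Test labels are used only to
    compute the ROC, never to score.
    """

    def __init__(
        self,
        cohorts: list[ExpressionCohort],
        signature: GeneSignature,
        train_name: str,
        distance_metric: str = "euclidean",
    ) -> None:
        if len(cohorts) < 2:
            raise SigauditError("cross-cohort audit needs at least two cohorts")
        names = [c.name for c in cohorts]
        if len(set(names)) != len(names):
            raise SigauditError("cohort names must be unique")
        if train_name not in names:
            raise SigauditError(f"training cohort {train_name!r} not among {names}")
        self.cohorts = cohorts
        self.signature = signature
        self.train_name = train_name
        self.distance_metric = distance_metric

    def fit(self) -> CrossCohortResults:
        train = next(c for c in self.cohorts if c.name == self.train_name)
        model = CentroidClassifier(train, self.signature, self.distance_metric).fit()
        resub = compute_roc(model.score(train), train.labels)
        results: dict[str, RocResult] = {}
        failures: dict[str, str] = {}
        for cohort in self.cohorts:
            if cohort.name == self.train_name:
                continue
            try:
                results[cohort.name] = compute_roc(
                    model.score(cohort), cohort.labels
                )
            except SigauditError as exc:
                failures[cohort.name] = str(exc)
        return CrossCohortResults(
            train_cohort=self.train_name,
            signature_name=self.signature.name,
            model=model,
            training_resubstitution=resub,
            test_results=results,
            failures=failures,
        )


def cross_cohort_audit(
    cohorts: list[ExpressionCohort],
    signature: GeneSignature,
    train_name: str,
    distance_metric: str = "euclidean",
) -> CrossCohortResults:
    """Convenience wrapper: ``CrossCohortAudit(...).fit()``."""
    return CrossCohortAudit(cohorts, signature, train_name, distance_metric).fit()


@dataclass
class AuditReport:
    """Per-cohort random-signature nulls paired with cross-cohort audits."""

    signature_name: str
    seed: int
    n_draws: int
    distance_metric: str
    cohort_names: list[str]
    matched_sizes: dict[str, int]
    null_audits: dict[str, RandomSignatureAudit]
    cross_audits: dict[str, CrossCohortResults]

    def null_frame(self) -> pd.DataFrame:
        frames = [self.null_audits[name].to_frame() for name in self.cohort_names]
        return pd.concat(frames, ignore_index=True)

    def cross_frame(self) -> pd.DataFrame:
        frames = [self.cross_audits[name].to_frame() for name in self.cohort_names]
        return pd.concat(frames, ignore_index=True)

    def to_json_dict(self) -> dict:
        return {
            "format": "sigaudit-report",
            "schema_version": 1,
            "signature": self.signature_name,
            "seed": self.seed,
            "n_draws": self.n_draws,
            "distance_metric": self.distance_metric,
            "cohorts": list(self.cohort_names),
            "matched_signature_sizes": dict(self.matched_sizes),
            "random_signature_null": {
                name: self.null_audits[name].box.to_dict()
                for name in self.cohort_names
            },
            "cross_cohort_auc": {
                name: {
                    "resubstitution": self.cross_audits[
                        name
                    ].training_resubstitution.auc,
                    "test": dict(sorted(self.cross_audits[name].test_aucs.items())),
                    "failed": dict(sorted(self.cross_audits[name].failures.items())),
                }
                for name in self.cohort_names
            },
        }

    def summary(self) -> str:
        parts = [
            f"Signature audit report — signature {self.signature_name!r}, "
            f"{len(self.cohort_names)} cohorts, n_draws={self.n_draws}, "
            f"seed={self.seed}",
            "",
        ]
        for name in self.cohort_names:
            parts.append(self.null_audits[name].summary())
            parts.append(self.cross_audits[name].summary())
            parts.append("")
        return "\n".join(parts).rstrip()


def full_audit(
    cohorts: list[ExpressionCohort],
    signature: GeneSignature,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    distance_metric: str = "euclidean",
) -> AuditReport:
    """Run both audits for every cohort.

    For each cohort: a random-signature null with the signature size
    matched to that cohort (|signature ∩ cohort genes|), and a
    cross-cohort audit with that cohort as training set.  Per-cohort
    random substreams are spawned deterministically from ``seed``.
    """
    names = [c.name for c in cohorts]
    matched = {c.name: size_matched_signature_size(signature, c) for c in cohorts}
    bad = [n for n, k in matched.items() if k == 0]
    if bad:
        raise SigauditError(
            f"signature {signature.name!r} shares no genes with cohorts {bad}"
        )
    children = np.random.SeedSequence(seed).spawn(len(cohorts))
    null_audits = {
        c.name: RandomSignatureNull(
            c, matched[c.name], n_draws, child, distance_metric
        ).fit()
        for c, child in zip(cohorts, children)
    }
    cross_audits = {
        c.name: CrossCohortAudit(cohorts, signature, c.name, distance_metric).fit()
        for c in cohorts
    }
    return AuditReport(
        signature_name=signature.name,
        seed=seed,
        n_draws=n_draws,
        distance_metric=distance_metric,
        cohort_names=names,
        matched_sizes=matched,
        null_audits=null_audits,
        cross_audits=cross_audits,
    )
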