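"""Core in-memory containers: expression cohorts and gene signatures.

An :class:`ExpressionCohort` holds one dataset's expression matrix on a
variance-stabilized log scale (genes in rows, samples in columns) together
with a binary response label per sample (1 = responder to immune checkpoint
therapy, 0 = non-responder).  A :class:`GeneSignature` is a named, ordered
list of unique gene identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd


class SigauditError(ValueError):
    """Base class for all validation errors raised by this package."""


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered set of unique gene identifiers."""

    name: str
    genes: tuple[str, ...]

    def __init__(self, name: str, genes: Sequence[str]) -> None:
        genes = tuple(str(g) for g in genes)
        if not genes:
            raise SigauditError(f"signature {name!r} is empty")
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if list(genes).count(g) > 1})
            raise SigauditError(
                f"signature {name!r} contains duplicate gene identifiers: {dupes[:5]}"
            )
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def intersect(self, gene_universe: Sequence[str]) -> tuple[str, ...]:
        """Signature genes present in *gene_universe*, in signature order."""
        present = set(gene_universe)
        return tuple(g for g in self.genes if g in present)


@dataclass
class ExpressionCohort:
    """One cohort: log-scale expression (genes x samples) plus binary labels.

    Parameters
    ----------
    name
        Cohort identifier (e.g. an accession or a simulation label).
    genes, samples
        Row / column identifiers; genes must be unique within the cohort.
    values
        Real matrix of shape ``(len(genes), len(samples))`` on a
        variance-stabilized log scale.  The package never re-normalizes.
    labels
        0/1 vector per sample; both classes must be present (AUC is
        undefined otherwise).
    metadata
        Free-form provenance (simulation parameters, adjustment flags, ...).
    """

    name: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray
    labels: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise SigauditError(
                f"cohort {self.name!r}: values shape {self.values.shape} does not "
                f"match {len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise SigauditError(f"cohort {self.name!r}: duplicate gene identifiers")
        if self.labels.shape != (len(self.samples),):
            raise SigauditError(f"cohort {self.name!r}: one label per sample required")
        if not np.isin(self.labels, (0, 1)).all():
            raise SigauditError(f"cohort {self.name!r}: labels must be 0/1")
        if len(np.unique(self.labels)) < 2:
            raise SigauditError(
                f"cohort {self.name!r}: both responder and non-responder labels "
                "are required"
            )
        if not np.isfinite(self.values).all():
            raise SigauditError(f"cohort {self.name!r}: non-finite expression values")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_responders(self) -> int:
        return int(self.labels.sum())

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices of *genes* (all must be present)."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise SigauditError(
                f"cohort {self.name!r}: {len(missing)} genes not present, "
                f"e.g. {missing[:5]}"
            )
        return np.array([lookup[g] for g in genes], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        """Expression as a DataFrame (genes in rows, samples in columns)."""
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def labels_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.samples, name="response")
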