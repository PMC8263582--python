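"""Synthetic multi-cohort expression generator.

Emulates the statistical structure the audits assume: several cohorts of
log-scale (variance-stabilized) bulk expression with imbalanced binary
response labels, cohort-specific per-gene batch shifts, an optional true
differential signal on a known gene subset, and partial gene-universe
overlap across cohorts.  The model is additive Gaussian on the log scale:

    x[g, i] = mu[g] + b[d, g] + beta[g] * y[i] + e[g, i]

with ``mu[g] ~ N(0, 1)`` shared across cohorts, batch ``b[d, g] ~
N(0, batch_sd^2)`` drawn independently per cohort, ``beta[g] =
effect_size`` on the first ``n_signal_genes`` genes of the universe and 0
elsewhere, residual ``e ~ N(0, noise_sd^2)``, and labels ``y[i] ~
Bernoulli(responder_fraction)``.  Each cohort then drops a uniformly
random ``gene_dropout_fraction`` of the gene universe, independently, so
a fixed signature matches a slightly different gene count in every cohort.

Everything is reproducible from ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .cohorts import ExpressionCohort, GeneSignature, SigauditError

#: default per-cohort sample count (small ICT cohorts; p >> n by design)
DEFAULT_SAMPLES = 26


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-cohort generator.

    Defaults describe the null study condition the audits are demonstrated
    on: four small cohorts (26 samples each) drawn from a 2000-gene
    universe, 40% responders, moderate cohort batch shifts, no true signal
    (``effect_size=0``), and 3% of the universe missing per cohort.
    """

    n_cohorts: int = 4
    genes_total: int = 2000
    samples_per_cohort: list[int] = field(default_factory=lambda: [DEFAULT_SAMPLES] * 4)
    responder_fraction: float = 0.4
    effect_size: float = 0.0
    n_signal_genes: int = 50
    batch_sd: float = 0.5
    noise_sd: float = 1.0
    gene_dropout_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohorts < 1:
            raise SigauditError("n_cohorts must be >= 1")
        if self.genes_total < 1:
            raise SigauditError("genes_total must be >= 1")
        if len(self.samples_per_cohort) != self.n_cohorts:
            raise SigauditError(
                f"samples_per_cohort has {len(self.samples_per_cohort)} entries "
                f"for {self.n_cohorts} cohorts"
            )
        if any(n < 2 for n in self.samples_per_cohort):
            raise SigauditError("each cohort needs >= 2 samples (both classes)")
        if not 0.0 < self.responder_fraction < 1.0:
            raise SigauditError("responder_fraction must be strictly in (0, 1)")
        if self.batch_sd < 0 or self.noise_sd < 0:
            raise SigauditError("standard deviations must be >= 0")
        if not 0.0 <= self.gene_dropout_fraction < 1.0:
            raise SigauditError("gene_dropout_fraction must be in [0, 1)")
        if self.n_signal_genes < 0 or self.n_signal_genes > self.genes_total:
            raise SigauditError("n_signal_genes must be in [0, genes_total]")

    def to_dict(self) -> dict:
        return asdict(self)


def gene_universe(config: SimulationConfig) -> list[str]:
    """Synthetic gene identifiers ``G000001 ... G<genes_total>``."""
    return [f"G{i + 1:06d}" for i in range(config.genes_total)]


def _force_both_classes(labels: np.ndarray) -> tuple[np.ndarray, bool]:
    """Deterministically flip labels so both classes are present.

    AUC is undefined for a single-class cohort, so a degenerate Bernoulli
    draw flips the first sample into the missing class.
    """
    labels = labels.copy()
    adjusted = False
    if labels.sum() == 0:
        labels[0] = 1
        adjusted = True
    elif labels.sum() == len(labels):
        labels[0] = 0
        adjusted = True
    return labels, adjusted


def generate_cohorts(config: SimulationConfig) -> list[ExpressionCohort]:
    """Generate the configured cohorts; bit-reproducible from the seed.

    The per-gene baseline means are shared across cohorts; each cohort gets
    its own independent random stream (labels, batch shifts, residual
    noise, gene dropout) spawned deterministically from the master seed, so
    adding a cohort never perturbs earlier ones.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_cohorts + 1)
    rng_shared = np.random.default_rng(children[0])

    universe = gene_universe(config)
    mu = rng_shared.normal(0.0, 1.0, size=config.genes_total)
    beta = np.zeros(config.genes_total)
    beta[: config.n_signal_genes] = config.effect_size

    n_drop = int(round(config.gene_dropout_fraction * config.genes_total))
    cohorts: list[ExpressionCohort] = []
    for d in range(config.n_cohorts):
        rng = np.random.default_rng(children[d + 1])
        n = config.samples_per_cohort[d]
        labels = (rng.random(n) < config.responder_fraction).astype(int)
        labels, adjusted = _force_both_classes(labels)
        batch = rng.normal(0.0, config.batch_sd, size=config.genes_total)
        noise = rng.normal(0.0, config.noise_sd, size=(config.genes_total, n))
        values = mu[:, None] + batch[:, None] + np.outer(beta, labels) + noise

        keep = np.ones(config.genes_total, dtype=bool)
        if n_drop:
            drop_idx = rng.choice(config.genes_total, size=n_drop, replace=False)
            keep[drop_idx] = False
        name = f"cohort{d + 1}"
        cohorts.append(
            ExpressionCohort(
                name=name,
                genes=[g for g, k in zip(universe, keep) if k],
                samples=[f"{name}_s{i + 1:03d}" for i in range(n)],
                values=values[keep, :],
                labels=labels,
                metadata={
                    "simulated": True,
                    "labels_adjusted": adjusted,
                    "n_genes_dropped": int(n_drop),
                    "config": config.to_dict(),
                },
            )
        )
    return cohorts


def signal_signature(config: SimulationConfig) -> GeneSignature:
    """The identifiers of the injected signal genes, for recovery tests."""
    if config.n_signal_genes == 0:
        raise SigauditError(
            "config has n_signal_genes=0: there is no signal signature"
        )
    universe = gene_universe(config)
    return GeneSignature("signal", universe[: config.n_signal_genes])
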