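# Methods

## Problem setting

A gene signature is a fixed list of gene identifiers claimed to predict a
binary phenotype — here, response to immune checkpoint therapy — from
bulk expression. The classifier audited throughout is the
nearest-centroid family commonly used for such signatures. The package
answers two questions about any signature/classifier pair: *does the
reported AUC merely reflect training error?* (random-signature null) and
*does the fitted model transfer to independent cohorts?* (leave-one-
cohort-out audit).

## Classifier

**Fitting.** Given a training cohort (genes × samples, variance-
stabilized log scale) and a signature, the model keeps the signature
genes present in the cohort, in signature order. Each retained gene is
standardized by its training mean and standard deviation computed over
*all* training samples (not per class); the sample standard deviation
(ddof = 1) is used. Genes with zero training variance are dropped with a
logged warning — standardization is undefined for them. The responder
and non-responder centroids are the mean standardized profiles of the
two classes.

**Scoring.** A sample is standardized with the frozen training
parameters and scored by the normalized distance difference
`s = (d⁻ − d⁺)/(d⁻ + d⁺ + ε)` with `ε = 1e−12` guarding the 0/0 case of
a sample coinciding with both centroids. The score is bounded in
[−1, 1], is +1 at the responder centroid and −1 at the non-responder
centroid, and is a strictly monotone function of relative proximity, so
the ROC and AUC it induces equal those of any other monotone score for
the same centroids. Nothing beyond the score convention is asserted to
match other nearest-centroid implementations: only the ROC ordering is
comparable across implementations, which is all the audits use. Hard
class calls (used nowhere in the audits) are `s > 0` → responder, with
the tie `s = 0` assigned to non-responder.

Two distance metrics are available: Euclidean (default) and correlation
(1 − Pearson, computed on the standardized vectors; a flat profile has
undefined correlation and is treated as distance 1). Correlation
distance scores by profile shape and ignores a sample-wide offset.

**Freezing.** A test cohort is never standardized with its own
statistics, and test labels are never read during scoring — this is the
leakage the audits are designed to expose, so it is excluded by
construction and asserted by a test (permuting test labels leaves scores
bit-identical). Model genes absent from a test cohort are dropped from
both centroids and the sample vectors at scoring time, with a logged
count; scoring fails only if no model gene is present.

## ROC and AUC

AUC uses the Mann–Whitney rank formulation with ties counted ½ — the
convention is fixed here because different tie rules give different
values on the heavily tied score vectors that small cohorts produce. The
swept ROC curve (all score thresholds, no intermediate-point dropping)
is produced by scikit-learn; a property test verifies that its
trapezoidal area equals the rank AUC on arbitrary tied inputs, so the
two routes cross-check each other. Box-plot summaries of AUC
distributions use linear interpolation between order statistics for the
quartiles (the numpy default) and whiskers at the most extreme observed
values within 1.5 × IQR of the quartiles.

## Audits

**Random-signature resubstitution null.** `n_draws` (default 50) gene
sets of a given size are drawn uniformly without replacement from the
cohort's own gene list, ignoring any biological annotation. "Repeated
draws of gene sets" — not resampling of patients — is the resampling
unit, since the question is about signatures, not sampling error. For a
named signature the draw size is matched per cohort to
|signature ∩ cohort genes|, so partial gene-universe overlap is handled
the same way for the null as for the signature itself. Each draw is
fitted on the full cohort and scored on the same cohort; that
resubstitution step is deliberate — the procedure measures how good
*noise* looks under same-cohort evaluation.

**Cross-cohort audit.** One cohort trains; the frozen model scores every
other cohort. The training-resubstitution ROC is recorded alongside so
inflation is visible side by side. A test cohort sharing no model genes
is reported as failed with a reason while the others are still computed.
Treatment-arm or platform sub-splits are handled by passing the sub-split
as its own cohort; nothing is hard-coded to particular datasets.

**Randomness.** One master seed per run. Per-cohort and per-draw
substreams are spawned deterministically (`numpy` `SeedSequence`), so
any single draw can be reproduced in isolation and reports rerun
byte-identically from the same seed.

## Synthetic cohorts

The generator emulates the structure the audits assume, on the scale the
pipeline consumes (already variance-stabilized log expression):

    x[g, i] = mu[g] + b[d, g] + beta[g] * y[i] + e[g, i]

with shared per-gene baselines `mu[g] ~ N(0, 1)`, independent per-cohort
batch shifts `b[d, g] ~ N(0, batch_sd²)`, labels
`y[i] ~ Bernoulli(responder_fraction)`, a mean shift `beta[g] =
effect_size` on the first `n_signal_genes` genes of the universe (zero
elsewhere), and residual noise `e ~ N(0, noise_sd²)`. Each cohort drops
a uniformly random `gene_dropout_fraction` of the universe,
independently, so a fixed signature matches a slightly different gene
count in each cohort. A degenerate label draw (all one class) is
repaired deterministically by flipping the first sample, and the repair
is recorded in cohort metadata, because AUC is undefined otherwise.

Defaults, chosen once as a realistic small multi-cohort ICT study:

| parameter              | default | rationale                                           |
|------------------------|---------|-----------------------------------------------------|
| `n_cohorts`            | 4       | typical discovery + validation layout               |
| `samples_per_cohort`   | 26 each | small pretreatment cohorts; p ≫ n by design         |
| `genes_total`          | 2000    | enough genes for 100-gene draws with p ≫ n, cheap   |
| `responder_fraction`   | 0.4     | imbalanced response, both classes well represented  |
| `effect_size`          | 0       | null by default; signal is opt-in                   |
| `n_signal_genes`       | 50      | signature-sized gene subset for recovery tests      |
| `batch_sd`             | 0.5     | cross-cohort shifts comparable to half the noise sd |
| `noise_sd`             | 1       | unit within-cohort variation (log scale)            |
| `gene_dropout_fraction`| 0.03    | per-cohort signature matches vary by a few genes    |

What the generator does **not** emulate: count-level sampling and the
regularized-log transform (data are generated directly on the
transformed scale), library-size effects, gene–gene correlation, and
any real biology behind the labels. Passing audits on these data show
the *procedures* behave correctly (inflated resubstitution AUC under
p ≫ n, chance-level transfer under the null, high transfer for a true
batch-free signal); they say nothing about any particular real
signature, which is exactly the point of shipping the audit rather than
a verdict.

## Numerical and design choices

- Score guard `ε = 1e−12`; a sample exactly at a centroid scores ±1 to
  within 1e−9.
- Standardization uses ddof = 1. Any common convention works — scores
  are monotone-invariant to it — but one must be fixed for exact
  serialization round-trips.
- Writers use `%.17g` float formatting, which round-trips IEEE doubles
  exactly; the reader parses with `float_precision="round_trip"`. All
  outputs are byte-deterministic given identical inputs and seed.
- Missing expression values are rejected, not imputed; expression is
  assumed pre-transformed and is never re-normalized.
- Gene matching is exact string identity; no alias resolution.

## Problem sizes

The shipped checks run the audits at the default study conditions: 50
draws per cohort for the null (5 master seeds), 20 replicate simulations
for the chance-transfer statistic, and 5 seeds for the signal-recovery
control. The full test suite and the acceptance script each complete in
well under a minute on one CPU; all sizes are plain parameters and scale
up directly.

## Known limitations

- The audits assume cohorts share a meaningful gene-identifier space;
  heavy identifier mismatch silently shrinks the usable signature (the
  matched size and drop counts are reported so this is visible).
- Correlation distance with very short gene lists (< 3 genes) is
  fragile; Euclidean is the default.
- No confidence intervals on AUC (e.g. DeLong) — the audits compare
  distributions and frozen-model transfer, not single-AUC significance.
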