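# sigaudit

Validation audits for gene-expression signature classifiers.

A recurring failure mode in transcriptomic biomarker studies is reporting
the *training* (resubstitution) error of a classifier as if it were a
validation result: a model is fitted on a cohort and then "validated" by
scoring the very same cohort. With tens of thousands of genes and a few
dozen patients, almost any gene set — including a random one — separates
the training samples almost perfectly, so a high same-cohort AUC says
nothing about the signature. `sigaudit` packages the two diagnostics that
expose this, for anyone evaluating expression signatures of treatment
response (the motivating setting is immune checkpoint therapy response in
melanoma):

1. **Random-signature resubstitution null.** Draw many size-matched random
   gene sets, train a nearest-centroid classifier on the cohort, score the
   same cohort, and look at the AUC distribution. If random genes score
   as well as the proposed signature, the evaluation scheme — not the
   biology — produced the number.
2. **Leave-one-cohort-out generalization audit.** Fit once on one cohort,
   freeze the model entirely (gene set, standardization parameters,
   centroids), and score every other cohort. A genuine signature
   transfers; an overfit one falls to chance (AUC ≈ 0.5).

A synthetic multi-cohort generator with cohort batch effects, imbalanced
labels and partial gene-universe overlap makes both audits runnable and
testable without downloading any accession.

## The model

For a signature *G* and training cohort with expression `x[g, i]` (log
scale, genes × samples) and binary labels `y[i]`:

- keep the genes of *G* present in the cohort (in signature order), drop
  genes with zero training variance;
- standardize each gene with the training mean and standard deviation
  (sample sd, all training samples pooled): `z[g, i] = (x[g, i] − m[g]) / s[g]`;
- class centroids `c⁺[g]`, `c⁻[g]` are the mean standardized profiles of
  responders and non-responders;
- a sample with standardized profile `z` gets the continuous score

  `s = (d⁻ − d⁺) / (d⁻ + d⁺ + ε)`,

  where `d±` is the (Euclidean or correlation) distance to each centroid,
  so `s ∈ [−1, 1]` and `s > 0` means "nearer the responder centroid".

AUC is the Mann–Whitney statistic with ties counted ½,
`AUC = [Σ ranks(pos) − n⁺(n⁺+1)/2] / (n⁺ n⁻)`, identical to the
trapezoidal area under the threshold-swept ROC curve. Held-out cohorts
are always standardized with the *training* parameters; scoring never
touches test labels.

## Worked example

```python
import sigaudit as sa

config = sa.SimulationConfig(seed=0)      # 4 null cohorts, 26 samples, 2000 genes
cohorts = sa.generate_cohorts(config)
signature = sa.signal_signature(config)   # 50 genes; effect_size=0, so pure noise

report = sa.full_audit(cohorts, signature, n_draws=50, seed=0)
print(report.summary())
```

prints (first cohort shown):

```
Signature audit report — signature 'signal', 4 cohorts, n_draws=50, seed=0

Random-signature resubstitution null — cohort cohort1
  draws=50  signature_size=46
  AUC median=0.990  IQR=[0.975, 1.000]  range=[0.922, 1.000]  mean=0.984
Cross-cohort audit — trained on cohort1 (signature 'signal', 46 genes)
  resubstitution AUC = 0.961
  test on cohort2: AUC = 0.436
  test on cohort3: AUC = 0.470
  test on cohort4: AUC = 0.519
```

Read it like this: the data contain **no** class signal, yet 50 random
46-gene sets achieve a median *training* AUC of 0.99 on 26 samples —
resubstitution evaluation certifies noise. The same frozen model scored
on the three other cohorts sits at chance (0.44–0.52), which is the
honest estimate of its predictive value. `signature_size` differs per
cohort (46/49/47/45 here) because each cohort is missing a few genes of
the universe; the null is always size-matched through the signature ∩
cohort intersection.

The same pipeline runs from the shell on TSV matrices
(genes in rows, samples in columns, plus a `sample`/`response` label
table — your own cohorts work the same way as simulated ones):

```bash
sigaudit simulate --seed 0 --out-dir data/
sigaudit audit-full \
  --cohort data/cohort1.expression.tsv data/cohort1.labels.tsv cohort1 \
  --cohort data/cohort2.expression.tsv data/cohort2.labels.tsv cohort2 \
  --cohort data/cohort3.expression.tsv data/cohort3.labels.tsv cohort3 \
  --cohort data/cohort4.expression.tsv data/cohort4.labels.tsv cohort4 \
  --signature data/signal_signature.txt --seed 0 --out-dir out/ --plot
```

which writes tidy CSVs (one row per random draw, one row per train/test
pair), a JSON summary, and optional box-plot / ROC-grid figures.

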