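# bulkpurity

Tumor purity — the fraction of malignant cells in a bulk tumor sample — is a
basic quantity in cancer genomics: it confounds expression-based analyses,
scales variant allele frequencies, and is itself a readout of tumor-immune
architecture. It is usually estimated from DNA (copy-number or mutation
data), but DNA is not always available. `bulkpurity` estimates purity
directly from a bulk RNA expression profile, for bioinformaticians who have
expression matrices (TPM/FPKM/counts) and want per-sample purity without
matched DNA.

## The method

Every sample's expression vector is replaced by its **rank percentiles**
over a fixed gene universe *G*: values are ranked ascending with the lowest
possible rank for ties, and each rank is divided by the number of ranked
genes (so `[0, 0, 1, 5, 100]` → ranks `[1, 1, 3, 4, 5]` → percentiles
`[0.2, 0.2, 0.6, 0.8, 1]`). Percentiles are invariant to any per-sample
rescaling, which makes one trained model portable across platforms and
units.

Training is **weakly supervised**: instead of gold-standard labels, each
training sample gets a consensus of several noisy DNA-based purity
estimates — implausible extremes (< 0.1, > 0.98) are masked, missing cells
are filled by iterative-PCA low-rank completion, methods are
quantile-normalized within each cancer type, and the per-sample median is
the label *y* ∈ [0, 1].

Features are chosen by a **two-step lasso**. Step 1 fits two L1-penalized
regressions of *y* on the rank features with leave-one-cancer-type-out
cross-validation — one excluding each type's top-20% purity tail, one the
bottom-20% — and intersects their supports, keeping genes informative over
the whole purity range. Step 2 repeats the grouped-CV lasso on balanced,
purity-distribution-preserving subsamples (equal *n* from every cancer
type), so no large cohort dominates. The final predictor is plain OLS on
the selected features:

> ŷ = clip( w·rank_G(x) + b , 0, 1 ),

with each feature's training-median percentile imputed when a gene is
missing from the input. Cancer-type-specific lasso models and
leave-one-cancer-type-out training are provided for benchmarking, and a
single-cell check verifies that the selected genes separate malignant from
non-malignant cells.

A synthetic-cohort generator (linear cancer/stroma mixtures with planted
marker genes, noisy pseudo-genomics estimator panels, labeled single cells)
makes the whole pipeline testable with no external data.

## Worked example

```python
import bulkpurity as bp

cohort = bp.make_cohort(n_groups=4, samples_per_group=150, n_genes=300,
                        n_informative=20, seed=7)
estimates, _ = bp.make_purity_estimates(cohort, seed=8)
labels = bp.build_consensus(estimates, cohort.groups)

train_ids, test_ids = bp.stratified_split(labels, cohort.groups.loc[labels.index],
                                          train_fraction=0.8, seed=9)
universe = bp.filter_genes(cohort.expr.loc[train_ids], cohort.groups.loc[train_ids])
ranks = bp.rank_percentile(cohort.expr.loc[train_ids], universe)

features = bp.select_features(ranks, labels.loc[train_ids],
                              cohort.groups.loc[train_ids],
                              bp.SelectionConfig(seed=10))
model = bp.train(ranks, labels.loc[train_ids], features, universe=universe)

pred = bp.predict(model, cohort.expr.loc[test_ids])
report = bp.score(pred["purity"], cohort.true_purity.loc[test_ids],
                  cohort.groups.loc[test_ids])
print(f"selected features: {len(features)} (step 1: {features.n_step1})")
print(report)
print(report.per_group.round(3))
```

prints

```
selected features: 9 (step 1: 9)
EvaluationReport(4 groups, median r = 0.989, median RMSE = 0.041)
     pearson_r   rmse   n
CT1      0.985  0.031  30
CT2      0.992  0.040  30
CT3      0.991  0.042  30
CT4      0.988  0.048  30
```

The lasso kept 9 genes out of 300; on held-out samples the predicted purity
correlates with the generator's true malignant fraction at r ≈ 0.99 per
cancer type with RMSE ≈ 0.03–0.05 purity units. Because the planted marker
genes all track purity, the sparse fit keeps a representative subset of
them, not every marker.

The same pipeline is available from the shell:

```bash
bulkpurity simulate cohort --seed 7 --out demo
bulkpurity simulate estimates --expr demo.expr.tsv --purity demo.purity.tsv \
    --seed 8 --out demo
bulkpurity consensus --estimates demo.estimates.tsv --groups demo.groups.tsv \
    --out demo.labels.tsv
bulkpurity train --expr demo.expr.tsv --labels demo.labels.tsv \
    --groups demo.groups.tsv --seed 9 --out demo.model.json
bulkpurity predict --model demo.model.json --expr demo.expr.tsv --out demo.pred.tsv
bulkpurity evaluate --pred demo.pred.tsv --truth demo.purity.tsv \
    --groups demo.groups.tsv --out demo.report
```

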