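# Methods

## Model

`bulkpurity` treats bulk tumor expression as a two-component linear mixture:
a sample with malignant-cell fraction *p* (purity) measures approximately
*p·C + (1−p)·S*, where *C* and *S* are the expression profiles of the
cancerous and the stromal/immune compartment of that cancer type. Genes
whose cancer-vs-stroma contrast has a consistent sign across solid tumor
types carry a purity signal that transfers between cohorts; the package
learns a sparse linear read-out of that signal.

The predictor operates on **sample-wise rank percentiles** rather than raw
values: within each sample, the genes shared with a fixed universe *G* are
ranked ascending (ties take the lowest possible rank) and divided by the
number of genes ranked in that sample. This removes all per-sample scale
and monotone-unit effects — TPM, FPKM and reasonably processed counts give
identical inputs — at the cost of discarding absolute abundance. The
percentile denominator is the count of universe genes *observed in that
sample*, not |*G*|: a complete sample's unique maximum then maps to exactly
1, the transform is self-contained per sample, and universe genes absent
from an input contribute nothing (they are handled by median imputation at
the feature stage instead of silently shifting every percentile). This is
one of two defensible denominators; it was fixed once and is documented
here because the alternative (always |*G*|) changes predictions when inputs
cover only part of the universe.

## Consensus labels (weak supervision)

Training labels are built from a panel of DNA-based purity estimates, in a
fixed order that the API enforces:

1. **Flagging** — entries strictly below 0.1 or strictly above 0.98 become
   missing. DNA callers are unreliable at the extremes of their range;
   boundary values are kept (strict inequalities).
2. **Imputation** — missing cells are filled by iterative PCA: initialize
   with column means, alternate a rank-*k* reconstruction (SVD of the
   column-centered table) with overwriting only the missing cells, until
   the largest change is below `tol`. Defaults *k* = 2 (half the default
   four-method panel; captures a shared purity factor plus one systematic
   contrast), `tol` = 1e-6, `max_iter` = 100. Observed cells are never
   altered; imputed cells are clipped to [0, 1]. Imputation runs
   pan-cancer by default (more rows stabilize the low-rank fit), with a
   per-cancer-type option.
3. **Quantile normalization per cancer type** — each method's values are
   mapped onto the mean of the per-method sorted vectors (ties get the
   mean of the tied reference positions), removing calibration differences
   between callers while preserving each caller's ranking.
4. **Reduction** — the per-sample median (mean available) across methods,
   clipped to [0, 1].

## Feature selection

Selection works on the rank matrix over the filtered universe. The
**gene filter** removes genes with both median expression < 1 and variance
< 1 (linear units) in *every* cancer type of the training split; one
passing group keeps the gene. An optional allow-list stands in for
biotype/chromosome restrictions, since those annotations are an external
resource.

**Step 1 — purity-range robustness.** Two lasso regressions of the label on
all rank features, one fitted after dropping each cancer type's top-20%
purity tail, one after dropping the bottom-20%. Both use
leave-one-cancer-type-out cross-validation over a penalty grid (50
log-spaced values spanning four decades below the critical penalty
max|Xᵀ(y−ȳ)|/n at which all coefficients vanish), choosing the penalty with
minimal mean CV squared error; ties break toward the sparser fit. The two
supports are intersected. Tails are trimmed per cancer type (purity
distributions differ strongly between types; a pooled trim would remove
whole types from one tail), with a pooled option.

**Step 2 — cancer-type balance.** Restricted to the step-1 genes, the
grouped-CV lasso is refitted with every training fold replaced by a
balanced subsample: an equal number of samples (default: the smallest
group's size) drawn from each cancer type, allocated across within-type
purity deciles by largest-remainder rounding so the purity distribution is
preserved. The penalty again minimizes mean CV error; the final support
comes from one refit at that penalty on a balanced subsample spanning all
types. "Iterative" refinement is realized as this single CV + refit pass —
the simplest deterministic reading; a scheme that re-subsamples and
accumulates supports across repetitions would select more genes at the
cost of a stochastic support. Coefficients with |w| ≤ 1e-10 count as zero
(coordinate-descent noise).

Each selected gene is annotated with its purity–expression Pearson
correlation computed within each cancer type and averaged across types —
the quantity later used to split features into positive and negative sets
for single-cell validation.

## Final model and inference

The production model is **unregularized OLS** of the label on the selected
rank features (selection already enforced sparsity; a second penalty would
only bias the weights), solved by minimum-norm least squares with a warning
if the design is rank-deficient. The model file carries the full ranking
universe, the feature genes, weights, intercept, and each feature's median
training percentile.

Prediction on unseen samples runs three stages: rank-percentile transform
over (input genes ∩ universe); restriction to the feature genes, imputing
any absent feature with its stored training median (medians of rank
percentiles, not raw expression, because imputation happens after the rank
stage); linear prediction clipped to [0, 1]. The output reports the number
of imputed features per sample and warns when more than half the features
were imputed.

Two comparison modes mirror common benchmarking questions:
cancer-type-specific lasso models (5-fold CV per type, full universe) and
leave-one-cancer-type-out OLS models on the fixed feature set, whose
evaluation on the withheld type measures transfer to unseen tumor types.

## Evaluation

Accuracy is summarized per cancer type as Pearson *r* and RMSE, with
cross-type medians and IQRs. Model-vs-model comparisons use the two-tailed
Wilcoxon signed-rank test on per-type metric pairs (exact null up to 25
types, normal approximation with continuity correction above; all-zero
differences give p = 1 by convention). Single-cell validation z-scores each
gene across all cells jointly — pooling malignant and non-malignant cells,
since per-class scaling would erase exactly the difference being tested —
and compares mean cell-wise z over the top- and bottom-correlated feature
subsets between classes with a two-tailed Mann–Whitney U test.

## Synthetic data

The generator emulates the data the method assumes, not any particular
cohort. Defaults define the package's standard study conditions: 8 cancer
types × 200 samples, 1000 genes, 60 planted markers (30 up in cancer, 30 up
in stroma), multiplicative log-normal noise with σ = 0.1.

Per type *g*, a shared log-normal baseline (log-mean 1, log-sd 1, mildly
perturbed per type) splits into references *C_g* and *S_g*: planted markers
get a fixed ±2.0 log offset between *C* and *S* (≈ 7.4-fold, the order of
strong epithelial/stromal markers), identical in every type; all other
genes get an independent per-type offset with sd 0.3, making them
purity-correlated within a type but inconsistent across types — exactly the
confounders the grouped CV must reject. Sample expression is
*p·C_g + (1−p)·S_g* times log-normal noise (additive-Gaussian option);
purity is Beta-distributed with per-type means evenly spaced over
0.35–0.72 and concentration 8, deliberately imbalanced to exercise the
balancing machinery. Pseudo-genomics panels add per-method bias (sd 0.03)
and noise (sd 0.08) to the true purity, corrupt 5% of entries to extremes
and delete 3%. Single cells are log-normal draws (sd 0.5) around *C_g* or
*S_g* with Bernoulli dropout (rate 0.6).

What the generator does **not** emulate: realistic per-gene expression
distributions, library-size and batch effects, more than two cell
compartments, copy-number-driven expression changes, or gene–gene
correlation beyond the purity axis. Passing tests therefore demonstrate
that the pipeline's machinery is correct and recovers a linear mixing
signal under noise — not that any particular accuracy will be attained on
real tumors.

A structural property of the mixture model matters for interpreting
feature-selection tests: because every planted marker is (up to noise) the
same monotone function of purity, their rank features are strongly mutually
correlated, and an L1-penalized fit keeps a small representative subset of
them — prediction-optimal, but not an enumeration of all markers. Recovery
of the *complete* planted set is thus not a property this pipeline can or
should promise; tests assert accuracy of the prediction and the quality
(precision) of what is selected.

## Numerical choices and degenerate inputs

- Lasso fits: scikit-learn coordinate descent, `max_iter` 20 000, cyclic
  (deterministic) updates; paths computed on column-centered data with the
  intercept restored afterwards.
- Determinism: every stochastic step (simulation, splitting, subsampling)
  takes an explicit seed through `numpy.random.default_rng`; fold-level
  subsample seeds derive from the configured seed. Identical seeds give
  byte-identical cohorts, selections and serialized models.
- Stratified operations build purity deciles with quantile cuts on
  rank-broken ties; groups smaller than the stratum count fall back to
  simple random splits with a warning.
- Degenerate cases: single-point purity ranges are allowed but warned
  (recovery metrics undefined); samples losing all purity estimates after
  flagging are dropped with a warning; a method column with no observation
  is an error; zero-variance prediction groups report RMSE with an
  undefined correlation; constant genes contribute z = 0 in single-cell
  scoring.
- Model serialization is a single JSON document; floating-point values
  round-trip exactly, so save → load → predict is bit-identical.

## Problem sizes

The test suite runs the full pipeline once on the standard 8 × 200 cohort
(the package's reference study conditions) and uses 2–4-type cohorts of
30–150 samples per type elsewhere; these sizes give stable statistics for
every asserted property while keeping the suite quick to run.

## Known limitations

- Trained on solid-tumor-style two-compartment mixtures; hematological
  malignancies and highly heterogeneous stromal mixes violate the model.
- The consensus labels are themselves estimates; systematic bias shared by
  all pseudo-label methods propagates into the model.
- The rank transform discards absolute expression; inputs must still be
  linear-scale and gene-level (no probe collapsing or count normalization
  is performed).
- Gene matching is exact string identity after whitespace stripping; symbol
  drift between annotations must be resolved by the caller (an alias map
  hook is provided in the I/O layer's design but no curated map ships with
  the package).
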