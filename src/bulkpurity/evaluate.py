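"""Evaluation: per-cancer-type accuracy, paired model comparison, single-cell checks.

Accuracy is reported per cohort group as Pearson correlation and RMSE
between predicted and reference purity, with cross-group medians and IQRs.
Two models are compared with the two-tailed Wilcoxon signed-rank test on
their per-group metrics (exact distribution at the usual handful-of-groups
scale).  Feature sets are validated on single-cell data by z-scoring
expression per gene across all cells and comparing mean cell-wise z-scores
of the most positively and most negatively purity-correlated genes between
malignant and non-malignant cells (two-tailed Mann-Whitney U).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from bulkpurity.selection import FeatureSet

__all__ = ["EvaluationReport", "score", "paired_compare", "single_cell_validation"]

#: group counts up to this use the exact signed-rank null distribution
EXACT_WILCOXON_MAX_N = 25


@dataclass
class EvaluationReport:
    """Per-group accuracy plus cross-group summaries."""

    per_group: pd.DataFrame  # index: group; columns: pearson_r, rmse, n
    summary: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # compact, for interactive use
        s = self.summary
        return (
            f"EvaluationReport({len(self.per_group)} groups, "
            f"median r = {s.get('median_r', float('nan')):.3f}, "
            f"median RMSE = {s.get('median_rmse', float('nan')):.3f})"
        )


def score(pred: pd.Series, truth: pd.Series, groups: pd.Series) -> EvaluationReport:
    """Per-group Pearson r and RMSE of predictions against reference purity.

    Computed on the sample intersection of ``pred`` and ``truth``.  Groups
    with fewer than two overlapping samples are skipped with a warning;
    groups where either vector has zero variance get an undefined (NaN)
    correlation but still report RMSE.
    """
    pred, truth = pred.align(truth, join="inner")
    groups = groups.reindex(pred.index)
    rows = {}
    for label, idx in groups.groupby(groups).groups.items():
        a = pred.loc[idx].to_numpy(dtype=float)
        b = truth.loc[idx].to_numpy(dtype=float)
        if len(a) < 2:
            warnings.warn(f"group {label!r} has < 2 overlapping samples; skipped", stacklevel=2)
            continue
        rmse = float(np.sqrt(np.mean((a - b) ** 2)))
        if np.std(a) == 0 or np.std(b) == 0:
            warnings.warn(f"zero variance in group {label!r}; correlation undefined", stacklevel=2)
            r = np.nan
        else:
            r = float(stats.pearsonr(a, b).statistic)
        rows[label] = {"pearson_r": r, "rmse": rmse, "n": len(a)}
    per_group = pd.DataFrame.from_dict(rows, orient="index")
    if per_group.empty:
        raise ValueError("no group had >= 2 overlapping samples")
    summary = {
        "median_r": float(per_group["pearson_r"].median()),
        "mean_r": float(per_group["pearson_r"].mean()),
        "iqr_r": float(per_group["pearson_r"].quantile(0.75) - per_group["pearson_r"].quantile(0.25)),
        "median_rmse": float(per_group["rmse"].median()),
        "mean_rmse": float(per_group["rmse"].mean()),
        "iqr_rmse": float(per_group["rmse"].quantile(0.75) - per_group["rmse"].quantile(0.25)),
        "n_groups": int(len(per_group)),
    }
    return EvaluationReport(per_group=per_group, summary=summary)


def paired_compare(
    report_a: EvaluationReport, report_b: EvaluationReport, metric: str = "r"
) -> tuple[float, float, float]:
    """Wilcoxon signed-rank comparison of two models' per-group metrics.

    Returns ``(statistic, p_two_tailed, delta_of_medians)`` where delta is
    ``median_a - median_b`` over the shared groups.  The exact signed-rank
    null is used for up to 25 groups, the normal approximation with
    continuity correction above.  All-zero differences give p = 1 by
    convention (warned).
    """
    col = {"r": "pearson_r", "rmse": "rmse"}.get(metric)
    if col is None:
        raise ValueError("metric must be 'r' or 'rmse'")
    a = report_a.per_group[col]
    b = report_b.per_group[col]
    common = a.index.intersection(b.index)
    if len(common) != len(a) or len(common) != len(b):
        raise ValueError("reports must cover the same groups")
    diffs = (a.loc[common] - b.loc[common]).to_numpy(dtype=float)
    delta = float(np.median(a.loc[common]) - np.median(b.loc[common]))
    if np.allclose(diffs, 0.0):
        warnings.warn("all per-group differences are zero; p = 1 by convention", stacklevel=2)
        return 0.0, 1.0, delta
    method = "exact" if len(diffs) <= EXACT_WILCOXON_MAX_N else "approx"
    res = stats.wilcoxon(diffs, alternative="two-sided", method=method, correction=True)
    return float(res.statistic), float(res.pvalue), delta


def single_cell_validation(
    expr: pd.DataFrame,
    cell_labels: pd.Series,
    features: FeatureSet,
    top_fraction: float = 0.2,
    bottom_fraction: float = 0.2,
) -> dict:
    """Check that the feature set separates malignant from non-malignant cells.

    The feature genes are split by their mean purity-expression correlation
    into a positive set (top ``top_fraction``) and a negative set (bottom
    ``bottom_fraction``).  Expression is z-scored per gene across all cells
    jointly (pooling both classes keeps the two on one scale), each cell
    gets its mean z over each gene set, and the class distributions are
    compared with a two-tailed Mann-Whitney U test.

    Returns a dict with per-cell scores (DataFrame ``positive_set`` /
    ``negative_set`` columns plus the label), per-class medians, and the two
    p-values.
    """
    if not 0 < top_fraction <= 0.5 or not 0 < bottom_fraction <= 0.5:
        raise ValueError("fractions must be in (0, 0.5]")
    corr = features.correlations.dropna().sort_values()
    n = len(corr)
    n_top = max(1, int(round(top_fraction * n)))
    n_bottom = max(1, int(round(bottom_fraction * n)))
    positive_genes = corr.index[-n_top:].tolist()
    negative_genes = corr.index[:n_bottom].tolist()
    for name, genes in (("positive", positive_genes), ("negative", negative_genes)):
        missing = [g for g in genes if g not in expr.columns]
        if missing:
            raise ValueError(f"{name}-set genes absent from the cell matrix: {missing}")

    cell_labels = cell_labels.reindex(expr.index)
    if cell_labels.isna().any():
        raise ValueError("every cell needs a label")
    classes = set(cell_labels.unique())
    if classes != {"malignant", "non_malignant"}:
        raise ValueError(f"labels must be 'malignant'/'non_malignant', got {sorted(classes)}")

    used = sorted(set(positive_genes) | set(negative_genes))
    x = expr[used].to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0  # constant genes contribute z = 0
    z = pd.DataFrame((x - mu) / sd, index=expr.index, columns=used)

    scores = pd.DataFrame(
        {
            "positive_set": z[positive_genes].mean(axis=1),
            "negative_set": z[negative_genes].mean(axis=1),
            "label": cell_labels,
        }
    )
    is_mal = cell_labels == "malignant"
    result: dict = {"cell_scores": scores, "positive_genes": positive_genes, "negative_genes": negative_genes}
    for key in ("positive_set", "negative_set"):
        mal = scores.loc[is_mal, key].to_numpy()
        non = scores.loc[~is_mal, key].to_numpy()
        test = stats.mannwhitneyu(mal, non, alternative="two-sided")
        result[key] = {
            "median_malignant": float(np.median(mal)),
            "median_non_malignant": float(np.median(non)),
            "statistic": float(test.statistic),
            "p_value": float(test.pvalue),
        }
    return result
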