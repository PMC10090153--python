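"""Consensus purity labels from multiple genomics-style estimators.

Bulk tumors rarely come with gold-standard purity; instead several DNA-based
callers (SNP-array or variant-allele-frequency based) each give a noisy
estimate in [0, 1].  This module turns a samples x methods table of such
estimates into a single per-sample consensus label, the weak-supervision
target for the expression model, in a fixed order:

    flag extremes -> impute missing (iterative PCA) -> quantile-normalize
    per cancer type -> sample-wise median.

Tables are DataFrames (samples x methods) with NaN marking missing values;
cohort groups are a Series aligned to the sample index.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "flag_extremes",
    "impute_missing_ipca",
    "quantile_normalize_by_group",
    "consensus",
    "build_consensus",
    "drop_empty_samples",
]


def _validate_table(table: pd.DataFrame) -> None:
    if table.shape[1] < 1:
        raise ValueError("purity table needs at least one method column")
    vals = table.to_numpy(dtype=float)
    observed = vals[~np.isnan(vals)]
    if observed.size and (observed.min() < 0 or observed.max() > 1):
        raise ValueError("purity estimates must lie in [0, 1]")


def flag_extremes(table: pd.DataFrame, low: float = 0.1, high: float = 0.98) -> pd.DataFrame:
    """Mask implausibly extreme purity estimates as missing.

    Entries strictly below ``low`` or strictly above ``high`` become NaN;
    boundary values are retained.  Genomics purity callers are unreliable at
    the extremes of their range, so such calls are treated as absent and
    later imputed.
    """
    if not 0 <= low < high <= 1:
        raise ValueError("need 0 <= low < high <= 1")
    _validate_table(table)
    out = table.copy()
    out[(out < low) | (out > high)] = np.nan
    return out


def drop_empty_samples(table: pd.DataFrame) -> pd.DataFrame:
    """Drop samples with no remaining observation, warning per drop."""
    empty = table.isna().all(axis=1)
    if empty.any():
        warnings.warn(
            f"dropping {int(empty.sum())} sample(s) with no observed purity estimate",
            stacklevel=2,
        )
        table = table.loc[~empty]
    return table


def impute_missing_ipca(
    table: pd.DataFrame,
    n_components: int = 2,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Fill missing estimates by iterative principal-component reconstruction.

    Missing cells are initialised with column means, then the table is
    alternately approximated by its rank-``n_components`` PCA reconstruction
    and the missing cells overwritten with the reconstructed values, until
    the largest absolute change falls below ``tol`` or ``max_iter`` sweeps.
    Observed entries are never altered; imputed values are clipped to [0, 1].

    Samples with no observation at all are dropped (with a warning); a
    method column with no observation is an error.
    """
    _validate_table(table)
    if table.shape[1] < 2:
        raise ValueError("imputation needs at least two method columns")
    if not 1 <= n_components < table.shape[1]:
        raise ValueError("n_components must satisfy 1 <= k < number of methods")
    no_obs = table.isna().all(axis=0)
    if no_obs.any():
        bad = table.columns[no_obs].tolist()
        raise ValueError(f"method has no observations: {bad}")
    table = drop_empty_samples(table)
    x = table.to_numpy(dtype=float).copy()
    missing = np.isnan(x)
    if not missing.any():
        return table.copy()
    col_means = np.nanmean(x, axis=0)
    x[missing] = np.take(col_means, np.nonzero(missing)[1])
    for _ in range(max_iter):
        mu = x.mean(axis=0)
        centered = x - mu
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        recon = (u[:, :n_components] * s[:n_components]) @ vt[:n_components] + mu
        delta = np.max(np.abs(x[missing] - recon[missing]))
        x[missing] = recon[missing]
        if delta < tol:
            break
    x[missing] = np.clip(x[missing], 0.0, 1.0)
    return pd.DataFrame(x, index=table.index, columns=table.columns)


def _qn_one_group(block: np.ndarray) -> np.ndarray:
    """Classic quantile normalization across the columns of one group."""
    n, _ = block.shape
    reference = np.sort(block, axis=0).mean(axis=1)
    out = np.empty_like(block)
    for j in range(block.shape[1]):
        order = np.argsort(block[:, j], kind="stable")
        sorted_vals = block[order, j]
        normalized = np.empty(n)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            normalized[i : k + 1] = reference[i : k + 1].mean()
            i = k + 1
        out[order, j] = normalized
    return out


def quantile_normalize_by_group(table: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Quantile-normalize the method columns within each cohort group.

    Different purity callers have systematically different value
    distributions; quantile normalization puts them on a common scale.
    Within each group the reference distribution is the mean of the
    per-method sorted value vectors, and each method's values are replaced
    by the reference value at their rank (tied values get the mean of the
    tied reference positions), preserving each method's within-group
    ordering.  Requires a complete table (run after imputation).  A group of
    a single sample is passed through unchanged with a warning.
    """
    _validate_table(table)
    if table.isna().any().any():
        raise ValueError("quantile normalization requires a complete table; impute first")
    groups = groups.reindex(table.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    out = table.copy()
    for label, idx in groups.groupby(groups).groups.items():
        if len(idx) < 2:
            warnings.warn(
                f"group {label!r} has a single sample; passed through unnormalized",
                stacklevel=2,
            )
            continue
        out.loc[idx] = _qn_one_group(table.loc[idx].to_numpy(dtype=float))
    return out


def consensus(table: pd.DataFrame, reducer: str = "median") -> pd.Series:
    """Reduce the methods of a flagged/imputed/normalized table per sample.

    The default reducer is the sample-wise median; ``"mean"`` is available.
    The result is clipped to [0, 1] and named ``"purity"``.
    """
    _validate_table(table)
    if reducer == "median":
        values = table.median(axis=1)
    elif reducer == "mean":
        values = table.mean(axis=1)
    else:
        raise ValueError(f"unknown reducer {reducer!r}; use 'median' or 'mean'")
    return values.clip(0.0, 1.0).rename("purity")


def build_consensus(
    table: pd.DataFrame,
    groups: pd.Series,
    low: float = 0.1,
    high: float = 0.98,
    n_components: int = 2,
    tol: float = 1e-6,
    max_iter: int = 100,
    reducer: str = "median",
    per_group_impute: bool = False,
) -> pd.Series:
    """Full consensus pipeline: flag -> impute -> normalize -> reduce.

    This is the only supported composition order.  ``per_group_impute`` runs
    the iterative-PCA imputation separately within each cohort group instead
    of across the whole cohort.
    """
    flagged = flag_extremes(table, low=low, high=high)
    flagged = drop_empty_samples(flagged)
    if per_group_impute:
        g = groups.reindex(flagged.index)
        parts = [
            impute_missing_ipca(flagged.loc[idx], n_components=n_components, tol=tol, max_iter=max_iter)
            for _, idx in g.groupby(g).groups.items()
        ]
        imputed = pd.concat(parts).reindex(flagged.index).dropna(how="all")
    else:
        imputed = impute_missing_ipca(flagged, n_components=n_components, tol=tol, max_iter=max_iter)
    normalized = quantile_normalize_by_group(imputed, groups.reindex(imputed.index))
    return consensus(normalized, reducer=reducer)
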