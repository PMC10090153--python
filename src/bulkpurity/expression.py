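"""Expression matrices: validation, gene filtering, and the rank-percentile transform.

Matrices are plain :class:`pandas.DataFrame` objects with samples in rows and
genes in columns, holding non-negative linear-scale values (TPM, FPKM or
counts).  Missing entries are NaN.  The rank-percentile transform replaces
each sample's values by their ascending rank divided by the number of ranked
genes, which removes any per-sample scale and makes downstream models
portable across platforms and units.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = ["validate_expression", "rank_percentile", "filter_genes", "stratified_split"]


def validate_expression(expr: pd.DataFrame, *, allow_missing: bool = True) -> None:
    """Check an expression matrix: unique ids, non-negative finite values.

    Parameters
    ----------
    expr
        Samples x genes matrix in linear units.
    allow_missing
        Whether NaN entries are tolerated (they are, everywhere ranking can
        skip them; set False for contexts that require a complete matrix).
    """
    if expr.index.has_duplicates:
        dup = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dup[:5]}")
    if expr.columns.has_duplicates:
        dup = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dup[:5]}")
    values = expr.to_numpy(dtype=float)
    if np.isinf(values).any():
        raise ValueError("expression matrix contains infinite values")
    if not allow_missing and np.isnan(values).any():
        raise ValueError("expression matrix contains missing values")
    with np.errstate(invalid="ignore"):
        if (values < 0).any():
            raise ValueError("expression values must be non-negative")


def rank_percentile(expr: pd.DataFrame, universe: Sequence[str]) -> pd.DataFrame:
    """Sample-wise rank-percentile transform over a fixed gene universe.

    For each sample independently, the genes shared between ``expr`` and
    ``universe`` are ranked ascending with the lowest possible rank for tied
    groups (min-rank), and each rank is divided by the number of genes ranked
    in that sample.  E.g. the values ``[0, 0, 1, 5, 100]`` over a five-gene
    universe rank as ``[1, 1, 3, 4, 5]`` and map to percentiles
    ``[0.2, 0.2, 0.6, 0.8, 1.0]``.

    Genes outside the universe are dropped before ranking; universe genes
    absent from ``expr`` contribute nothing (they are imputed downstream).
    NaN cells are skipped and stay NaN; the percentile denominator is the
    per-sample count of observed universe genes, so a complete sample's
    unique maximum maps to exactly 1.

    Returns
    -------
    pandas.DataFrame
        Samples x (universe ∩ expr genes), values in (0, 1].
    """
    universe = list(dict.fromkeys(str(g).strip() for g in universe))
    if not universe:
        raise ValueError("gene universe is empty")
    cols = expr.columns.astype(str).str.strip()
    present = [g for g in universe if g in set(cols)]
    if not present:
        raise ValueError("no universe genes present in the expression matrix")
    sub = expr.copy()
    sub.columns = cols
    sub = sub[present]
    validate_expression(sub)
    ranks = sub.rank(axis=1, method="min", na_option="keep")
    n_observed = sub.notna().sum(axis=1)
    if (n_observed == 0).any():
        empty = sub.index[n_observed == 0].tolist()
        raise ValueError(f"samples with no observed universe genes: {empty[:5]}")
    return ranks.div(n_observed, axis=0)


def filter_genes(
    expr: pd.DataFrame,
    groups: pd.Series,
    expr_threshold: float = 1.0,
    var_threshold: float = 1.0,
    allow_list: Sequence[str] | None = None,
) -> list[str]:
    """Select the gene universe by removing uninformative genes.

    A gene is removed only if it has both low median expression
    (< ``expr_threshold``) and low variance (< ``var_threshold``) in *every*
    cohort group; it is kept as soon as one group passes either criterion.
    An optional ``allow_list`` (e.g. autosomal protein-coding genes) is
    applied first.

    Groups with fewer than two samples have undefined variance and are
    treated as non-qualifying, with a warning.

    Returns the kept gene ids in the matrix's column order.
    """
    if expr_threshold < 0 or var_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    validate_expression(expr)
    groups = groups.reindex(expr.index)
    if groups.isna().any():
        missing = expr.index[groups.isna()].tolist()
        raise ValueError(f"samples without a group label: {missing[:5]}")
    genes = expr.columns
    if allow_list is not None:
        allowed = {str(g).strip() for g in allow_list}
        genes = [g for g in genes if str(g).strip() in allowed]
    keep = pd.Series(False, index=genes)
    for label, idx in groups.groupby(groups).groups.items():
        block = expr.loc[idx, genes]
        if len(idx) < 2:
            warnings.warn(
                f"group {label!r} has fewer than 2 samples; "
                "variance undefined, group ignored by the gene filter",
                stacklevel=2,
            )
            continue
        med = block.median(axis=0)
        var = block.var(axis=0, ddof=1)
        keep |= (med >= expr_threshold) | (var >= var_threshold)
    return [g for g in genes if keep[g]]


def stratified_split(
    purity: pd.Series,
    groups: pd.Series,
    train_fraction: float = 0.8,
    seed: int = 0,
    n_strata: int = 10,
) -> tuple[list, list]:
    """Purity-decile-stratified train/test split within each cohort group.

    Within each group, samples are binned into up to ``n_strata`` purity
    quantile strata and assigned at random to train or test at
    ``train_fraction``, so both splits carry comparable cancer-type and
    purity distributions.  Groups smaller than ``n_strata`` fall back to a
    simple random split, with a warning.  Deterministic given ``seed``.

    Returns
    -------
    (train_ids, test_ids)
        Disjoint, exhaustive sample-id lists.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    purity, groups = purity.align(groups, join="inner")
    if purity.isna().any() or groups.isna().any():
        raise ValueError("every sample needs both a purity label and a group")
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for label in pd.unique(groups):
        ids = groups.index[groups == label]
        p = purity.loc[ids]
        if len(ids) < n_strata:
            warnings.warn(
                f"group {label!r} smaller than {n_strata} strata; "
                "using a simple random split",
                stacklevel=2,
            )
            strata = pd.Series(0, index=ids)
        else:
            strata = pd.qcut(p.rank(method="first"), q=n_strata, labels=False, duplicates="drop")
        for _, stratum_ids in strata.groupby(strata).groups.items():
            members = np.asarray(stratum_ids, dtype=object)
            perm = rng.permutation(len(members))
            n_train = int(round(train_fraction * len(members)))
            train_ids.extend(members[perm[:n_train]].tolist())
            test_ids.extend(members[perm[n_train:]].tolist())
    return train_ids, test_ids
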