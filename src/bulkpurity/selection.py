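"""Two-step lasso feature selection on rank-percentile features.

Step 1 finds genes predictive in both the low- and the high-purity regime:
two lasso models are fitted with leave-one-cancer-type-out cross-validation,
one on samples excluding each group's top 20% purity tail and one excluding
the bottom 20%, and their selected gene sets are intersected.  Step 2
rebalances the cohort (an equal, purity-distribution-preserving subsample
from every cancer type) and repeats the grouped-CV lasso restricted to the
step-1 genes, so the final set is equally relevant to all cancer types
rather than dominated by the largest cohorts.

All fits are plain coordinate-descent lasso; regularization is chosen by
minimal mean squared error across the leave-one-group-out folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path

__all__ = [
    "SelectionConfig",
    "FeatureSet",
    "range_restricted_lasso",
    "step1_intersect",
    "balanced_subsample",
    "step2_refine",
    "select_features",
    "mean_group_correlation",
]

#: coefficients below this magnitude count as zero (solver noise)
COEF_TOL = 1e-10


@dataclass
class SelectionConfig:
    """Parameters of the two-step selection.

    trim_fraction
        Per-group purity tail removed in the range-restricted fits
        (default 0.20, i.e. top/bottom 20%).
    balance_size
        Samples drawn per cancer type in step 2; ``"auto"`` uses the
        smallest group's size.
    alpha_grid
        Lasso penalties to scan; ``None`` derives 50 log-spaced values over
        four decades below the data's critical (all-zero) penalty.
    n_alphas, alpha_decades
        Shape of the derived grid when ``alpha_grid`` is None.
    per_group_trim
        Compute purity tails within each cancer type (default) rather than
        over the pooled cohort.
    seed
        Seed for the balanced subsampling draws.
    """

    trim_fraction: float = 0.20
    balance_size: int | str = "auto"
    alpha_grid: np.ndarray | None = None
    n_alphas: int = 50
    alpha_decades: float = 4.0
    per_group_trim: bool = True
    seed: int = 0
    max_iter: int = 20000

    def __post_init__(self) -> None:
        if not 0 < self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in (0, 0.5)")
        if self.balance_size != "auto" and int(self.balance_size) < 10:
            raise ValueError("balance_size must be >= 10")


@dataclass
class FeatureSet:
    """Selected genes plus their mean per-group purity-expression correlation."""

    genes: list[str]
    correlations: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    n_step1: int | None = None
    n_step2: int | None = None

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("feature set is empty")
        if len(self.correlations):
            c = self.correlations.dropna()
            if ((c < -1 - 1e-9) | (c > 1 + 1e-9)).any():
                raise ValueError("correlations outside [-1, 1]")

    def __len__(self) -> int:
        return len(self.genes)


def _default_alpha_grid(x: np.ndarray, y: np.ndarray, n_alphas: int, decades: float) -> np.ndarray:
    n = x.shape[0]
    alpha_max = np.max(np.abs(x.T @ (y - y.mean()))) / n
    if alpha_max <= 0:
        alpha_max = 1.0
    hi = np.log10(alpha_max)
    return np.logspace(hi, hi - decades, n_alphas)


def _grouped_cv_lasso(
    x: np.ndarray,
    y: np.ndarray,
    fold_ids: np.ndarray,
    alphas: np.ndarray,
    max_iter: int,
    train_subsets: dict | None = None,
) -> tuple[float, np.ndarray]:
    """Leave-one-group-out CV over a lasso path; returns (best alpha, CV MSE per alpha).

    ``train_subsets`` optionally maps each held-out fold to the row indices
    to train on (used for balanced subsampling); default is all other rows.
    """
    folds = pd.unique(fold_ids)
    if len(folds) < 2:
        raise ValueError("group CV requires >= 2 cancer types")
    alphas = np.sort(np.asarray(alphas, dtype=float))[::-1]
    mse = np.empty((len(folds), len(alphas)))
    for i, fold in enumerate(folds):
        test = fold_ids == fold
        if train_subsets is not None:
            train_idx = train_subsets[fold]
        else:
            train_idx = np.nonzero(~test)[0]
        xt, yt = x[train_idx], y[train_idx]
        xm, ym = xt.mean(axis=0), yt.mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence at tiny alphas
            _, coefs, _ = lasso_path(xt - xm, yt - ym, alphas=alphas, max_iter=max_iter)
        pred = (x[test] - xm) @ coefs + ym  # (n_test, n_alphas)
        mse[i] = ((pred - y[test, None]) ** 2).mean(axis=0)
    mean_mse = mse.mean(axis=0)
    best = float(alphas[int(np.argmin(mean_mse))])  # ties break to sparser fit
    return best, mean_mse


def _fit_lasso(x: np.ndarray, y: np.ndarray, alpha: float, max_iter: int) -> Lasso:
    model = Lasso(alpha=alpha, fit_intercept=True, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, y)
    return model


def _trim_tail(
    purity: pd.Series, groups: pd.Series, exclude: str, fraction: float, per_group: bool
) -> pd.Index:
    """Sample ids kept after dropping one purity tail (per group by default)."""
    if exclude not in ("top", "bottom"):
        raise ValueError("exclude must be 'top' or 'bottom'")
    keep: list = []
    blocks = groups.groupby(groups).groups.items() if per_group else [("all", purity.index)]
    for _, idx in blocks:
        p = purity.loc[idx]
        n_drop = int(round(fraction * len(p)))
        order = np.argsort(p.to_numpy(), kind="stable")
        kept = order[:-n_drop] if exclude == "top" and n_drop else order
        if exclude == "bottom" and n_drop:
            kept = order[n_drop:]
        keep.extend(np.asarray(p.index)[kept].tolist())
    return pd.Index(keep)


def range_restricted_lasso(
    ranks: pd.DataFrame,
    purity: pd.Series,
    groups: pd.Series,
    exclude: str,
    cfg: SelectionConfig | None = None,
) -> list[str]:
    """Lasso selection after excluding one purity tail.

    Drops each cancer type's ``trim_fraction`` highest (``exclude="top"``) or
    lowest (``exclude="bottom"``) purity samples, then fits a lasso of purity
    on the rank-percentile features with leave-one-cancer-type-out CV over the
    penalty grid and refits at the best penalty on all retained samples.
    Returns the genes with non-zero coefficients.
    """
    cfg = cfg or SelectionConfig()
    purity = purity.reindex(ranks.index)
    groups = groups.reindex(ranks.index)
    kept = _trim_tail(purity, groups, exclude, cfg.trim_fraction, cfg.per_group_trim)
    x = ranks.loc[kept].to_numpy(dtype=float)
    y = purity.loc[kept].to_numpy(dtype=float)
    fold_ids = groups.loc[kept].to_numpy()
    alphas = cfg.alpha_grid
    if alphas is None:
        alphas = _default_alpha_grid(x, y, cfg.n_alphas, cfg.alpha_decades)
    best_alpha, _ = _grouped_cv_lasso(x, y, fold_ids, alphas, cfg.max_iter)
    model = _fit_lasso(x, y, best_alpha, cfg.max_iter)
    selected = np.abs(model.coef_) > COEF_TOL
    return [g for g, s in zip(ranks.columns, selected) if s]


def step1_intersect(
    ranks: pd.DataFrame,
    purity: pd.Series,
    groups: pd.Series,
    cfg: SelectionConfig | None = None,
) -> list[str]:
    """Intersect the two range-restricted lasso selections.

    Genes must survive both the fit excluding the high-purity tail and the
    fit excluding the low-purity tail, i.e. be informative over the whole
    purity range.
    """
    cfg = cfg or SelectionConfig()
    no_top = range_restricted_lasso(ranks, purity, groups, "top", cfg)
    no_bottom = range_restricted_lasso(ranks, purity, groups, "bottom", cfg)
    inter = set(no_top) & set(no_bottom)
    if not inter:
        raise ValueError(
            "empty intersection of range-restricted selections "
            f"(|exclude-top set| = {len(no_top)}, |exclude-bottom set| = {len(no_bottom)})"
        )
    return [g for g in ranks.columns if g in inter]


def balanced_subsample(
    purity: pd.Series,
    groups: pd.Series,
    balance_size: int,
    seed: int,
    n_strata: int = 10,
) -> list:
    """Draw ``balance_size`` samples from every group, preserving purity shape.

    Within each group, samples are binned into purity deciles and the draw is
    allocated proportionally to stratum sizes (largest-remainder rounding),
    then sampled without replacement.  Deterministic given ``seed``.
    """
    purity, groups = purity.align(groups, join="inner")
    sizes = groups.value_counts()
    if balance_size > sizes.min():
        raise ValueError(
            f"balance_size {balance_size} exceeds smallest group size {sizes.min()}"
        )
    rng = np.random.default_rng(seed)
    chosen: list = []
    for label in pd.unique(groups):
        ids = groups.index[groups == label]
        if len(ids) == balance_size:
            chosen.extend(ids.tolist())
            continue
        p = purity.loc[ids]
        strata = pd.qcut(p.rank(method="first"), q=min(n_strata, len(ids)), labels=False, duplicates="drop")
        counts = strata.value_counts().sort_index()
        quota = balance_size * counts / counts.sum()
        base = np.floor(quota).astype(int)
        remainder = balance_size - int(base.sum())
        order = np.argsort(-(quota - base).to_numpy(), kind="stable")
        alloc = base.to_numpy().copy()
        alloc[order[:remainder]] += 1
        for stratum_label, n_take in zip(counts.index, alloc):
            members = np.asarray(strata.index[strata == stratum_label], dtype=object)
            pick = rng.choice(len(members), size=n_take, replace=False)
            chosen.extend(members[np.sort(pick)].tolist())
    return chosen


def mean_group_correlation(
    ranks: pd.DataFrame, purity: pd.Series, groups: pd.Series, genes: list[str]
) -> pd.Series:
    """Per-gene Pearson correlation with purity, averaged over cancer types.

    Computed within each group and mean-aggregated; groups where a gene has
    zero variance contribute nothing for that gene.
    """
    purity = purity.reindex(ranks.index)
    groups = groups.reindex(ranks.index)
    per_group = []
    for _, idx in groups.groupby(groups).groups.items():
        x = ranks.loc[idx, genes].to_numpy(dtype=float)
        y = purity.loc[idx].to_numpy(dtype=float)
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc * yc[:, None]).sum(axis=0) / denom
        per_group.append(r)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN genes
        mean_r = np.nanmean(np.vstack(per_group), axis=0)
    return pd.Series(mean_r, index=genes, name="mean_purity_correlation")


def step2_refine(
    ranks: pd.DataFrame,
    purity: pd.Series,
    groups: pd.Series,
    step1_genes: list[str],
    cfg: SelectionConfig | None = None,
) -> FeatureSet:
    """Balanced, grouped-CV lasso refinement of the step-1 genes.

    For every leave-one-cancer-type-out fold, a lasso path is fitted on a
    balanced subsample of the remaining groups and scored on the withheld
    group; the penalty with minimal mean CV error is then refitted on a
    balanced subsample spanning all groups.  Genes with non-zero final
    weights form the :class:`FeatureSet`, annotated with their mean
    per-group purity correlation computed on the full training data.
    """
    if not step1_genes:
        raise ValueError("step1_genes is empty")
    cfg = cfg or SelectionConfig()
    purity = purity.reindex(ranks.index)
    groups = groups.reindex(ranks.index)
    sub = ranks[step1_genes]
    x = sub.to_numpy(dtype=float)
    y = purity.to_numpy(dtype=float)
    fold_ids = groups.to_numpy()
    balance = cfg.balance_size
    if balance == "auto":
        balance = int(groups.value_counts().min())
    rng = np.random.default_rng(cfg.seed)
    folds = pd.unique(fold_ids)
    pos = {sid: i for i, sid in enumerate(sub.index)}
    train_subsets = {}
    for fold in folds:
        other = groups.index[fold_ids != fold]
        sub_ids = balanced_subsample(
            purity.loc[other], groups.loc[other], balance, seed=int(rng.integers(2**31))
        )
        train_subsets[fold] = np.array([pos[s] for s in sub_ids])
    alphas = cfg.alpha_grid
    if alphas is None:
        alphas = _default_alpha_grid(x, y, cfg.n_alphas, cfg.alpha_decades)
    best_alpha, _ = _grouped_cv_lasso(x, y, fold_ids, alphas, cfg.max_iter, train_subsets)
    final_ids = balanced_subsample(purity, groups, balance, seed=int(rng.integers(2**31)))
    final_rows = np.array([pos[s] for s in final_ids])
    model = _fit_lasso(x[final_rows], y[final_rows], best_alpha, cfg.max_iter)
    selected = [g for g, w in zip(step1_genes, model.coef_) if abs(w) > COEF_TOL]
    if not selected:
        raise ValueError("step-2 lasso selected no genes")
    corr = mean_group_correlation(ranks, purity, groups, selected)
    return FeatureSet(
        genes=selected,
        correlations=corr,
        n_step1=len(step1_genes),
        n_step2=len(selected),
    )


def select_features(
    ranks: pd.DataFrame,
    purity: pd.Series,
    groups: pd.Series,
    cfg: SelectionConfig | None = None,
) -> FeatureSet:
    """Run the full two-step selection: range-restricted intersection, then refinement."""
    cfg = cfg or SelectionConfig()
    step1 = step1_intersect(ranks, purity, groups, cfg)
    return step2_refine(ranks, purity, groups, step1, cfg)
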