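"""The purity predictor: training, inference, and specialised training modes.

The final model is deliberately simple — ordinary least squares of consensus
purity on the selected rank-percentile features (the lasso stage already
enforced sparsity, so no penalty is needed here).  Inference on unseen
samples runs three stages: rank-percentile transform over the model's gene
universe, restriction to the feature genes with training-median imputation of
any that are absent, then the linear prediction clipped to [0, 1].

Two additional training modes mirror common benchmarking questions: one
lasso model per cancer type (5-fold CV on the full universe) and
leave-one-cancer-type-out linear models on the fixed feature set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV

from bulkpurity.expression import rank_percentile
from bulkpurity.selection import COEF_TOL, FeatureSet

__all__ = [
    "PurityModel",
    "train",
    "predict",
    "train_per_group",
    "train_leave_one_group_out",
]


@dataclass
class PurityModel:
    """Frozen linear purity predictor.

    Carries everything prediction needs: the ranking universe (so unseen
    samples are ranked exactly as the training data was), the feature genes
    with their weights and intercept, and per-feature training medians (rank
    percentiles) used to impute feature genes missing from a query matrix.
    """

    universe: list[str]
    feature_genes: list[str]
    weights: np.ndarray
    intercept: float
    feature_medians: pd.Series
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.feature_genes):
            raise ValueError("one weight per feature gene required")
        med = self.feature_medians.reindex(self.feature_genes)
        if med.isna().any() or ((med <= 0) | (med > 1)).any():
            raise ValueError("feature medians must be rank percentiles in (0, 1]")
        self.feature_medians = med

    # -- serialization: a single self-describing JSON document ------------
    def to_json(self) -> str:
        doc = {
            "format": "bulkpurity-model",
            "version": 1,
            "universe": list(self.universe),
            "feature_genes": list(self.feature_genes),
            "weights": self.weights.tolist(),
            "intercept": float(self.intercept),
            "feature_medians": self.feature_medians.tolist(),
            "metadata": self.metadata,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PurityModel":
        doc = json.loads(text)
        if doc.get("format") != "bulkpurity-model":
            raise ValueError("not a bulkpurity model file")
        return cls(
            universe=doc["universe"],
            feature_genes=doc["feature_genes"],
            weights=np.array(doc["weights"], dtype=float),
            intercept=float(doc["intercept"]),
            feature_medians=pd.Series(doc["feature_medians"], index=doc["feature_genes"]),
            metadata=doc.get("metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "PurityModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def train(
    ranks: pd.DataFrame,
    purity: pd.Series,
    features: FeatureSet | list[str],
    universe: list[str] | None = None,
    metadata: dict | None = None,
) -> PurityModel:
    """Fit the final linear model on rank-percentile features.

    Ordinary least squares of purity on the feature columns of ``ranks``
    (minimum-norm solution, with a warning, if the design is rank
    deficient).  Per-feature medians of the training rank percentiles are
    stored for prediction-time imputation.

    ``universe`` defaults to all columns of ``ranks``; pass the training
    gene universe explicitly when ``ranks`` was already restricted.
    """
    genes = features.genes if isinstance(features, FeatureSet) else list(features)
    missing = [g for g in genes if g not in ranks.columns]
    if missing:
        raise ValueError(f"feature genes absent from rank matrix: {missing[:5]}")
    x = ranks[genes].to_numpy(dtype=float)
    y = purity.reindex(ranks.index).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("every training sample needs a purity label")
    if ((y < 0) | (y > 1)).any():
        raise ValueError("purity labels must lie in [0, 1]")
    if x.shape[0] < x.shape[1] + 1:
        warnings.warn(
            f"only {x.shape[0]} samples for {x.shape[1]} features; fit may be unstable",
            stacklevel=2,
        )
    design = np.column_stack([x, np.ones(len(x))])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient design; using minimum-norm least squares", stacklevel=2)
    medians = ranks[genes].median(axis=0)
    return PurityModel(
        universe=list(universe) if universe is not None else list(ranks.columns),
        feature_genes=genes,
        weights=coef[:-1],
        intercept=float(coef[-1]),
        feature_medians=medians,
        metadata=metadata or {},
    )


def predict(model: PurityModel, expr: pd.DataFrame) -> pd.DataFrame:
    """Predict purity for unseen samples from linear-scale expression.

    Three stages: (1) rank-percentile transform of the genes shared with the
    model universe; (2) restriction to the feature genes, imputing any
    feature absent from the input (or NaN in a sample) with its stored
    training median; (3) linear prediction, clipped to [0, 1].

    Returns a DataFrame indexed by sample with columns ``purity`` and
    ``n_imputed_features``.  A warning is raised if more than half the
    features had to be imputed.
    """
    rp = rank_percentile(expr, model.universe)
    x = pd.DataFrame(index=rp.index, columns=model.feature_genes, dtype=float)
    present = [g for g in model.feature_genes if g in rp.columns]
    x[present] = rp[present]
    imputed_mask = x.isna()
    n_imputed = imputed_mask.sum(axis=1)
    for g in model.feature_genes:
        if imputed_mask[g].any():
            x[g] = x[g].fillna(model.feature_medians[g])
    if (n_imputed > len(model.feature_genes) / 2).any():
        worst = int(n_imputed.max())
        warnings.warn(
            f"more than half of the feature genes imputed for some samples "
            f"(worst: {worst}/{len(model.feature_genes)}); predictions may be unreliable",
            stacklevel=2,
        )
    raw = x.to_numpy(dtype=float) @ model.weights + model.intercept
    return pd.DataFrame(
        {"purity": np.clip(raw, 0.0, 1.0), "n_imputed_features": n_imputed},
        index=rp.index,
    )


def train_per_group(
    ranks: pd.DataFrame,
    purity: pd.Series,
    groups: pd.Series,
    universe: list[str] | None = None,
    seed: int = 0,
    min_group_size: int = 20,
) -> dict[str, PurityModel]:
    """One cancer-type-specific lasso model per group.

    Each model is a lasso on that group's samples over the full gene
    universe, with 5-fold cross-validation choosing the penalty.  Intended as
    the baseline the pan-cancer model is compared against.
    """
    purity = purity.reindex(ranks.index)
    groups = groups.reindex(ranks.index)
    models: dict[str, PurityModel] = {}
    for label, idx in groups.groupby(groups).groups.items():
        if len(idx) < min_group_size:
            warnings.warn(
                f"group {label!r} has only {len(idx)} samples; model may be unstable",
                stacklevel=2,
            )
        x = ranks.loc[idx].to_numpy(dtype=float)
        y = purity.loc[idx].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lasso = LassoCV(cv=5, random_state=seed, max_iter=20000).fit(x, y)
        nonzero = np.abs(lasso.coef_) > COEF_TOL
        if not nonzero.any():  # all shrunk away: constant model at the label mean
            genes = [ranks.columns[0]]
            weights = np.array([0.0])
            intercept = float(y.mean())
        else:
            genes = [g for g, nz in zip(ranks.columns, nonzero) if nz]
            weights = lasso.coef_[nonzero]
            intercept = float(lasso.intercept_)
        models[label] = PurityModel(
            universe=list(universe) if universe is not None else list(ranks.columns),
            feature_genes=genes,
            weights=weights,
            intercept=intercept,
            feature_medians=ranks.loc[idx, genes].median(axis=0),
            metadata={"mode": "per_group", "group": str(label), "seed": seed},
        )
    return models


def train_leave_one_group_out(
    ranks: pd.DataFrame,
    purity: pd.Series,
    groups: pd.Series,
    features: FeatureSet | list[str],
    universe: list[str] | None = None,
) -> dict[str, PurityModel]:
    """One linear model per group, trained with that group withheld.

    Evaluating model ``g`` on group ``g`` measures generalization to cancer
    types absent from training.  Requires at least two groups.
    """
    groups = groups.reindex(ranks.index)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("leave-one-group-out requires >= 2 groups")
    models: dict[str, PurityModel] = {}
    for label in labels:
        keep = groups.index[groups != label]
        models[label] = train(
            ranks.loc[keep],
            purity,
            features,
            universe=universe,
            metadata={"mode": "leave_one_group_out", "withheld_group": str(label)},
        )
    return models
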