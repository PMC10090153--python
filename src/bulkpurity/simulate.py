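"""Synthetic cohorts: bulk mixtures, pseudo-genomics purity calls, single cells.

The generator implements the linear mixing model the purity method assumes:
every bulk sample of cancer type ``g`` is ``p * C_g + (1 - p) * S_g`` — a
purity-weighted blend of that type's cancer reference profile ``C_g`` and
stroma reference ``S_g`` — times multiplicative log-normal measurement noise.
A fixed subset of "informative" marker genes carries a cancer-vs-stroma
fold change with a consistent sign across all cancer types (half up in
cancer, half up in stroma); the remaining genes get independent per-type
offsets, so they can correlate with purity within one type but not
consistently across types.  Per-type purity distributions are Beta with
means spanning the range seen across solid tumor cohorts, making the types
imbalanced on purpose.

Companion generators emulate (i) a panel of noisy DNA-based purity
estimators with per-method bias, extreme-value corruptions and missing
entries, and (ii) labeled single cells drawn around the cancer or stroma
reference with dropout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticCohort",
    "SyntheticSingleCell",
    "make_cohort",
    "make_purity_estimates",
    "make_single_cell",
]


@dataclass
class SyntheticCohort:
    """A generated bulk cohort with full ground truth."""

    expr: pd.DataFrame  # samples x genes, linear units
    true_purity: pd.Series
    groups: pd.Series
    informative_genes: pd.Series  # gene -> +1 (cancer-up) / -1 (stroma-up)
    cancer_profiles: pd.DataFrame  # groups x genes reference C_g
    stroma_profiles: pd.DataFrame  # groups x genes reference S_g
    config: dict = field(default_factory=dict)


@dataclass
class SyntheticSingleCell:
    """A generated cells x genes matrix with malignant / non-malignant labels."""

    expr: pd.DataFrame
    cell_labels: pd.Series  # "malignant" / "non_malignant"
    config: dict = field(default_factory=dict)


def make_cohort(
    n_groups: int = 8,
    samples_per_group: int = 200,
    n_genes: int = 1000,
    n_informative: int = 60,
    purity_range: tuple[float, float] = (0.0, 1.0),
    noise_sd: float = 0.1,
    group_effect_sd: float = 0.3,
    seed: int | None = None,
    informative_log_offset: float = 2.0,
    purity_mean_range: tuple[float, float] = (0.35, 0.72),
    purity_concentration: float = 8.0,
    noise_model: str = "lognormal",
) -> SyntheticCohort:
    """Generate a multi-cancer-type bulk cohort of linear cancer/stroma mixtures.

    Parameters
    ----------
    n_groups, samples_per_group, n_genes, n_informative
        Cohort shape; ``n_informative`` is split evenly into cancer-up and
        stroma-up marker genes.
    purity_range
        True purities are clipped into this interval; a degenerate single
        point is allowed (with a warning) for edge-case testing.
    noise_sd
        SD of the log-normal (or Gaussian, see ``noise_model``) measurement
        noise applied to each expression value.
    group_effect_sd
        SD of the per-type log cancer-vs-stroma offset of non-informative
        genes — confounders that track purity inside a type but not across
        types.
    informative_log_offset
        Log-scale cancer-vs-stroma separation of the marker genes, identical
        in every type (about 7.4-fold at the default 2.0).
    purity_mean_range, purity_concentration
        Per-type Beta purity distributions: means are evenly spaced over
        ``purity_mean_range`` and shaped by the concentration parameter.
    noise_model
        ``"lognormal"`` (multiplicative, default) or ``"gaussian"``
        (additive, truncated at zero).
    """
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    if n_informative > n_genes:
        raise ValueError("n_informative cannot exceed n_genes")
    lo, hi = purity_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError("purity_range must be within [0, 1]")
    if lo == hi:
        warnings.warn(
            "degenerate single-point purity range: purity-recovery metrics are undefined",
            stacklevel=2,
        )
    if noise_model not in ("lognormal", "gaussian"):
        raise ValueError("noise_model must be 'lognormal' or 'gaussian'")

    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    group_names = [f"CT{g + 1}" for g in range(n_groups)]

    # marker genes: first half cancer-up (+1), second half stroma-up (-1)
    n_up = n_informative // 2
    signs = np.zeros(n_genes)
    signs[:n_up] = 1.0
    signs[n_up:n_informative] = -1.0
    informative = pd.Series(
        signs[:n_informative].astype(int), index=genes[:n_informative], name="sign"
    )

    base = rng.lognormal(mean=1.0, sigma=1.0, size=n_genes)
    means = np.linspace(purity_mean_range[0], purity_mean_range[1], n_groups)

    cancer_profiles = np.empty((n_groups, n_genes))
    stroma_profiles = np.empty((n_groups, n_genes))
    expr_blocks, purity_blocks, group_blocks, sample_ids = [], [], [], []
    for g, name in enumerate(group_names):
        group_base = base * np.exp(rng.normal(0.0, 0.1, n_genes))
        offset = signs * informative_log_offset
        offset = offset + (signs == 0) * rng.normal(0.0, group_effect_sd, n_genes)
        cancer = group_base * np.exp(offset / 2.0)
        stroma = group_base * np.exp(-offset / 2.0)
        cancer_profiles[g] = cancer
        stroma_profiles[g] = stroma

        m = means[g]
        if lo == hi:
            p = np.full(samples_per_group, lo)
        else:
            p = rng.beta(m * purity_concentration, (1 - m) * purity_concentration, samples_per_group)
            p = np.clip(p, lo, hi)
        mix = p[:, None] * cancer[None, :] + (1 - p)[:, None] * stroma[None, :]
        if noise_sd > 0:
            if noise_model == "lognormal":
                mix = mix * np.exp(rng.normal(0.0, noise_sd, mix.shape))
            else:
                mix = np.maximum(mix + rng.normal(0.0, noise_sd, mix.shape), 0.0)
        expr_blocks.append(mix)
        purity_blocks.append(p)
        group_blocks.extend([name] * samples_per_group)
        sample_ids.extend(f"{name}_S{i:04d}" for i in range(samples_per_group))

    expr = pd.DataFrame(np.vstack(expr_blocks), index=sample_ids, columns=genes)
    config = {
        "n_groups": n_groups,
        "samples_per_group": samples_per_group,
        "n_genes": n_genes,
        "n_informative": n_informative,
        "purity_range": list(purity_range),
        "noise_sd": noise_sd,
        "group_effect_sd": group_effect_sd,
        "informative_log_offset": informative_log_offset,
        "purity_mean_range": list(purity_mean_range),
        "purity_concentration": purity_concentration,
        "noise_model": noise_model,
        "seed": seed,
    }
    return SyntheticCohort(
        expr=expr,
        true_purity=pd.Series(np.concatenate(purity_blocks), index=sample_ids, name="purity"),
        groups=pd.Series(group_blocks, index=sample_ids, name="group"),
        informative_genes=informative,
        cancer_profiles=pd.DataFrame(cancer_profiles, index=group_names, columns=genes),
        stroma_profiles=pd.DataFrame(stroma_profiles, index=group_names, columns=genes),
        config=config,
    )


def make_purity_estimates(
    cohort: SyntheticCohort,
    n_methods: int = 4,
    method_noise_sd: float = 0.08,
    method_bias_sd: float = 0.03,
    extreme_corruption_rate: float = 0.05,
    missing_rate: float = 0.03,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emulate a panel of noisy DNA-based purity estimators.

    Each method reports ``clip(true_purity + bias_m + noise, 0, 1)`` with a
    per-method bias; a fraction of entries is corrupted to extreme values
    (drawn below 0.1 or above 0.98, the failure mode the flagging step
    targets) and another fraction set missing.

    Returns
    -------
    (table, corrupted)
        ``table``: samples x methods DataFrame with NaN for missing cells.
        ``corrupted``: same-shape boolean DataFrame marking injected
        corruptions, for test assertions.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    if n_methods < 1:
        raise ValueError("need at least one method")
    rng = np.random.default_rng(seed)
    p = cohort.true_purity.to_numpy()
    n = len(p)
    methods = [f"method_{chr(ord('A') + m)}" for m in range(n_methods)]
    bias = rng.normal(0.0, method_bias_sd, n_methods)
    values = np.clip(
        p[:, None] + bias[None, :] + rng.normal(0.0, method_noise_sd, (n, n_methods)), 0.0, 1.0
    )
    corrupted = rng.random((n, n_methods)) < extreme_corruption_rate
    n_corrupt = int(corrupted.sum())
    if n_corrupt:
        low_side = rng.random(n_corrupt) < 0.5
        extremes = np.where(
            low_side, rng.uniform(0.0, 0.1, n_corrupt), rng.uniform(0.98, 1.0, n_corrupt)
        )
        values[corrupted] = extremes
    missing = rng.random((n, n_methods)) < missing_rate
    values[missing] = np.nan
    corrupted = corrupted & ~missing
    index = cohort.true_purity.index
    return (
        pd.DataFrame(values, index=index, columns=methods),
        pd.DataFrame(corrupted, index=index, columns=methods),
    )


def make_single_cell(
    cohort: SyntheticCohort,
    n_malignant: int = 1500,
    n_nonmalignant: int = 1000,
    dropout_rate: float = 0.6,
    seed: int | None = None,
    group: str | None = None,
    cell_noise_sd: float = 0.5,
) -> SyntheticSingleCell:
    """Generate labeled single cells around a cohort group's reference profiles.

    Malignant cells are log-normal draws around the group's cancer reference
    ``C_g``, non-malignant cells around the stroma reference ``S_g``, each
    value then zeroed with probability ``dropout_rate`` — a crude but
    sufficient stand-in for the sparsity of droplet single-cell data.  The
    gene set is identical to the cohort's.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    if min(n_malignant, n_nonmalignant) < 50:
        raise ValueError("need at least 50 cells per class")
    if dropout_rate >= 1.0:
        warnings.warn("dropout_rate 1.0 yields an all-zero matrix", stacklevel=2)
    rng = np.random.default_rng(seed)
    if group is None:
        group = cohort.cancer_profiles.index[0]
    cancer = cohort.cancer_profiles.loc[group].to_numpy()
    stroma = cohort.stroma_profiles.loc[group].to_numpy()

    def _draw(reference: np.ndarray, n_cells: int) -> np.ndarray:
        x = reference[None, :] * np.exp(rng.normal(0.0, cell_noise_sd, (n_cells, len(reference))))
        keep = rng.random(x.shape) >= dropout_rate
        return x * keep

    mal = _draw(cancer, n_malignant)
    non = _draw(stroma, n_nonmalignant)
    cells = [f"MAL_{i:04d}" for i in range(n_malignant)] + [
        f"NON_{i:04d}" for i in range(n_nonmalignant)
    ]
    labels = ["malignant"] * n_malignant + ["non_malignant"] * n_nonmalignant
    return SyntheticSingleCell(
        expr=pd.DataFrame(np.vstack([mal, non]), index=cells, columns=cohort.expr.columns),
        cell_labels=pd.Series(labels, index=cells, name="label"),
        config={
            "n_malignant": n_malignant,
            "n_nonmalignant": n_nonmalignant,
            "dropout_rate": dropout_rate,
            "cell_noise_sd": cell_noise_sd,
            "group": group,
            "seed": seed,
        },
    )
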