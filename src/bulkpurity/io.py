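"""Readers and writers for the package's plain-text formats.

Expression matrices, purity tables and annotations travel as delimited text
(TSV by default, CSV by extension, transparent gzip via pandas).  The first
column holds sample identifiers; matrices default to samples in rows and
genes in columns, with ``transpose=True`` for gene-major files.  Empty
fields, ``NA`` and ``NaN`` are read as missing.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_gene_list",
    "write_gene_list",
    "read_column",
    "write_column",
    "read_feature_set",
    "write_feature_set",
]

NA_TOKENS = ["", "NA", "NaN"]


def _sep(path: str | Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


def read_matrix(
    path: str | Path,
    transpose: bool = False,
    alias_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a delimited numeric matrix with identifiers in the first column.

    ``alias_map`` optionally renames gene columns (old id -> canonical id)
    after orientation is fixed; matching elsewhere is exact string identity,
    so symbol drift must be resolved explicitly here.
    """
    df = pd.read_csv(
        path, sep=_sep(path), index_col=0, na_values=NA_TOKENS, keep_default_na=False
    )
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if transpose:
        df = df.T
    if alias_map:
        df = df.rename(columns={str(k).strip(): str(v).strip() for k, v in alias_map.items()})
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, transpose: bool = False) -> None:
    (df.T if transpose else df).to_csv(path, sep=_sep(path))


def read_gene_list(path: str | Path) -> list[str]:
    """One gene identifier per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.writelines(f"{g}\n" for g in genes)


def read_column(path: str | Path, name: str | None = None) -> pd.Series:
    """Read a two-column table (sample id, value) as a Series."""
    df = pd.read_csv(
        path, sep=_sep(path), index_col=0, na_values=NA_TOKENS, keep_default_na=False
    )
    if df.shape[1] < 1:
        raise ValueError(f"{path}: expected at least two columns")
    s = df.iloc[:, 0]
    s.index = s.index.astype(str).str.strip()
    return s.rename(name or s.name)


def write_column(series: pd.Series, path: str | Path) -> None:
    series.rename(series.name or "value").to_csv(path, sep=_sep(path))


def read_feature_set(path: str | Path):
    from bulkpurity.selection import FeatureSet

    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    return FeatureSet(
        genes=df.index.astype(str).tolist(),
        correlations=df["mean_purity_correlation"].astype(float),
    )


def write_feature_set(features, path: str | Path) -> None:
    pd.DataFrame(
        {"mean_purity_correlation": features.correlations.reindex(features.genes)}
    ).rename_axis("gene_id").to_csv(path, sep=_sep(path))
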