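"""Reading and writing the plain-text formats used throughout.

Count/expression matrices are tab-separated text: the first column holds
gene identifiers, the header row holds sample identifiers.  Factor tables
are two-column TSV (sample_id, factor); reference-gene lists are one ID
per line; condition labels are two-column TSV (sample_id, condition).
"""

from __future__ import annotations

import pandas as pd

from .exceptions import DegenerateInputError


def read_matrix(path) -> pd.DataFrame:
    """Read a gene-by-sample expression matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if not df.index.is_unique:
        raise DegenerateInputError(f"duplicate gene IDs in {path}")
    if not df.columns.is_unique:
        raise DegenerateInputError(f"duplicate sample IDs in {path}")
    return df


def write_matrix(df: pd.DataFrame, path, float_format: str | None = None) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format=float_format)


def read_gene_list(path) -> list[str]:
    """Read a plain-text gene ID list, one ID per line, blanks skipped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(ids, path) -> None:
    with open(path, "w") as fh:
        for gid in ids:
            fh.write(f"{gid}\n")


def read_factors(path) -> pd.Series:
    """Read per-sample scaling factors from two-column TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0].astype(float)
    s.index = s.index.astype(str)
    s.name = "factor"
    return s


def write_factors(factors: pd.Series, path) -> None:
    factors.rename("factor").to_csv(path, sep="\t", index_label="sample_id")


def read_conditions(path) -> pd.Series:
    """Read per-sample condition labels from two-column TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0]
    s.index = s.index.astype(str)
    s.name = "condition"
    return s


def write_conditions(conditions: pd.Series, path) -> None:
    conditions.rename("condition").to_csv(path, sep="\t", index_label="sample_id")
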