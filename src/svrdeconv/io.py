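"""Tab-delimited readers and writers.

All tables are TSV with a header row: expression tables are genes x
samples with the gene symbol in the first column; fraction tables are
samples x cell types. Writes are atomic (temp file + rename) so a
failed run never leaves a partial output.
"""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path

import pandas as pd

from .core import ExpressionMatrix

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_fraction_table",
    "write_table",
]

logger = logging.getLogger(__name__)


def read_expression_table(
    path: str | Path,
    scale: str = "linear",
    duplicate_rule: str = "max",
) -> ExpressionMatrix:
    """Read a genes x samples TSV into an :class:`ExpressionMatrix`.

    Duplicate gene symbols — the usual leftover of probe-to-symbol
    collapsed arrays — are merged by ``max`` (default) or ``mean``,
    with a warning. Non-numeric cells and missing values are errors.
    """
    path = Path(path)
    if duplicate_rule not in ("max", "mean"):
        raise ValueError("duplicate_rule must be 'max' or 'mean'")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty expression table") from None
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ]
    if len(non_numeric):
        for col in non_numeric:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                line = df.index.get_loc(bad.index[0]) + 2  # header is line 1
                raise ValueError(
                    f"{path}: non-numeric value in column {col!r} at line {line}"
                )
        df = df.apply(pd.to_numeric)
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        line = df.index.get_loc(gene) + 2
        raise ValueError(f"{path}: missing value at line {line} (gene {gene!r})")
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.warning(
            "%s: %d duplicate gene symbols collapsed by %s", path, n_dup, duplicate_rule
        )
        df = df.groupby(level=0, sort=False).agg(duplicate_rule)
    df.index.name = "gene"
    return ExpressionMatrix(df, scale=scale)


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Write a DataFrame as TSV atomically (temp file in place, then rename)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            df.to_csv(fh, sep="\t", index_label=index_label or df.index.name or "id")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_expression_table(m: ExpressionMatrix, path: str | Path) -> None:
    write_table(m.data, path, index_label="gene")


def read_fraction_table(path: str | Path) -> pd.DataFrame:
    """Read a samples x cell-types fraction TSV (e.g. gated flow percentages)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in fraction table")
    df.index.name = "sample"
    return df.apply(pd.to_numeric)
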