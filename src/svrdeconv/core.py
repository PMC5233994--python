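"""Shared domain types and numeric primitives.

The deconvolution problem is posed as a linear mixture model ``A x = B``:
``A`` is a signature matrix of mean cell-type-specific expression
(genes x cell types), ``B`` a bulk expression profile (genes x samples),
and ``x`` the vector of relative cell-type proportions to be recovered.
Everything here operates on *linear-scale* transcript abundance; log2
inputs are anti-logged at ingestion because the mixture model is linear
in abundance, not in its logarithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SignatureMatrix",
    "FractionVector",
    "CellTypeHierarchy",
    "MAJOR_CELL_TYPES",
    "DEFAULT_CELL_TYPES",
    "DEFAULT_HIERARCHY",
    "quantile_normalize",
    "condition_number",
    "standardize_for_regression",
    "aggregate_fractions",
]

#: The seven major immune lineages used for coarse summaries.
MAJOR_CELL_TYPES = (
    "granulocytes",
    "B cells",
    "T cells CD4",
    "T cells CD8",
    "NK cells",
    "dendritic cells",
    "mono/macrophages",
)

#: Default fine-grained panel of 25 mouse hematopoietic cell types.
#: This is a configurable default, not a contract: every function that
#: consumes cell types takes them from its inputs.
DEFAULT_CELL_TYPES = (
    "Neutrophils",
    "Eosinophils",
    "Basophils",
    "Mast cells resting",
    "Mast cells activated",
    "B cells naive",
    "B cells memory",
    "Plasma cells",
    "T cells CD4 naive",
    "T cells CD4 memory",
    "T cells follicular helper",
    "Tregs",
    "Th17 cells",
    "T cells CD8 naive",
    "T cells CD8 memory",
    "T cells CD8 effector",
    "NK cells resting",
    "NK cells activated",
    "DC immature",
    "DC activated",
    "pDC",
    "Monocytes",
    "Macrophages M0",
    "Macrophages M1",
    "Macrophages M2",
)

_DEFAULT_MAJOR_OF = {
    "Neutrophils": "granulocytes",
    "Eosinophils": "granulocytes",
    "Basophils": "granulocytes",
    "Mast cells resting": "granulocytes",
    "Mast cells activated": "granulocytes",
    "B cells naive": "B cells",
    "B cells memory": "B cells",
    "Plasma cells": "B cells",
    "T cells CD4 naive": "T cells CD4",
    "T cells CD4 memory": "T cells CD4",
    "T cells follicular helper": "T cells CD4",
    "Tregs": "T cells CD4",
    "Th17 cells": "T cells CD4",
    "T cells CD8 naive": "T cells CD8",
    "T cells CD8 memory": "T cells CD8",
    "T cells CD8 effector": "T cells CD8",
    "NK cells resting": "NK cells",
    "NK cells activated": "NK cells",
    "DC immature": "dendritic cells",
    "DC activated": "dendritic cells",
    "pDC": "dendritic cells",
    "Monocytes": "mono/macrophages",
    "Macrophages M0": "mono/macrophages",
    "Macrophages M1": "mono/macrophages",
    "Macrophages M2": "mono/macrophages",
}


def _check_unique(labels, what: str) -> None:
    if len(set(labels)) != len(labels):
        dupes = pd.Index(labels)[pd.Index(labels).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with an explicit scale declaration.

    Parameters
    ----------
    data
        DataFrame indexed by gene symbol with one column per sample.
    scale
        ``"linear"`` or ``"log2"``. Linear values must be non-negative.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(values).any():
            raise ValueError("expression matrix contains missing values")
        if self.scale == "linear" and (values < 0).any():
            raise ValueError("linear-scale expression must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def to_linear(self) -> "ExpressionMatrix":
        """Anti-log to linear scale (2**x); no-op if already linear."""
        if self.scale == "linear":
            return self
        return ExpressionMatrix(np.power(2.0, self.data), scale="linear")

    def to_log2(self, pseudocount: float = 1.0) -> "ExpressionMatrix":
        """Log2-transform (log2(x + pseudocount)); no-op if already log2."""
        if self.scale == "log2":
            return self
        return ExpressionMatrix(np.log2(self.data + pseudocount), scale="log2")


@dataclass
class SignatureMatrix:
    """Genes x cell-types basis of mean linear-scale expression.

    The 2-norm condition number of the basis is computed once and cached;
    a well-conditioned signature is less sensitive to perturbations of the
    mixture profile.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "cell types")
        if self.data.shape[1] < 2:
            raise ValueError("signature needs at least 2 cell types")
        if self.data.shape[0] <= self.data.shape[1]:
            # merging top-n marker lists can legitimately yield a small
            # union; deconvolution itself enforces gene count >= cell types
            warnings.warn(
                f"signature has {self.data.shape[0]} genes for "
                f"{self.data.shape[1]} cell types; deconvolution needs more "
                "genes than cell types",
                stacklevel=2,
            )
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("signature matrix contains missing values")
        if (values.std(axis=0) == 0).any():
            flat = self.data.columns[values.std(axis=0) == 0].tolist()
            raise ValueError(f"signature columns with zero variance: {flat}")
        self._condition_number: float | None = None

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def cell_types(self) -> pd.Index:
        return self.data.columns

    @property
    def condition_number(self) -> float:
        if self._condition_number is None:
            self._condition_number = condition_number(self.data.to_numpy(dtype=float))
        return self._condition_number


@dataclass
class FractionVector:
    """Relative cell-type proportions; sums to 1 unless degenerate.

    ``all_zero`` flags the degenerate case where every regression weight
    was non-positive and no composition could be assigned.
    """

    fractions: pd.Series
    all_zero: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.fractions.index, "cell types")
        values = self.fractions.to_numpy(dtype=float)
        if ((values < -1e-12) | (values > 1 + 1e-12)).any():
            raise ValueError("fractions must lie in [0, 1]")
        if ((values < 0) | (values > 1)).any():  # forgive float round-off only
            values = np.clip(values, 0.0, 1.0)
            self.fractions = pd.Series(values, index=self.fractions.index)
        if self.all_zero:
            if values.any():
                raise ValueError("all_zero fraction vector must be identically 0")
        elif abs(values.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {values.sum():.12f}, expected 1")

    @property
    def cell_types(self) -> pd.Index:
        return self.fractions.index

    def __getitem__(self, cell_type: str) -> float:
        return float(self.fractions[cell_type])


@dataclass
class CellTypeHierarchy:
    """Total single-valued mapping from each fine cell type to its major type."""

    mapping: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_MAJOR_OF))

    def major_of(self, cell_type: str) -> str:
        try:
            return self.mapping[cell_type]
        except KeyError:
            raise KeyError(f"cell type {cell_type!r} has no major-type mapping") from None

    @property
    def majors(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for major in self.mapping.values():
            seen.setdefault(major)
        return tuple(seen)

    def validate_covers(self, cell_types) -> None:
        missing = [ct for ct in cell_types if ct not in self.mapping]
        if missing:
            raise ValueError(f"cell types without major-type mapping: {missing}")


#: Default hierarchy over :data:`DEFAULT_CELL_TYPES`.
DEFAULT_HIERARCHY = CellTypeHierarchy(dict(_DEFAULT_MAJOR_OF))


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column to share the same empirical distribution.

    Each column's order statistics are replaced by the across-sample mean
    of order statistics; within-column ranks are preserved. Ties within a
    column receive the mean of their assigned target quantiles, so the
    result is deterministic and idempotent.
    """
    if m.n_samples < 2:
        warnings.warn(
            "quantile normalization of a single sample is a no-op", stacklevel=2
        )
        return m
    values = m.data.to_numpy(dtype=float)
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = target
        # ties occupy contiguous positions in the sorted order; replace each
        # tied group's values by the mean of the target quantiles it spans
        out[:, j] = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns), scale=m.scale
    )


def condition_number(values: np.ndarray) -> float:
    """2-norm condition number: ratio of largest to smallest singular value.

    Returns ``inf`` when the smallest singular value is zero to machine
    tolerance (rank-deficient basis).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("condition number of an empty matrix is undefined")
    s = np.linalg.svd(values, compute_uv=False)
    if s[0] == 0:
        raise ValueError("matrix has no nonzero singular value")
    tol = max(values.shape) * np.finfo(float).eps * s[0]
    if s[-1] <= tol:
        return float("inf")
    return float(s[0] / s[-1])


def standardize_for_regression(
    sig: SignatureMatrix, mix: ExpressionMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict signature and mixture to their shared genes and z-score columns.

    Both outputs carry the shared genes in the signature's order; every
    column is scaled to zero mean and unit variance over those genes, which
    makes the subsequent regression invariant to per-sample scale factors.
    """
    shared = sig.gene_ids.intersection(mix.gene_ids)
    shared = sig.gene_ids[sig.gene_ids.isin(shared)]  # keep signature order
    n_types = len(sig.cell_types)
    if len(shared) < n_types:
        missing = len(sig.gene_ids) - len(shared)
        raise ValueError(
            f"only {len(shared)} signature genes found in the mixture "
            f"({missing} missing); need at least {n_types}"
        )
    mix_linear = mix.to_linear()

    def _zscore(df: pd.DataFrame) -> pd.DataFrame:
        values = df.to_numpy(dtype=float)
        sd = values.std(axis=0)
        if (sd == 0).any():
            flat = df.columns[sd == 0].tolist()
            raise ValueError(f"constant columns over shared genes: {flat}")
        return pd.DataFrame(
            (values - values.mean(axis=0)) / sd, index=df.index, columns=df.columns
        )

    return _zscore(sig.data.loc[shared]), _zscore(mix_linear.data.loc[shared])


def aggregate_fractions(f: FractionVector, h: CellTypeHierarchy) -> FractionVector:
    """Sum fine-grained fractions into their major cell types.

    Total mass is conserved exactly; an unmapped cell type is an error.
    """
    h.validate_covers(f.cell_types)
    majors = [m for m in h.majors if m in {h.major_of(ct) for ct in f.cell_types}]
    sums = {m: 0.0 for m in majors}
    for ct, value in f.fractions.items():
        sums[h.major_of(ct)] += float(value)
    out = pd.Series(sums, index=pd.Index(majors, name="cell_type"))
    return FractionVector(out, all_zero=f.all_zero)
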