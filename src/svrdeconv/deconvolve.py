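"""The nu-SVR deconvolution engine.

Each mixture column is regressed on the signature basis with a
linear-kernel nu-support-vector regression over a small grid of nu
values; the fit with the lowest reconstruction RMSE is kept and its
coefficients, clipped at zero and renormalized, are reported as relative
cell-type proportions. nu bounds the fraction of support vectors and
margin errors, so the grid trades sparsity of the effective gene set
against fit tightness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import NuSVR

from .core import (
    ExpressionMatrix,
    FractionVector,
    SignatureMatrix,
    quantile_normalize,
    standardize_for_regression,
)

__all__ = [
    "DeconvolutionConfig",
    "SampleDeconvolution",
    "DeconvolutionResult",
    "fit_nu_svr",
    "reconstruction_rmse",
    "weights_to_fractions",
    "deconvolve_sample",
    "deconvolve_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class DeconvolutionConfig:
    """Engine settings.

    ``nu_grid`` is the set of nu values tried per sample (each in (0, 1]);
    ``quantile_normalize_input`` applies quantile normalization across the
    mixture matrix's sample columns before deconvolution, removing
    between-sample distribution differences the way array preprocessing
    does (it is a no-op for a single sample, and should stay off for
    mixtures already on the signature's scale, e.g. simulated ones);
    ``C`` is the SVR regularization constant.
    """

    nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    quantile_normalize_input: bool = True
    C: float = 1.0

    def __post_init__(self) -> None:
        if len(self.nu_grid) == 0:
            raise ValueError("nu_grid must be nonempty")
        if any(not 0 < nu <= 1 for nu in self.nu_grid):
            raise ValueError("every nu must lie in (0, 1]")
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class SampleDeconvolution:
    """Deconvolution outcome for one mixture column."""

    fractions: FractionVector
    nu: float
    rmse: float
    correlation: float
    support_genes: int


@dataclass
class DeconvolutionResult:
    """Batch outcome: per-sample fractions plus fit diagnostics.

    ``fractions`` is samples x cell types; ``metrics`` holds the chosen
    nu, reconstruction RMSE, reconstruction Pearson correlation and
    support-gene count per sample; ``failures`` maps failed sample ids to
    the error message (those samples are absent from the tables).
    """

    fractions: pd.DataFrame
    metrics: pd.DataFrame
    failures: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """One row per sample: fractions then nu, rmse, correlation, support_genes."""
        return pd.concat([self.fractions, self.metrics], axis=1)


def fit_nu_svr(
    sig_std: pd.DataFrame | np.ndarray,
    mix_std: pd.Series | np.ndarray,
    nu: float,
    C: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear-kernel nu-SVR regression of a mixture on the signature basis.

    Returns the raw regression weights (one per cell type) and the
    indices of the support genes — the genes with nonzero dual
    coefficients, the only ones the fit effectively uses.
    """
    X = np.asarray(sig_std, dtype=float)
    y = np.asarray(mix_std, dtype=float).ravel()
    model = NuSVR(kernel="linear", nu=nu, C=C)
    model.fit(X, y)
    if not model.fit_status_ == 0:
        raise RuntimeError(f"nu-SVR failed to converge at nu={nu}")
    weights = np.asarray(model.coef_).ravel()
    return weights, np.asarray(model.support_)


def reconstruction_rmse(
    sig_std: pd.DataFrame | np.ndarray,
    weights: np.ndarray,
    mix_std: pd.Series | np.ndarray,
) -> float:
    """Root mean squared difference between the reconstruction and the mixture."""
    X = np.asarray(sig_std, dtype=float)
    y = np.asarray(mix_std, dtype=float).ravel()
    resid = X @ np.asarray(weights, dtype=float) - y
    return float(np.sqrt(np.mean(resid**2)))


def weights_to_fractions(
    weights: np.ndarray, cell_types: pd.Index
) -> FractionVector:
    """Clip negative weights at zero and renormalize to a composition.

    If every weight is non-positive the result is an all-zero vector
    flagged as degenerate.
    """
    w = np.asarray(weights, dtype=float).copy()
    if len(w) != len(cell_types):
        raise ValueError("one weight per cell type required")
    w[w < 0] = 0.0
    total = w.sum()
    index = pd.Index(cell_types, name="cell_type")
    if total <= 0:
        return FractionVector(pd.Series(0.0, index=index), all_zero=True)
    return FractionVector(pd.Series(w / total, index=index))


def deconvolve_sample(
    sig: SignatureMatrix,
    mix_col: pd.Series,
    cfg: DeconvolutionConfig | None = None,
) -> SampleDeconvolution:
    """Deconvolve one linear-scale mixture column against the signature.

    The column is aligned to the signature by gene id, both are z-scored
    over the shared genes, and one nu-SVR is fitted per nu in the grid;
    the fit with minimal reconstruction RMSE wins, ties broken toward
    smaller nu (sparser support).
    """
    cfg = cfg or DeconvolutionConfig()
    mix = ExpressionMatrix(mix_col.to_frame(), scale="linear")
    sig_std, mix_std = standardize_for_regression(sig, mix)
    y = mix_std.iloc[:, 0].to_numpy()
    X = sig_std.to_numpy()
    best: tuple[float, float, np.ndarray, np.ndarray] | None = None
    errors = []
    for nu in sorted(cfg.nu_grid):
        try:
            weights, support = fit_nu_svr(X, y, nu, C=cfg.C)
        except Exception as exc:  # propagate only if the whole grid fails
            errors.append(f"nu={nu}: {exc}")
            continue
        rmse = reconstruction_rmse(X, weights, y)
        if best is None or rmse < best[0]:
            best = (rmse, nu, weights, support)
    if best is None:
        raise RuntimeError("all nu values failed: " + "; ".join(errors))
    rmse, nu, weights, support = best
    recon = X @ weights
    correlation = float(stats.pearsonr(recon, y)[0]) if np.std(recon) > 0 else float("nan")
    return SampleDeconvolution(
        fractions=weights_to_fractions(weights, sig.cell_types),
        nu=float(nu),
        rmse=rmse,
        correlation=correlation,
        support_genes=int(len(support)),
    )


def deconvolve_matrix(
    sig: SignatureMatrix,
    mixtures: ExpressionMatrix,
    cfg: DeconvolutionConfig | None = None,
) -> DeconvolutionResult:
    """Deconvolve every sample column of a mixture matrix.

    Sample order is preserved; per-sample failures are collected so one
    bad column does not abort the batch.
    """
    cfg = cfg or DeconvolutionConfig()
    mixtures = mixtures.to_linear()
    if cfg.quantile_normalize_input and mixtures.n_samples >= 2:
        mixtures = quantile_normalize(mixtures)
    rows: dict[str, pd.Series] = {}
    metrics: dict[str, dict[str, float]] = {}
    failures: dict[str, str] = {}
    for sample in mixtures.sample_ids:
        try:
            res = deconvolve_sample(sig, mixtures.data[sample], cfg)
        except Exception as exc:
            failures[str(sample)] = str(exc)
            logger.warning("sample %s failed: %s", sample, exc)
            continue
        rows[str(sample)] = res.fractions.fractions
        metrics[str(sample)] = {
            "nu": res.nu,
            "rmse": res.rmse,
            "correlation": res.correlation,
            "support_genes": res.support_genes,
        }
    if failures:
        logger.warning("%d/%d samples failed", len(failures), mixtures.n_samples)
    fractions = pd.DataFrame.from_dict(rows, orient="index")
    metrics_df = pd.DataFrame.from_dict(metrics, orient="index")
    if fractions.empty:
        fractions = pd.DataFrame(columns=sig.cell_types)
        metrics_df = pd.DataFrame(
            columns=["nu", "rmse", "correlation", "support_genes"]
        )
    fractions.index.name = "sample"
    metrics_df.index.name = "sample"
    return DeconvolutionResult(fractions=fractions, metrics=metrics_df, failures=failures)
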