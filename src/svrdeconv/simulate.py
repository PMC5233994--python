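"""In-silico mixture benchmarks with known ground-truth composition.

Three benchmark designs are generated here: pure single-cell-type
profiles, spike-in series of one target type swept against a fixed
random background of the remaining types, and tumor-dilution series in
which a fixed immune mixture is blended with increasing amounts of a
non-immune tumor profile. A fully synthetic block-structured signature
panel makes every other module testable without any external data.

All mixtures are convex combinations of signature columns in linear
space — the mixture value of gene g is sum_c f_c * A[g, c], times
multiplicative log-normal noise when enabled — and every operation is
deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_CELL_TYPES,
    DEFAULT_HIERARCHY,
    MAJOR_CELL_TYPES,
    CellTypeHierarchy,
    ExpressionMatrix,
    FractionVector,
    SignatureMatrix,
)

__all__ = [
    "SyntheticPanelSpec",
    "MixtureTruth",
    "generate_synthetic_panel",
    "sample_pure_profile",
    "random_background_mixture",
    "random_immune_mixture",
    "spike_in_series",
    "synthetic_tumor_profile",
    "tumor_dilution_series",
]


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Shape and noise of the synthetic reference panel.

    Defaults emulate a microarray-scale immune signature: 25 cell types
    with 20 markers each, a fifth of each type's markers shared with a
    sibling type (marker sharing between related subtypes is what makes
    real panels partially ambiguous), markers elevated 16-fold (4 log2
    units) over a baseline intensity of 64, and multiplicative
    log-normal noise with sd 0.1 on the natural-log scale for replicate
    reference samples.
    """

    n_cell_types: int = 25
    markers_per_type: int = 20
    shared_marker_fraction: float = 0.2
    baseline: float = 64.0
    marker_fold_change: float = 16.0
    noise_sd: float = 0.1
    n_replicates: int = 4
    cell_types: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 2:
            raise ValueError("need at least 2 cell types")
        if self.markers_per_type < 1:
            raise ValueError("need at least 1 marker per type")
        if not 0 <= self.shared_marker_fraction < 1:
            raise ValueError("shared_marker_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.baseline <= 0 or self.marker_fold_change <= 1:
            raise ValueError("baseline must be > 0 and fold change > 1")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per type for DE testing")
        if self.cell_types is not None and len(self.cell_types) != self.n_cell_types:
            raise ValueError("cell_types length must equal n_cell_types")

    def resolved_cell_types(self) -> tuple[str, ...]:
        if self.cell_types is not None:
            return self.cell_types
        if self.n_cell_types == len(DEFAULT_CELL_TYPES):
            return DEFAULT_CELL_TYPES
        return tuple(f"CT{i + 1:02d}" for i in range(self.n_cell_types))


@dataclass
class MixtureTruth:
    """Ground truth attached to a simulated mixture.

    ``composition`` covers the immune types and sums to 1 before tumor
    blending; after blending, immune mass is (1 - tumor_fraction).
    """

    composition: FractionVector
    tumor_fraction: float = 0.0
    seed: int | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.tumor_fraction < 1:
            raise ValueError("tumor_fraction must lie in [0, 1)")

    def blended_fractions(self) -> pd.Series:
        """Immune fractions on the mixture scale (summing to 1 - tumor_fraction)."""
        return self.composition.fractions * (1.0 - self.tumor_fraction)


def _hierarchy_for(cell_types: tuple[str, ...]) -> CellTypeHierarchy:
    if all(ct in DEFAULT_HIERARCHY.mapping for ct in cell_types):
        return CellTypeHierarchy(
            {ct: DEFAULT_HIERARCHY.mapping[ct] for ct in cell_types}
        )
    majors = MAJOR_CELL_TYPES
    return CellTypeHierarchy(
        {ct: majors[i % len(majors)] for i, ct in enumerate(cell_types)}
    )


def generate_synthetic_panel(
    spec: SyntheticPanelSpec | None = None,
) -> tuple[SignatureMatrix, ExpressionMatrix, pd.Series, CellTypeHierarchy]:
    """Build a block-structured signature with a noisy reference panel.

    Each cell type owns a block of markers elevated by the fold change
    over the baseline; a spec-controlled fraction of every type's
    markers is additionally elevated in the next (sibling) type, so
    neighbouring types share part of their marker set. Reference samples
    are the signature columns perturbed by multiplicative log-normal
    noise, ``n_replicates`` per type.

    Returns ``(signature, reference, labels, hierarchy)``.
    """
    spec = spec or SyntheticPanelSpec()
    rng = np.random.default_rng(spec.seed)
    k, m = spec.n_cell_types, spec.markers_per_type
    cell_types = spec.resolved_cell_types()
    n_genes = k * m
    genes = pd.Index([f"G{i + 1:05d}" for i in range(n_genes)], name="gene")
    values = np.full((n_genes, k), spec.baseline)
    n_shared = int(round(spec.shared_marker_fraction * m))
    for c in range(k):
        block = slice(c * m, (c + 1) * m)
        values[block, c] *= spec.marker_fold_change
        if n_shared:
            sibling = (c + 1) % k
            values[c * m : c * m + n_shared, sibling] *= spec.marker_fold_change
    sig = SignatureMatrix(
        pd.DataFrame(values, index=genes, columns=pd.Index(cell_types, name="cell_type"))
    )
    columns = []
    labels = {}
    for c, cell_type in enumerate(cell_types):
        for r in range(spec.n_replicates):
            sample = f"{cell_type}_rep{r + 1}"
            noise = np.exp(rng.normal(0.0, spec.noise_sd, n_genes))
            columns.append(pd.Series(values[:, c] * noise, index=genes, name=sample))
            labels[sample] = cell_type
    ref = ExpressionMatrix(pd.concat(columns, axis=1), scale="linear")
    return sig, ref, pd.Series(labels, name="cell_type"), _hierarchy_for(cell_types)


def sample_pure_profile(
    sig: SignatureMatrix,
    cell_type: str,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.Series, MixtureTruth]:
    """A single-cell-type profile: one signature column under noise.

    The truth composition is the indicator of ``cell_type``.
    """
    if cell_type not in sig.cell_types:
        raise KeyError(f"unknown cell type {cell_type!r}")
    rng = np.random.default_rng(seed)
    column = sig.data[cell_type].to_numpy(dtype=float)
    if noise_sd > 0:
        column = column * np.exp(rng.normal(0.0, noise_sd, len(column)))
    profile = pd.Series(column, index=sig.gene_ids, name=f"pure_{cell_type}")
    truth = FractionVector(
        pd.Series(
            (sig.cell_types == cell_type).astype(float),
            index=pd.Index(sig.cell_types, name="cell_type"),
        )
    )
    return profile, MixtureTruth(truth, seed=seed, noise_sd=noise_sd)


def _dirichlet_composition(
    rng: np.random.Generator, cell_types: pd.Index, support: list[str]
) -> FractionVector:
    f = pd.Series(0.0, index=pd.Index(cell_types, name="cell_type"))
    f[support] = rng.dirichlet(np.ones(len(support)))
    return FractionVector(f)


def random_background_mixture(
    sig: SignatureMatrix, excluded_type: str, seed: int = 0
) -> tuple[pd.Series, MixtureTruth]:
    """A random mixture of every signature type except one.

    The composition over the remaining types is drawn uniformly on the
    simplex (symmetric Dirichlet with concentration 1); the profile is
    the corresponding convex combination of signature columns in linear
    space. The excluded type's true fraction is exactly 0.
    """
    if excluded_type not in sig.cell_types:
        raise KeyError(f"unknown cell type {excluded_type!r}")
    if len(sig.cell_types) < 2:
        raise ValueError("background mixture needs at least 2 cell types")
    rng = np.random.default_rng(seed)
    support = [ct for ct in sig.cell_types if ct != excluded_type]
    truth = _dirichlet_composition(rng, sig.cell_types, support)
    profile = pd.Series(
        sig.data.to_numpy(dtype=float) @ truth.fractions.to_numpy(),
        index=sig.gene_ids,
        name=f"background_wo_{excluded_type}",
    )
    return profile, MixtureTruth(truth, seed=seed)


def random_immune_mixture(
    sig: SignatureMatrix, seed: int = 0
) -> tuple[pd.Series, MixtureTruth]:
    """A random mixture over *all* signature types (Dirichlet(1) composition)."""
    rng = np.random.default_rng(seed)
    truth = _dirichlet_composition(rng, sig.cell_types, list(sig.cell_types))
    profile = pd.Series(
        sig.data.to_numpy(dtype=float) @ truth.fractions.to_numpy(),
        index=sig.gene_ids,
        name="immune_mixture",
    )
    return profile, MixtureTruth(truth, seed=seed)


def spike_in_series(
    sig: SignatureMatrix,
    target_type: str,
    step: int = 10,
    seed: int = 0,
) -> list[tuple[pd.Series, MixtureTruth]]:
    """Sweep one type's proportion from 0% to 100% against a fixed background.

    A single random background over the other types is drawn once; the
    series blends ``p * pure_target + (1 - p) * background`` for
    p = 0, step, ..., 100 percent (default step 10, an 11-point series).
    """
    if step < 1 or 100 % step != 0:
        raise ValueError("step must be a positive divisor of 100")
    background, bg_truth = random_background_mixture(sig, target_type, seed=seed)
    pure = sig.data[target_type].to_numpy(dtype=float)
    series = []
    for pct in range(0, 101, step):
        p = pct / 100.0
        profile = pd.Series(
            p * pure + (1.0 - p) * background.to_numpy(),
            index=sig.gene_ids,
            name=f"spike_{target_type}_{pct:03d}",
        )
        comp = bg_truth.composition.fractions * (1.0 - p)
        comp[target_type] = p
        truth = MixtureTruth(FractionVector(comp), seed=seed)
        series.append((profile, truth))
    return series


def synthetic_tumor_profile(
    sig: SignatureMatrix,
    seed: int = 0,
    n_tumor_markers: int = 100,
    marker_level: float = 2048.0,
    baseline: float = 16.0,
    noise_sd: float = 0.25,
) -> pd.Series:
    """A synthetic non-immune (tumor-like) expression profile.

    Signature genes are hematopoietic-restricted and explicitly filtered
    against tumor expression during construction, so a pure cultured
    tumor line expresses them near the array background floor (default
    baseline 16, i.e. log2 level 4, under multiplicative log-normal
    technical variation). A set of tumor-specific marker genes disjoint
    from the signature is appended at a high level; intersecting with
    the signature's gene universe therefore leaves structureless
    background — the behaviour of real tumor content from the
    deconvolution basis's point of view.
    """
    rng = np.random.default_rng(seed)
    base = baseline * np.exp(rng.normal(0.0, noise_sd, len(sig.gene_ids)))
    extra_genes = [f"TUM{i + 1:04d}" for i in range(n_tumor_markers)]
    extra = marker_level * np.exp(rng.normal(0.0, noise_sd, n_tumor_markers))
    return pd.Series(
        np.concatenate([base, extra]),
        index=pd.Index(list(sig.gene_ids) + extra_genes, name="gene"),
        name="tumor",
    )


def tumor_dilution_series(
    immune_mixture: tuple[pd.Series, MixtureTruth],
    tumor_profile: pd.Series,
) -> list[tuple[pd.Series, MixtureTruth]]:
    """Blend an immune mixture with increasing tumor content.

    Tumor fractions run 0% to 90% in even 10% increments and then 91% to
    99% in 1% increments — a 19-point series probing tolerance to
    dominant unknown content. Profiles are intersected onto the shared
    gene universe; the truth records the tumor fraction while the
    *relative* immune composition stays identical at every point.
    """
    profile, truth = immune_mixture
    shared = profile.index.intersection(tumor_profile.index)
    if len(shared) == 0:
        raise ValueError("immune mixture and tumor profile share no genes")
    immune = profile.loc[shared].to_numpy(dtype=float)
    tumor = tumor_profile.loc[shared].to_numpy(dtype=float)
    series = []
    for pct in list(range(0, 91, 10)) + list(range(91, 100)):
        t = pct / 100.0
        blend = pd.Series(
            (1.0 - t) * immune + t * tumor,
            index=shared,
            name=f"tumor_{pct:03d}",
        )
        series.append(
            (blend, replace(truth, tumor_fraction=t))
        )
    return series
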