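"""Signature-matrix construction from a labelled reference expression panel.

Pipeline order is fixed: one-vs-rest differential-expression ranking,
removal of genes expressed outside the hematopoietic compartment
(enrichment-score filter), removal of tumor-expressed genes, then a scan
over the per-type marker count ``n`` that keeps the signature with the
minimal 2-norm condition number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, SignatureMatrix, condition_number

__all__ = [
    "SignatureBuildConfig",
    "RankedMarkerTable",
    "EnrichmentScoreTable",
    "rank_marker_genes",
    "compute_enrichment_scores",
    "hematopoietic_gene_set",
    "filter_tumor_expressed",
    "assemble_signature",
    "optimize_signature",
]

logger = logging.getLogger(__name__)


@dataclass
class SignatureBuildConfig:
    """Tunables of the signature-construction pipeline.

    ``n_range`` is the inclusive range of per-type marker counts scanned
    during condition-number optimization; the default 1..44 covers up to
    the largest marker list a per-type contrast typically yields.
    """

    n_range: range = field(default_factory=lambda: range(1, 45))
    significance: float = 0.05
    non_hematopoietic_fraction: float = 0.05
    tumor_log2_threshold: float = 7.0
    de_method: str = "moderated"  # or "ttest"

    def __post_init__(self) -> None:
        if len(self.n_range) == 0 or min(self.n_range) < 1:
            raise ValueError("n_range must be a nonempty range of positive integers")
        if not 0 < self.significance < 1:
            raise ValueError("significance threshold must lie in (0, 1)")
        if not 0 <= self.non_hematopoietic_fraction < 1:
            raise ValueError("non-hematopoietic fraction threshold must lie in [0, 1)")
        if self.de_method not in ("moderated", "ttest"):
            raise ValueError("de_method must be 'moderated' or 'ttest'")


@dataclass
class RankedMarkerTable:
    """Per-cell-type marker lists, ordered by decreasing log2 fold change.

    Each table has columns ``gene``, ``log2_fc``, ``adj_p``; only genes
    significantly *up* in the target type are retained.
    """

    tables: dict[str, pd.DataFrame]
    significance: float = 0.05

    def __post_init__(self) -> None:
        for cell_type, table in self.tables.items():
            fc = table["log2_fc"].to_numpy()
            if (np.diff(fc) > 1e-12).any():
                raise ValueError(f"fold changes not non-increasing for {cell_type}")
            if (table["adj_p"].to_numpy() >= self.significance).any():
                raise ValueError(f"non-significant entries in table for {cell_type}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.tables)

    def top(self, cell_type: str, n: int) -> list[str]:
        table = self.tables[cell_type]
        if len(table) < n:
            logger.info(
                "cell type %s has only %d markers (requested %d)",
                cell_type, len(table), n,
            )
        return table["gene"].head(n).tolist()

    def restrict(self, genes) -> "RankedMarkerTable":
        """Drop markers outside ``genes``, preserving order."""
        keep = set(genes)
        return RankedMarkerTable(
            {
                ct: t[t["gene"].isin(keep)].reset_index(drop=True)
                for ct, t in self.tables.items()
            },
            significance=self.significance,
        )


@dataclass
class EnrichmentScoreTable:
    """Per (gene, tissue group) enrichment scores with hematopoietic flags.

    ``scores`` is genes x groups; an entry is the sum of the group's
    significant pairwise linear-model coefficients for that gene (0 when
    none are significant). ``hematopoietic`` flags each group as blood
    lineage or not.
    """

    scores: pd.DataFrame
    hematopoietic: dict[str, bool]

    def __post_init__(self) -> None:
        missing = [g for g in self.scores.columns if g not in self.hematopoietic]
        if missing:
            raise ValueError(f"tissue groups without hematopoietic flag: {missing}")


# ---------------------------------------------------------------------------
# moderated one-vs-rest differential expression


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes prior (df0, s2_0) for gene-wise variances.

    Moment-matches the distribution of log sample variances to a scaled
    F distribution, the standard variance-shrinkage construction for
    moderated t statistics.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return float("inf"), float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return float("inf"), float(np.exp(e_mean))
    df0 = float(2.0 * _trigamma_inverse(np.array(e_var / 2.0)))
    s2_0 = float(
        np.exp(e_mean + special.digamma(df0 / 2.0) - np.log(df0 / 2.0))
    )
    return df0, s2_0


def _two_group_stats(
    values: np.ndarray, in_group: np.ndarray, moderated: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-group comparison per gene on log2 values.

    Returns (log2 fold change target-minus-rest, two-sided p-values).
    With ``moderated`` the pooled variances are shrunk toward an
    empirical-Bayes prior and the t statistic gains the prior's degrees
    of freedom; otherwise it is a plain pooled-variance two-sample t.
    """
    x1 = values[:, in_group]
    x2 = values[:, ~in_group]
    n1, n2 = x1.shape[1], x2.shape[1]
    lfc = x1.mean(axis=1) - x2.mean(axis=1)
    df = n1 + n2 - 2
    s2 = (x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)) / df
    if moderated:
        df0, s2_0 = _fit_variance_prior(s2, df)
        if np.isinf(df0):
            s2_post = np.full_like(s2, s2_0)
            df_total = np.inf
        else:
            s2_post = (df0 * s2_0 + df * s2) / (df0 + df)
            df_total = df0 + df
    else:
        s2_post = s2
        df_total = df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # a gene constant in both groups with zero difference carries no signal
    p = np.where(np.isnan(t) | (se == 0) & (lfc == 0), 1.0, p)
    return lfc, p


def rank_marker_genes(
    ref: ExpressionMatrix,
    labels: pd.Series,
    cfg: SignatureBuildConfig | None = None,
) -> RankedMarkerTable:
    """One-vs-rest marker ranking for every cell type in the reference panel.

    For each cell type, every gene is tested for differential expression
    between that type's samples and all remaining samples on the log2
    scale; p-values are Benjamini-Hochberg adjusted across genes within
    the contrast. Markers are genes with adjusted p below the
    significance threshold and positive fold change (up in the target
    type), ordered by decreasing log2 fold change.
    """
    cfg = cfg or SignatureBuildConfig()
    labels = pd.Series(labels)
    labels = labels.reindex(ref.sample_ids)
    if labels.isna().any():
        raise ValueError("every reference sample needs a cell-type label")
    counts = labels.value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        raise ValueError(f"cell types with fewer than 2 samples: {small}")
    values = ref.to_log2().data.to_numpy(dtype=float)
    genes = ref.gene_ids.to_numpy()
    tables: dict[str, pd.DataFrame] = {}
    for cell_type in pd.unique(labels):
        in_group = (labels == cell_type).to_numpy()
        lfc, p = _two_group_stats(values, in_group, cfg.de_method == "moderated")
        adj_p = multipletests(p, method="fdr_bh")[1]
        keep = (adj_p < cfg.significance) & (lfc > 0)
        table = pd.DataFrame(
            {"gene": genes[keep], "log2_fc": lfc[keep], "adj_p": adj_p[keep]}
        )
        table = table.sort_values(
            ["log2_fc", "gene"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
        tables[str(cell_type)] = table
    return RankedMarkerTable(tables, significance=cfg.significance)


# ---------------------------------------------------------------------------
# filters


def compute_enrichment_scores(
    tissue_panel: ExpressionMatrix,
    tissue_labels: pd.Series,
    hematopoietic_groups: set[str] | frozenset[str],
) -> EnrichmentScoreTable:
    """Enrichment score of every gene in every tissue group.

    Each group is contrasted against every other group individually with
    a per-gene linear model (equivalent to a pooled-variance two-sample
    fit, coefficient = log2 mean difference); q-values are
    Benjamini-Hochberg adjusted across genes within each pairwise
    contrast, and the enrichment score is the sum of the coefficients
    whose q-value falls below 0.05.
    """
    labels = pd.Series(tissue_labels).reindex(tissue_panel.sample_ids)
    if labels.isna().any():
        raise ValueError("every tissue sample needs a group label")
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("enrichment scores need at least 2 tissue groups")
    values = tissue_panel.to_log2().data.to_numpy(dtype=float)
    scores = pd.DataFrame(
        0.0, index=tissue_panel.gene_ids, columns=pd.Index(groups, name="group")
    )
    for g in groups:
        mask_g = (labels == g).to_numpy()
        for h in groups:
            if h == g:
                continue
            mask_h = (labels == h).to_numpy()
            sub = values[:, mask_g | mask_h]
            in_g = mask_g[mask_g | mask_h]
            coef, p = _two_group_stats(sub, in_g, moderated=False)
            q = multipletests(p, method="fdr_bh")[1]
            sig = q < 0.05
            scores.loc[sig, g] += coef[sig]
    flags = {g: g in hematopoietic_groups for g in groups}
    return EnrichmentScoreTable(scores=scores, hematopoietic=flags)


def hematopoietic_gene_set(
    es: EnrichmentScoreTable, cfg: SignatureBuildConfig | None = None
) -> set[str]:
    """Genes whose enrichment mass is confined to blood-lineage groups.

    For genes positively enriched somewhere, the non-hematopoietic
    fraction is the share of positive enrichment-score mass carried by
    non-hematopoietic groups; genes with fraction above the threshold
    are dropped, as are genes with no positive enrichment anywhere (no
    evidence of lineage).
    """
    cfg = cfg or SignatureBuildConfig()
    positive = es.scores.clip(lower=0.0)
    total = positive.sum(axis=1)
    non_hemato_cols = [g for g, flag in es.hematopoietic.items() if not flag]
    non_hemato = positive[non_hemato_cols].sum(axis=1)
    no_evidence = total <= 0
    if no_evidence.any():
        logger.info(
            "%d genes with no positive enrichment excluded from the "
            "hematopoietic set", int(no_evidence.sum()),
        )
    with np.errstate(invalid="ignore"):
        fraction = non_hemato / total
    keep = (~no_evidence) & (fraction <= cfg.non_hematopoietic_fraction)
    return set(es.scores.index[keep])


def filter_tumor_expressed(
    candidates: set[str],
    tumor_panel: ExpressionMatrix,
    cfg: SignatureBuildConfig | None = None,
) -> set[str]:
    """Drop candidate genes highly expressed in non-hematopoietic tumors.

    A gene with mean log2 expression above the threshold (default 7)
    across the tumor panel is considered tumor-expressed and removed;
    candidates absent from the panel are kept and logged.
    """
    cfg = cfg or SignatureBuildConfig()
    mean_log2 = tumor_panel.to_log2().data.mean(axis=1)
    absent = sorted(g for g in candidates if g not in mean_log2.index)
    if absent:
        logger.info("%d candidate genes absent from the tumor panel, kept", len(absent))
    removed = {
        g for g in candidates
        if g in mean_log2.index and mean_log2[g] > cfg.tumor_log2_threshold
    }
    return candidates - removed


# ---------------------------------------------------------------------------
# assembly and optimization


def assemble_signature(
    markers: RankedMarkerTable,
    n: int,
    ref: ExpressionMatrix,
    labels: pd.Series,
) -> SignatureMatrix:
    """Merge each type's top-n markers into a mean-expression basis.

    The gene set is the union of the per-type top-n lists (shared markers
    enter once); each entry is the mean linear-scale expression of the
    gene over the reference samples of that cell type.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = pd.Series(labels).reindex(ref.sample_ids)
    genes: list[str] = []
    seen: set[str] = set()
    for cell_type in markers.cell_types:
        for gene in markers.top(cell_type, n):
            if gene not in seen:
                seen.add(gene)
                genes.append(gene)
    if not genes:
        raise ValueError("empty marker union: no signature can be assembled")
    linear = ref.to_linear().data.loc[genes]
    means = {
        cell_type: linear.loc[:, (labels == cell_type).to_numpy()].mean(axis=1)
        for cell_type in markers.cell_types
    }
    return SignatureMatrix(pd.DataFrame(means, index=pd.Index(genes, name="gene")))


def optimize_signature(
    markers: RankedMarkerTable,
    ref: ExpressionMatrix,
    labels: pd.Series,
    cfg: SignatureBuildConfig | None = None,
) -> tuple[int, SignatureMatrix, pd.DataFrame]:
    """Scan top-n marker counts and keep the best-conditioned signature.

    For every n in the configured range a candidate signature is
    assembled and its condition number recorded; the n with the minimal
    condition number wins, ties broken toward smaller n (fewer genes).
    Returns ``(best_n, signature, profile)`` where ``profile`` has one
    row per attempted n with columns ``n``, ``n_genes``,
    ``condition_number``.
    """
    cfg = cfg or SignatureBuildConfig()
    rows = []
    candidates: dict[int, SignatureMatrix] = {}
    for n in cfg.n_range:
        try:
            sig = assemble_signature(markers, n, ref, labels)
        except ValueError as exc:
            logger.warning("n=%d skipped: %s", n, exc)
            continue
        candidates[n] = sig
        rows.append(
            {"n": n, "n_genes": len(sig.gene_ids),
             "condition_number": sig.condition_number}
        )
    if not candidates:
        raise ValueError("signature assembly failed for every n in the range")
    profile = pd.DataFrame(rows)
    finite = profile[np.isfinite(profile["condition_number"])]
    pool = finite if len(finite) else profile
    best_n = int(pool.sort_values(["condition_number", "n"]).iloc[0]["n"])
    return best_n, candidates[best_n], profile
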