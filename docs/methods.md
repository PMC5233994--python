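# Methods

## The mixture model

A bulk expression profile is modeled as a convex combination of
cell-type-specific mean profiles on the *linear* intensity scale:
`B = A x`, with `A` the signature matrix (genes × cell types), `x` the
relative proportions. Linearity holds for transcript abundance, not its
logarithm, so log2 inputs are anti-logged at ingestion (`2**x`); the
only place log2 values are used directly is the differential-expression
testing and the tumor-expression filter, where the log scale is the
convention.

Proportions are *relative to the modeled cell types*: content the basis
does not describe (tumor cells, stroma) takes no share of the output,
which always sums to 1 unless every regression weight is non-positive
(then an all-zero vector is returned, explicitly flagged).

## The regression

Each mixture column is aligned to the signature by gene symbol,
restricted to the shared genes (required: at least as many shared genes
as cell types), and both signature columns and the mixture column are
z-scored over those genes (zero mean, unit variance per column). A
linear-kernel ν-SVR (libsvm via scikit-learn) is fitted once per ν in
the grid, default {0.25, 0.5, 0.75} with regularization constant C = 1;
the fit with the smallest reconstruction RMSE (computed as
`rms(A_std w − b_std)` in the standardized space, no intercept) is
kept, ties broken toward the smaller ν because its support is sparser.
Negative coefficients are clipped to zero and the remainder normalized
to sum to 1. The reported diagnostics — RMSE, reconstruction Pearson
correlation, support-gene count — all refer to the winning fit in
standardized space, which is the regression's own space.

Consequences of this construction worth knowing:

- **Scale invariance.** Multiplying a mixture column by any positive
  constant leaves the standardized column, hence the fractions,
  unchanged.
- **Gene count interacts with regularization.** libsvm's data term is a
  *sum* over genes while the weight penalty is not, so with very few
  genes (tens) C = 1 under-fits and small fractions are clipped to
  zero. The guarantee of near-exact recovery for noiseless in-space
  mixtures holds for realistically sized signatures (hundreds of
  genes); with small bases, raise C.
- **Column standardization assumes comparable column scales.** Z-scoring
  each signature column separately rescales columns by their own
  standard deviation, so recovered weights are proportional to
  `f_c · sd_c`. In the synthetic panels all columns have equal sd by
  symmetry and this is exact; for strongly asymmetric real signatures
  the induced bias is a known caveat of the formulation.

## Quantile normalization

`quantile_normalize` forces every sample column to share the across-
sample mean of order statistics, preserving within-column ranks; tied
values within a column receive the mean of the target quantiles their
positions span (deterministic). Two facts about ties: a tied column
cannot carry the full target distribution (the tie collapses distinct
quantiles), and consequently strict idempotence holds only for tie-free
columns — both are asserted in the tests at exactly that scope.

In the deconvolution pipeline, quantile normalization is applied
*across the mixture matrix's own sample columns* before fitting (the
convention of the SVR-deconvolution family this package belongs to),
and is a warning no-op for a single sample. An alternative considered
and rejected was rank-mapping the mixture onto the signature's pooled
value distribution: that transform is monotone but non-linear, and on
exact linear mixtures it destroys recovery (max per-type error 0.85
versus 1e-4 without it on the default panel), so it is not offered.
The simulation benchmarks run with normalization off
(`quantile_normalize_input=False`): simulated mixtures are constructed
directly in the signature's linear space, so there is no between-sample
distribution artifact to remove, and forcing all series points onto a
common distribution would itself perturb the compositions being
measured.

## Signature construction

*Marker ranking.* One-vs-rest per cell type on log2 values. The default
statistic is a moderated two-sample t: per-gene pooled variances are
shrunk toward an empirical-Bayes prior obtained by moment-matching the
log sample variances to a scaled F distribution (the trigamma-inverse
Newton iteration), and the t statistic gains the prior degrees of
freedom. A plain pooled t is available via
`SignatureBuildConfig(de_method="ttest")`. P-values are
Benjamini–Hochberg adjusted across genes within each contrast; markers
must have adjusted p < 0.05 (configurable) *and* positive log2 fold
change — down-regulated genes are never markers, because signature
entries are mean expressions of genes characterizing the type. Fold
change is the difference of group means on the log2 scale. Ties in
fold change are broken by gene id for determinism.

*Enrichment score.* Each tissue group is contrasted against every other
group individually; the per-gene coefficient is the log2 mean
difference (equivalently the slope of the two-group linear model), with
q-values BH-adjusted across genes within each pairwise contrast. The
enrichment score of a gene in a group is the sum of its significant
(q < 0.05) coefficients. A gene's *non-hematopoietic fraction* is the
share of its positive enrichment mass carried by non-hematopoietic
groups; genes above 0.05 are excluded, as are genes with no positive
enrichment anywhere (no lineage evidence, logged). A count-of-groups
variant was considered; the mass fraction is the more direct reading
and is the one implemented.

*Tumor filter.* Genes with mean log2 expression > 7 across the tumor
panel are removed (strict inequality; exactly 7 survives). Candidates
absent from the panel are kept and logged.

*Top-n scan.* For each n in 1..44 the per-type top-n lists are merged
(shared markers enter once), matrix entries are per-type means of
linear-scale reference expression, and the 2-norm condition number
σ_max/σ_min is recorded; the minimal-condition-number n wins, ties
toward smaller n (parsimony). Rank-deficient candidates get condition
number +∞ and lose to any finite one; an n whose assembly fails is
skipped and logged. The gene union is monotone non-decreasing in n.

## The synthetic panel

`SyntheticPanelSpec` defaults describe a microarray-scale immune
panel:

| parameter | default | meaning |
|---|---|---|
| n_cell_types | 25 | fine-grained immune panel, mapped onto 7 major lineages |
| markers_per_type | 20 | 500 signature genes total, the scale of real immune signatures |
| shared_marker_fraction | 0.2 | a fifth of each type's markers also elevated in its sibling — marker sharing between related subtypes is what makes real panels partially ambiguous |
| baseline | 64 (log2 = 6) | typical expressed-gene intensity |
| marker_fold_change | 16 (4 log2 units) | typical marker separation on these arrays |
| noise_sd | 0.1 | multiplicative log-normal replicate noise (natural-log sd) |
| n_replicates | 4 | arrays per cell type in the reference panel |

The default cell-type names and their 7-way major grouping
(granulocytes, B cells, T cells CD4, T cells CD8, NK cells, dendritic
cells, mono/macrophages) are configurable defaults, not contracts:
every function takes the panel from its inputs.

The synthetic tumor profile expresses the signature genes at the array
background floor (level 16, log2 = 4, log-normal sd 0.25) with
tumor-specific markers only outside the signature's gene universe.
This is the condition the construction pipeline engineers: the tumor
filter removes genes with mean log2 > 7 in tumors, and a cultured
tumor line contains no immune cells, so hematopoietic-restricted
signature genes sit at background there. The tumor-dilution benchmark
measures tolerance *under that design*; a tumor that did express
signature genes strongly would first have to defeat the filter.

What the generator does **not** emulate: platform artifacts (probe
saturation, batch effects), correlated biological variation between
related subtypes beyond literal marker sharing, heavy-tailed expression
distributions, and unequal signature column scales. Passing benchmarks
therefore demonstrate correctness of the estimator under the linear
mixing model, not performance on any particular real platform.

## Benchmark designs and problem sizes

- *Pure profiles*: one profile per type, noise sd 0.1; the predicted
  self-proportion exceeds 90% for at least 23/25 types (the remaining
  couple are the deliberately ambiguous sibling pairs).
- *Noiseless recovery*: 100 Dirichlet(1) compositions; max per-type
  error observed ~2e-4, asserted ≤ 0.02.
- *Spike-in*: per type, an 11-point 0→100% sweep (step 10%) against one
  fixed Dirichlet background over the other 24 types; Spearman ρ = 1
  and endpoint errors ≤ 0.05 for every type.
- *Tumor dilution*: 19 points (0–90% by 10%, 91–99% by 1%); Pearson r
  between predicted and true immune composition ≥ 0.8 at 95% tumor
  (observed ~0.97 on the default seed).

These sizes run the whole suite in a few minutes on one core and were
chosen as the smallest designs that still exercise every regime
(rare-type detection, exactness, dominant unknown content).

## Numerical choices and degenerate inputs

- Condition number: 2-norm (SVD); +∞ when σ_min is zero within
  `max(shape)·eps·σ_max`; empty matrix is an error.
- Duplicate gene symbols at ingestion: collapsed by max (mean
  available), warning logged — the convention for probe-to-symbol
  collapsed arrays.
- A constant mixture column cannot be standardized and fails that
  sample only; batch deconvolution collects per-sample failures and
  continues.
- A signature with genes ≤ cell types warns at construction; the
  regression itself refuses to run without at least as many shared
  genes as cell types.
- All simulation seeds feed `numpy.random.default_rng`; equal seeds
  give byte-identical outputs.

## Limitations

Flow-cytometry comparison is table ingestion only (already-gated
percentages); no FCS parsing. No absolute abundance estimation and no
empirical significance testing of deconvolution results. The moderated
t is a self-contained implementation of the standard variance-shrinkage
construction, not a wrapper around an external DE framework; exact
shrinkage details (e.g. robust prior fitting) are intentionally
minimal.
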