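# svrdeconv

Estimation of immune cell-type composition from bulk expression
profiles of mouse tissues by ν-support-vector regression, together with
the pipeline that constructs the signature matrix the estimation rests
on, and the in-silico mixture benchmarks used to characterize such
models.

## The problem and the model

Solid tissues are mixtures of many cell populations, and bulk
microarray or RNA profiles average over all of them. Under the linear
mixing assumption, the bulk profile **B** (genes × 1) of a sample is

```
A x = B
```

where **A** is a *signature matrix* — genes × cell types, the mean
linear-scale expression of genes that jointly discriminate the immune
cell types — and **x** is the vector of relative cell-type proportions
to be recovered. `svrdeconv` solves for **x** by regressing the
standardized mixture on the standardized signature columns with a
linear-kernel **ν-SVR** over a grid of ν values (default
{0.25, 0.5, 0.75}); the fit with the lowest reconstruction RMSE is
kept, and its coefficients — clipped at zero and renormalized — are the
reported fractions. The genes with nonzero dual coefficients are the
*support genes*, the subset of the signature a given fit effectively
uses. ν-SVR's ε-insensitive loss is what gives the estimates their
tolerance to content the basis does not model, such as tumor cells.

The signature matrix itself is built from a labelled reference panel of
sorted immune cell populations in four steps:

1. **Marker ranking** — per cell type, a one-vs-rest moderated t test
   per gene (empirical-Bayes variance shrinkage, Benjamini–Hochberg
   adjustment within the contrast); genes with adjusted p < 0.05 and
   positive log2 fold change, ordered by decreasing fold change.
2. **Hematopoietic filter** — an enrichment score per gene and tissue
   group (sum of significant pairwise linear-model coefficients, q <
   0.05); genes whose positive enrichment mass falls > 5% in
   non-hematopoietic tissue groups are removed.
3. **Tumor filter** — genes with mean log2 expression > 7 across a
   non-hematopoietic tumor panel are removed.
4. **Condition-number scan** — for each n in 1..44 the per-type top-n
   markers are merged into a candidate basis; the n minimizing the
   2-norm condition number σ_max/σ_min wins (a better-conditioned basis
   is less sensitive to perturbations of the mixture).

A fully synthetic 25-type panel (block-structured signature with
partially shared markers, log-normal replicate noise) makes the whole
pipeline runnable and testable without any external data, and the three
simulation benchmark designs — pure profiles, spike-in series, and
tumor-dilution series — quantify recovery against known ground truth.

## Worked example

```python
from svrdeconv import (DeconvolutionConfig, SyntheticPanelSpec,
                       deconvolve_sample, generate_synthetic_panel,
                       random_immune_mixture)

sig, _, _, _ = generate_synthetic_panel(SyntheticPanelSpec(seed=0))
profile, truth = random_immune_mixture(sig, seed=42)
cfg = DeconvolutionConfig(quantile_normalize_input=False)
res = deconvolve_sample(sig, profile, cfg)
```

Running `python examples/deconvolve_mixture.py` (this code plus
printing) gives

```
chosen nu = 0.75, reconstruction RMSE = 0.0002, support genes = 51/500
                  true  predicted  abs_error
cell_type
Plasma cells    0.1193     0.1194        0.0
Neutrophils     0.0918     0.0919        0.0
...
max per-type error: 0.0000
```

i.e. for a noiseless mixture inside the basis's column space the
composition is recovered essentially exactly: the chosen ν = 0.75 fit
reconstructs the standardized mixture with RMSE 2e-4 using 51 of the
500 signature genes, and every one of the 25 predicted fractions
matches the generating composition to four decimals.

The other examples print the remaining designs:
`examples/spike_in_benchmark.py` sweeps regulatory T cells 0→100%
against a random background (Spearman ρ = 1.000 over the 11-point
series); `examples/tumor_dilution.py` blends an immune mixture with
tumor content up to 99% (correlation with the true immune composition
r = 0.973 at 95% tumor); `examples/build_signature.py` builds a
signature from a noisy reference panel and prints the condition-number
profile over n.

## Command line

A thin CLI wraps the library:

```
svrdeconv build-signature --reference ref.tsv --labels labels.tsv \
    --n-min 1 --n-max 44 --out signature.tsv --report profile.tsv
svrdeconv deconvolve --signature signature.tsv --mixture mixtures.tsv \
    --scale linear --out fractions.tsv
svrdeconv simulate pure --signature signature.tsv --seed 1 --out-prefix sim_
svrdeconv benchmark --seed 1 --out-prefix bench_
svrdeconv report --predicted fractions.tsv --reference flow.tsv --out report.tsv
```

All tables are TSV (genes × samples for expression, samples × cell
types for fractions); a YAML config file can supply any flag, and flags
override it. Commands exit nonzero on error and write outputs
atomically.

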