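"""Build a signature matrix from a labelled reference panel.

Generates a noisy synthetic reference panel (4 replicate arrays per
cell type), ranks one-vs-rest marker genes with the moderated t test,
then scans the per-type marker count n for the basis with the smallest
condition number. A smaller condition number means the deconvolution is
less sensitive to perturbations of the input profile.
"""

from svrdeconv import (
    SignatureBuildConfig,
    SyntheticPanelSpec,
    generate_synthetic_panel,
    optimize_signature,
    rank_marker_genes,
)

spec = SyntheticPanelSpec(n_cell_types=10, markers_per_type=12, seed=1)
_, ref, labels, _ = generate_synthetic_panel(spec)

cfg = SignatureBuildConfig(n_range=range(2, 16))
markers = rank_marker_genes(ref, labels, cfg)
print("markers found per cell type:",
      {ct: len(t) for ct, t in list(markers.tables.items())[:3]}, "...")

best_n, sig, profile = optimize_signature(markers, ref, labels, cfg)
print(profile.round(3).to_string(index=False))
print(f"\nbest n = {best_n}: {len(sig.gene_ids)} genes, "
      f"condition number {sig.condition_number:.3f}")
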