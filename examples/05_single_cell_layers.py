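"""Single-cell epidermal-layer pipeline.

Simulates droplet data with basal/spinous/granular keratinocytes (layer
markers DST/KRT5, KRT10, KLK7), opposing PCSK9 and IL36G gradients and
25% empty droplets, then runs the full chain: UMI droplet filter,
library normalization, marker-score layer assignment, layer-gradient
ANOVA and the PCSK9-high/low Welch t contrast on IL36G.
"""

from varex.sc import run_sc_pipeline
from varex.simulate import CellSimConfig, simulate_cells

adata, truth = simulate_cells(CellSimConfig(seed=5))
print(f"simulated {adata.n_obs} barcodes "
      f"({int(adata.obs['is_cell'].sum())} real cells)")

res = run_sc_pipeline(adata)
kept = res["adata"]
labels = res["assignment"].labels
true_labels = truth.layer_labels.loc[kept.obs_names]
print(f"kept {kept.n_obs} barcodes after the UMI filter "
      f"(threshold {kept.uns['umi_threshold']:.0f})")
print(f"layer recovery: {(labels == true_labels).mean():.1%}")

for gene, grad in res["gradients"].items():
    means = ", ".join(f"{k}={v:.2f}" for k, v in grad.layer_means.items())
    print(f"{gene}: {grad.direction} across layers ({means}), "
          f"F = {grad.F:.1f}, p = {grad.p:.2e}")

c = res["contrast"]
print(f"IL36G in PCSK9-high vs PCSK9-low cells: t = {c.t:.2f}, p = {c.p:.2e} "
      f"(means {c.mean_high:.2f} vs {c.mean_low:.2f})")
print("PCSK9 falls and IL36G rises from the basal to the granular layer, "
      "and IL36G is higher in PCSK9-low cells — the opposing epidermal "
      "gradients the pipeline is built to detect.")
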