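"""Linkage-disequilibrium estimation and cross-panel concordance.

Draws two independent cohorts from the same haplotype frequencies — one
standing in for RNA-Seq-derived genotype calls, the other for a
reference panel — computes composite (dosage-correlation) LD in each,
and scores their agreement.
"""

import numpy as np

from varex.ld import ld_concordance, ld_long_table, ld_matrix
from varex.simulate import default_blocks, simulate_genotypes

rng = np.random.default_rng(2)
blocks = default_blocks()
rna_like = ld_matrix(simulate_genotypes(blocks, 2000, rng))
panel_like = ld_matrix(simulate_genotypes(blocks, 2000, rng))

print("RNA-like cohort LD (upper triangle):")
print(ld_long_table(rna_like).round(4).to_string(index=False))

report = ld_concordance(rna_like, panel_like)
print(f"\nconcordance: Pearson r = {report.pearson_r:.4f}, "
      f"MAD(r2) = {report.mad_r2:.4f} over {len(report.shared_ids)} variants")
print("r near 1 and a small mean absolute r2 difference mean the two "
      "genotype sources see the same LD structure around the risk locus, "
      "which is how RNA-derived variant calls are validated against a "
      "gold-standard panel.")
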