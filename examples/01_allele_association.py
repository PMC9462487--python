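"""Case/control allele-count association and meta-analysis.

Simulates two case/control cohorts carrying a risk allele with a true
allelic odds ratio of 2, scans every variant with the allele-counting
OR + Fisher exact test, and pools the causal variant's effect across the
two cohorts with a REML random-effects meta-analysis.
"""

import numpy as np

from varex import run_association
from varex.assoc import AlleleTable, odds_ratio
from varex.meta import StudyEffect, combine
from varex.simulate import assign_phenotypes, default_blocks, simulate_genotypes

rng = np.random.default_rng(1)
effects = []
for label, (n_case, n_control) in {"cohortA": (1000, 1000),
                                   "cohortB": (300, 300)}.items():
    population = simulate_genotypes(default_blocks(), 20000, rng)
    cohort, phenotypes = assign_phenotypes(
        population, "rs662145", allelic_or=2.0, baseline_logit=-4.0,
        n_case=n_case, n_control=n_control, seed=rng, dataset=label)
    scan = run_association(cohort, phenotypes)
    print(f"\n{label} ({n_case}+{n_control}):")
    print(scan[["variant", "or_hat", "p", "p_adj"]].round(4).to_string(index=False))
    row = scan[scan["variant"] == "rs662145"].iloc[0]
    effects.append(StudyEffect(label, row["log_or"], row["se_log_or"] ** 2))

pooled = combine(effects)
lo, hi = pooled.ci()
print(f"\npooled OR = {pooled.odds_ratio:.3f} [{lo:.3f}, {hi:.3f}], "
      f"tau2 = {pooled.tau2:.4f}, Wald p = {pooled.p:.2e}")
print("The causal variant's OR estimates sit near the true value 2; the "
      "pooled diamond tightens the per-cohort intervals. Variants in LD "
      "with the causal site inherit attenuated associations.")
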