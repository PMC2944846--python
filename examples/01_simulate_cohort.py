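"""Simulate a case/control cohort with planted latent-class structure.

The paper-scale preset emulates a two-group candidate-SNP study:
875 cases in 6 latent classes, 367 controls in 5 classes, 46 additively
coded SNPs with ~2% missing genotypes, and clinical phenotypes whose
prevalence depends on the (unobserved) class.
"""

import numpy as np

from snplca import paper_scale_design, simulate_cohort

design = paper_scale_design()
sim = simulate_cohort(design, seed=1)

gm = sim.genotypes
print(f"cohort: {gm.n} individuals x {gm.m} SNPs")
print(f"cases: {sim.cases().n}, controls: {sim.controls().n}")
print(f"mean per-SNP missingness: {gm.missing_rate_per_snp().mean():.3f}")
sizes = np.bincount(sim.true_labels_cases)
print(f"true case-class sizes: {sizes.tolist()}")
print(f"surgery prevalence among cases: "
      f"{sim.phenotypes.df['surgery'].astype(float).mean():.2f}")
# The class sizes mirror the designed mixing proportions; the surgery
# prevalence is a mixture of the per-class designed prevalences.
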