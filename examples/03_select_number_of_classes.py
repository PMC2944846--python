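"""Choose the number of latent classes by parametric-bootstrap LRT.

For k = 1, 2, ... the test simulates B datasets from the fitted k-class
model (re-imposing the observed per-SNP missingness), refits k and k+1
on each, and compares the observed likelihood-ratio statistic to those
replicates.  Selection stops at the first k whose p-value is >= alpha.
"""

from snplca import select_num_classes, simulate_cohort, three_class_demo_design

sim = simulate_cohort(three_class_demo_design(seed=0))
result = select_num_classes(
    sim.cases(), alpha=0.05, k_max=6, B=20, seed=0, em_kwargs=dict(n_starts=10)
)

print("k_null  observed_LR   p")
for t in result.tests:
    print(f"{t.k_null:>6}  {t.observed_lr:>11.1f}   {t.p_value:.3f}")
print(f"chosen number of classes: {result.chosen_k} (3 were planted)")
# Tests at k=1 and k=2 reject (the observed LR dwarfs every bootstrap
# replicate, p = 1/21); the test at k=3 cannot reject, so 3 is chosen.
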