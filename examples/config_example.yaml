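# Annotated pipeline configuration for `reclassify run --config ...`
#
# Exactly one input source: either file paths or a simulation preset.
#
# File input (delimited tables; see README for the formats):
# genotypes_path: cohort_genotypes.csv   # needs a `status` column
# phenotypes_path: cohort_phenotypes.csv # one row per case individual
preset: paper_scale        # built-in synthetic cohort (875/367, 46 SNPs)

alpha: 0.05                # level for the bootstrap LRT stopping rule
bootstrap_B: 20            # bootstrap replicates per k vs k+1 test
k_max: 10                  # safety cap for the stepwise search
# forced_k: 3              # skip selection and fit exactly this k

em:                        # EM settings for every model fit
  n_starts: 10             # random starts (short-run strategy)
  tol: 1.0e-8              # relative log-likelihood convergence
  max_iter: 2000

tree:
  min_split: 20            # smallest node the tree will try to split
  cp: 0.01                 # complexity threshold (fraction of root Gini)

forest:
  n_trees: 500
  # mtry: 3                # default: floor(sqrt(#features))

seed: 11                   # drives every random stage
out_dir: pipeline_output   # report.md/json, models, trees, memberships
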