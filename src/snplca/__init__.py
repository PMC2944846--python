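"""snplca: latent-class reclassification of case/control SNP cohorts.

Clusters individuals from additively coded genotypes with a latent
class model (mixture of independent per-SNP multinomials, EM with
missing data), selects the number of classes by parametric-bootstrap
likelihood-ratio tests, explains clusters with classification trees and
random forests, compares populations through canonical discriminant
analysis with MANOVA, and tests cluster-phenotype associations with
odds ratios and Woolf confidence intervals.
"""

from .data_io import (
    BINARY_PHENOTYPES,
    MISSING,
    GenotypeMatrix,
    PhenotypeTable,
    SnpInfo,
    load_genotypes,
    load_phenotypes,
    orient_to_control_minor,
    write_genotypes,
    write_phenotypes,
)
from .simulate import (
    DesignError,
    SimulatedCohort,
    SimulationDesign,
    apply_missingness_pattern,
    paper_scale_design,
    profiles_from_mafs,
    signature_block_mafs,
    simulate_cohort,
    single_class_null_design,
    three_class_demo_design,
)
from .lca import (
    LatentClassModel,
    MembershipMatrix,
    MembershipSummary,
    em_fit,
    loglikelihood,
    membership_summary,
    posterior_memberships,
    sample_from_model,
)
from .model_selection import (
    BootstrapLRTResult,
    ClusterFlow,
    SelectionResult,
    bootstrap_lrt,
    bootstrap_p_value,
    cluster_flow,
    select_num_classes,
)
from .trees import (
    UNALLOCATED,
    ClassificationTree,
    DropDownReport,
    ForestReport,
    drop_down,
    drop_down_report,
    fit_forest,
    grow_tree,
    predict_many,
)
from .cda import (
    CDAResult,
    ManovaResult,
    fit_cda,
    manova_wilks,
    mean_impute,
    project,
    separation_ratio,
)
from .association import (
    ContingencyResult,
    LogisticFit,
    SeparationError,
    association_table,
    contingency_from_counts,
    fisher_exact,
    logistic_backward,
    odds_ratio_woolf,
    pearson_chi2,
    two_by_two,
)
from .pipeline import PipelineConfig, PipelineResult, run_pipeline

__version__ = "0.1.0"

__all__ = [
    "BINARY_PHENOTYPES",
    "MISSING",
    "UNALLOCATED",
    "GenotypeMatrix",
    "PhenotypeTable",
    "SnpInfo",
    "load_genotypes",
    "load_phenotypes",
    "orient_to_control_minor",
    "write_genotypes",
    "write_phenotypes",
    "DesignError",
    "SimulatedCohort",
    "SimulationDesign",
    "apply_missingness_pattern",
    "paper_scale_design",
    "profiles_from_mafs",
    "signature_block_mafs",
    "simulate_cohort",
    "single_class_null_design",
    "three_class_demo_design",
    "LatentClassModel",
    "MembershipMatrix",
    "MembershipSummary",
    "em_fit",
    "loglikelihood",
    "membership_summary",
    "posterior_memberships",
    "sample_from_model",
    "BootstrapLRTResult",
    "ClusterFlow",
    "SelectionResult",
    "bootstrap_lrt",
    "bootstrap_p_value",
    "cluster_flow",
    "select_num_classes",
    "ClassificationTree",
    "DropDownReport",
    "ForestReport",
    "drop_down",
    "drop_down_report",
    "fit_forest",
    "grow_tree",
    "predict_many",
    "CDAResult",
    "ManovaResult",
    "fit_cda",
    "manova_wilks",
    "mean_impute",
    "project",
    "separation_ratio",
    "ContingencyResult",
    "LogisticFit",
    "SeparationError",
    "association_table",
    "contingency_from_counts",
    "fisher_exact",
    "logistic_backward",
    "odds_ratio_woolf",
    "pearson_chi2",
    "two_by_two",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
]
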