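"""End-to-end case/control reclassification pipeline.

Per group (cases and controls separately): select the number of latent
classes by bootstrap LRT, fit the chosen model, summarize membership
clarity, track cluster flow across the stepwise models, and explain the
clusters with a classification tree audited by drop-down.  Across
groups: canonical discriminant axes are derived in each group, the
control sample is pushed through the case-derived rule, and the case
vs projected-control canonical means are compared by MANOVA.  Finally,
case clusters are tested against clinical phenotypes (2x2 tables,
backward logistic regression, random forest).

Minor-allele orientation always uses the control group, including for
the case-only analyses.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from .cda import CDAResult, ManovaResult, fit_cda, manova_wilks, mean_impute, project, separation_ratio
from .data_io import (
    GenotypeMatrix,
    PhenotypeTable,
    load_genotypes,
    load_phenotypes,
    orient_to_control_minor,
    write_genotypes,
)
from .lca import (
    LatentClassModel,
    MembershipSummary,
    membership_summary,
)
from .model_selection import ClusterFlow, SelectionResult, cluster_flow, select_num_classes
from .simulate import SimulationDesign, paper_scale_design, simulate_cohort
from .trees import ClassificationTree, DropDownReport, drop_down_report, fit_forest, grow_tree


@dataclass
class PipelineConfig:
    """Everything needed to run the full analysis reproducibly."""

    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    design: SimulationDesign | None = None
    preset: str | None = None  # e.g. "paper_scale"
    alpha: float = 0.05
    bootstrap_B: int = 20
    k_max: int = 10
    forced_k: int | None = None  # skip selection; fit exactly this k per group
    em: dict = field(default_factory=lambda: dict(n_starts=20))
    replicate_em: dict = field(default_factory=dict)
    tree: dict = field(default_factory=lambda: dict(min_split=20, cp=0.01))
    forest: dict = field(default_factory=lambda: dict(n_trees=500))
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        has_files = self.genotypes_path is not None
        has_sim = self.design is not None or self.preset is not None
        if has_files == has_sim:
            raise ValueError(
                "config must provide exactly one of input files or a simulation design"
            )
        if has_files:
            for p in (self.genotypes_path, self.phenotypes_path):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class GroupResult:
    name: str
    chosen_k: int
    selection: SelectionResult
    model: LatentClassModel
    assignments: np.ndarray
    membership: MembershipSummary
    flows: list[ClusterFlow]
    tree: ClassificationTree
    dropdown: DropDownReport
    cda: CDAResult | None


def _derive_axes(X: np.ndarray, labels: np.ndarray, n_axes: int = 2) -> CDAResult:
    """Canonical axes, padded with principal axes when fewer are defined.

    With k clusters only k-1 canonical axes exist; a single-cluster
    group has none.  Missing axes are filled with leading principal
    components of the within-cluster residual, scaled to unit pooled
    within variance, so projection and MANOVA remain well defined on
    degenerate configurations.
    """
    groups = np.unique(labels)
    if groups.size >= 2:
        cda = fit_cda(X, labels)
        if cda.r >= n_axes:
            return cda
        base_coef = cda.coefficients
        eig = cda.eigenvalues
        centering = cda.centering
    else:
        base_coef = np.zeros((X.shape[1], 0))
        eig = np.zeros(0)
        centering = X.mean(axis=0)

    # residual after removing group means and existing axes
    Xc = X - centering
    resid = Xc.copy()
    for g in groups:
        resid[labels == g] -= Xc[labels == g].mean(axis=0)
    if base_coef.shape[1]:
        scores = Xc @ base_coef
        # deflate directions already captured (in input space via lstsq)
        proj, *_ = np.linalg.lstsq(scores, resid, rcond=None)
        resid = resid - scores @ proj
    n_extra = n_axes - base_coef.shape[1]
    _, s, vt = np.linalg.svd(resid, full_matrices=False)
    extra = []
    dof = max(X.shape[0] - groups.size, 1)
    for a in range(n_extra):
        v = vt[a]
        within_var = float(((resid @ v) ** 2).sum()) / dof
        extra.append(v / np.sqrt(within_var) if within_var > 0 else v)
    coef = np.column_stack([base_coef] + [np.asarray(extra).T]) if extra else base_coef
    scores = Xc @ coef
    return CDAResult(
        coefficients=coef,
        eigenvalues=np.concatenate([eig, np.zeros(n_extra)]),
        centering=centering,
        group_means={g: scores[labels == g].mean(axis=0) for g in groups},
        groups=list(groups),
        scores=scores,
    )


def _analyze_group(
    gm: GenotypeMatrix, name: str, cfg: PipelineConfig, seed: int
) -> GroupResult:
    if cfg.forced_k is not None:
        from .lca import em_fit

        model, mem = em_fit(gm, cfg.forced_k, seed=seed, **cfg.em)
        selection = SelectionResult(
            chosen_k=cfg.forced_k, tests=[],
            models={cfg.forced_k: model}, memberships={cfg.forced_k: mem},
        )
    else:
        selection = select_num_classes(
            gm,
            alpha=cfg.alpha,
            k_max=cfg.k_max,
            B=cfg.bootstrap_B,
            seed=seed,
            em_kwargs=cfg.em,
            replicate_em_kwargs=cfg.replicate_em,
        )
    k = selection.chosen_k
    model = selection.models[k]
    mem = selection.memberships[k]
    summary = membership_summary(mem)
    flows = [
        cluster_flow(
            selection.memberships[i].assignment, selection.memberships[i + 1].assignment
        )
        for i in range(1, k)
        if i in selection.memberships and i + 1 in selection.memberships
    ]
    tree = grow_tree(gm, mem.assignment, **cfg.tree)
    dropdown = drop_down_report(tree, gm, mem.assignment)
    cda = _derive_axes(mean_impute(gm.values), mem.assignment)
    return GroupResult(
        name=name,
        chosen_k=k,
        selection=selection,
        model=model,
        assignments=mem.assignment,
        membership=summary,
        flows=flows,
        tree=tree,
        dropdown=dropdown,
        cda=cda,
    )


@dataclass
class PipelineResult:
    config: PipelineConfig
    cases: GroupResult
    controls: GroupResult
    manova: ManovaResult
    separation_cases: float
    separation_controls_projected: float
    association: pd.DataFrame
    multivariable: pd.DataFrame
    forest: object  # ForestReport
    seed: int

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        def group_dict(g: GroupResult) -> dict:
            return {
                "chosen_k": g.chosen_k,
                "selection": [
                    {
                        "k_null": t.k_null,
                        "observed_lr": t.observed_lr,
                        "p_value": t.p_value,
                    }
                    for t in g.selection.tests
                ],
                "membership": dataclasses.asdict(g.membership),
                "flows": [f.counts.tolist() for f in g.flows],
                "tree_snps": g.tree.decision_features(),
                "dropdown": {
                    "n_total": g.dropdown.n_total,
                    "n_misclassified": g.dropdown.n_misclassified,
                    "n_unallocated": g.dropdown.n_unallocated,
                },
                "cda_eigenvalues": g.cda.eigenvalues.tolist(),
            }

        return {
            "seed": self.seed,
            "alpha": self.config.alpha,
            "bootstrap_B": self.config.bootstrap_B,
            "cases": group_dict(self.cases),
            "controls": group_dict(self.controls),
            "manova": dataclasses.asdict(self.manova),
            "separation_cases": self.separation_cases,
            "separation_controls_projected": self.separation_controls_projected,
            "association": self.association.to_dict(orient="records"),
            "multivariable": self.multivariable.to_dict(orient="records"),
            "forest": {
                "n_trees": self.forest.n_trees,
                "mtry": self.forest.mtry,
                "oob_error_rate": self.forest.oob_error_rate,
                "importance_mda": self.forest.importance_mda.tolist(),
                "importance_gini": self.forest.importance_gini.tolist(),
                "feature_names": self.forest.feature_names,
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1, default=str)

    def to_markdown(self) -> str:
        lines = ["# Reclassification report", ""]
        for g in (self.cases, self.controls):
            lines += [
                f"## {g.name}",
                f"- chosen number of latent classes: **{g.chosen_k}**",
                f"- membership: {g.membership.n_above_high}/{g.membership.n} "
                f"({100 * g.membership.frac_above_high:.1f}%) with max posterior > "
                f"{g.membership.high}; {g.membership.n_below_low} "
                f"({100 * g.membership.frac_below_low:.1f}%) below {g.membership.low}",
                f"- explanation tree uses SNPs: {', '.join(g.tree.decision_features()) or '(none)'}",
                f"- drop-down: {g.dropdown.n_misclassified} misclassified "
                f"({100 * g.dropdown.misclassified_fraction:.1f}%), "
                f"{g.dropdown.n_unallocated} unallocated "
                f"({100 * g.dropdown.unallocated_fraction:.1f}%)",
                "",
            ]
        lines += [
            "## Cross-population comparison",
            f"- Wilks' lambda = {self.manova.wilks_lambda:.4g}, "
            f"F({self.manova.df_num:.0f}, {self.manova.df_den:.1f}) = "
            f"{self.manova.f_stat:.2f}, p = {self.manova.p_value:.3g}",
            f"- between/within separation on case axes: cases "
            f"{self.separation_cases:.3f} vs projected controls "
            f"{self.separation_controls_projected:.3f}",
            "",
            "## Cluster-phenotype association (top rows)",
            self.association.head(12).to_string(index=False),
            "",
            f"## Random forest (clinical -> cluster): OOB error "
            f"{self.forest.oob_error_rate:.4f}",
            "",
        ]
        return "\n".join(lines)


def _clinical_features(pheno: PhenotypeTable):
    """Impute clinical variables for the forest (mode / median)."""
    binary = pheno.binary_view()
    feats = {}
    types = []
    names = []
    for col in binary.columns:
        vals = binary[col].astype(float)
        mode = vals.mode(dropna=True)
        fill = float(mode.iloc[0]) if len(mode) else 0.0
        feats[col] = vals.fillna(fill).to_numpy()
        names.append(col)
        types.append("categorical")
    age = pheno.df["age_at_diagnosis"].astype(float)
    feats["age_at_diagnosis"] = age.fillna(age.median()).to_numpy()
    names.append("age_at_diagnosis")
    types.append("numeric")
    X = np.column_stack([feats[n] for n in names])
    return X, names, types


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; writes artifacts when out_dir is set."""
    ss = np.random.SeedSequence(config.seed)
    s_sim, s_cases, s_controls, s_forest = (_seed_int(c) for c in ss.spawn(4))

    if config.design is not None or config.preset is not None:
        design = config.design
        if design is None:
            if config.preset != "paper_scale":
                raise ValueError(f"unknown preset {config.preset!r}")
            design = paper_scale_design()
        sim = simulate_cohort(design, seed=s_sim)
        genotypes = sim.genotypes
        phenotypes = sim.phenotypes
    else:
        genotypes = load_genotypes(config.genotypes_path)
        if genotypes.status is None:
            raise ValueError("genotype file must carry a status column")
        phenotypes = (
            load_phenotypes(config.phenotypes_path)
            if config.phenotypes_path
            else None
        )
        if phenotypes is not None:
            # align phenotype rows with the case individuals
            case_ids = [
                iid
                for iid, st in zip(genotypes.individual_ids, genotypes.status)
                if st == "case"
            ]
            pos = {iid: i for i, iid in enumerate(phenotypes.individual_ids)}
            absent = [iid for iid in case_ids if iid not in pos]
            if absent:
                raise ValueError(
                    f"{len(absent)} case individuals lack phenotype rows "
                    f"(e.g. {absent[0]!r})"
                )
            phenotypes = PhenotypeTable(
                phenotypes.df.iloc[[pos[i] for i in case_ids]].reset_index(drop=True)
            )

    control_ids = [
        iid
        for iid, st in zip(genotypes.individual_ids, genotypes.status)
        if st == "control"
    ]
    oriented = orient_to_control_minor(genotypes, control_ids)
    gm_cases = oriented.by_status("case")
    gm_controls = oriented.by_status("control")

    cases = _analyze_group(gm_cases, "cases", config, s_cases)
    controls = _analyze_group(gm_controls, "controls", config, s_controls)

    # analysis 2: controls through the case-derived discriminant rule
    X_controls = mean_impute(gm_controls.values)
    proj_controls = project(cases.cda, X_controls)[:, :2]
    case_scores = cases.cda.scores[:, :2]
    manova = manova_wilks(case_scores, proj_controls)
    sep_cases = separation_ratio(case_scores, cases.assignments)
    sep_controls = separation_ratio(proj_controls, controls.assignments)

    # cluster vs phenotype association (cases)
    if phenotypes is not None:
        binary = phenotypes.binary_view()
        table = assoc.association_table(cases.assignments, binary)
        multi = _multivariable(cases.assignments, binary)
        feats, names, types = _clinical_features(phenotypes)
        forest = fit_forest(
            feats,
            cases.assignments,
            seed=s_forest,
            feature_types=types,
            feature_names=names,
            **config.forest,
        )
    else:
        table = pd.DataFrame()
        multi = pd.DataFrame()
        forest = None

    result = PipelineResult(
        config=config,
        cases=cases,
        controls=controls,
        manova=manova,
        separation_cases=sep_cases,
        separation_controls_projected=sep_controls,
        association=table,
        multivariable=multi,
        forest=forest,
        seed=config.seed,
    )
    if config.out_dir:
        _write_artifacts(result, oriented, Path(config.out_dir))
    return result


def _multivariable(assignments, binary: pd.DataFrame, screen_p: float = 0.1) -> pd.DataFrame:
    """Backward logistic models per phenotype, screened at univariate p<0.1."""
    rows = []
    clusters = np.unique(assignments)
    indicators = pd.DataFrame(
        {f"cluster_{c}": (assignments == c).astype(float) for c in clusters}
    )
    for col in binary.columns:
        keep = []
        for c in clusters:
            try:
                res = assoc.two_by_two(assignments, c, binary[col])
            except ValueError:
                continue
            if res.chi2_p < screen_p:
                keep.append(f"cluster_{c}")
        if not keep:
            continue
        y = binary[col].astype(float)
        obs = y.notna().to_numpy()
        try:
            fit = assoc.logistic_backward(
                indicators.loc[obs, keep], y.to_numpy(dtype=float)[obs]
            )
        except assoc.SeparationError as exc:
            warnings.warn(f"multivariable model for {col!r} skipped: {exc}")
            continue
        for _, r in fit.retained.iterrows():
            rows.append({"phenotype": col, **r.to_dict()})
    return pd.DataFrame(rows)


def _write_artifacts(result: PipelineResult, oriented: GenotypeMatrix, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(result.to_json())
    (out / "report.md").write_text(result.to_markdown())
    write_genotypes(oriented, out / "genotypes_oriented.csv")
    for g in (result.cases, result.controls):
        (out / f"model_{g.name}.json").write_text(g.model.to_json())
        (out / f"tree_{g.name}.txt").write_text(g.tree.to_text())
        (out / f"tree_{g.name}.json").write_text(
            json.dumps(g.tree.to_dict(), sort_keys=True, default=str)
        )
        mem = pd.DataFrame(
            g.selection.memberships[g.chosen_k].posterior,
            columns=[f"class_{i}" for i in range(g.chosen_k)],
        )
        mem.insert(0, "assignment", g.assignments)
        mem.to_csv(out / f"memberships_{g.name}.csv", index=False)
        for i, flow in enumerate(g.flows, start=1):
            pd.DataFrame(flow.counts).to_csv(
                out / f"flow_{g.name}_k{i}_to_k{i+1}.csv", index=False
            )
    if len(result.association):
        result.association.to_csv(out / "association.csv", index=False)
    if len(result.multivariable):
        result.multivariable.to_csv(out / "multivariable.csv", index=False)
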