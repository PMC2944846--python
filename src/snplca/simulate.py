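"""Synthetic case/control cohorts with planted latent-class structure.

Each individual belongs to one latent class drawn from the group's
mixing proportions; given the class, genotypes at each SNP are drawn
independently from the class's 3-category genotype profile, entries are
masked missing-completely-at-random, and binary clinical phenotypes are
drawn from class-conditional prevalences (phenotypes are independent of
genotype given the class).  Everything is reproducible from the design
seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (
    BINARY_PHENOTYPES,
    MISSING,
    GenotypeMatrix,
    PhenotypeTable,
    SnpInfo,
)

_SIMPLEX_TOL = 1e-12


class DesignError(ValueError):
    """An invalid simulation design (non-simplex weights, bad rates...)."""


def _check_simplex(arr: np.ndarray, name: str, axis: int = -1) -> None:
    arr = np.asarray(arr, dtype=float)
    if (arr < 0).any():
        raise DesignError(f"{name} has negative entries")
    sums = arr.sum(axis=axis)
    if not np.allclose(sums, 1.0, atol=_SIMPLEX_TOL, rtol=0.0):
        raise DesignError(f"{name} rows must sum to 1 within {_SIMPLEX_TOL}")


def profiles_from_mafs(per_class_mafs: np.ndarray) -> np.ndarray:
    """Genotype-category probabilities under Hardy-Weinberg proportions.

    Maps a (k, m) array of per-class minor-allele frequencies p to a
    (k, m, 3) array of probabilities ((1-p)^2, 2p(1-p), p^2).
    """
    p = np.asarray(per_class_mafs, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise DesignError("minor-allele frequencies must lie in [0, 1]")
    q = 1.0 - p
    return np.stack([q * q, 2.0 * p * q, p * p], axis=-1)


@dataclass
class SimulationDesign:
    """Full specification of a two-group cohort simulation."""

    n_cases: int
    n_controls: int
    m_snps: int
    k_cases: int
    k_controls: int
    mixing_cases: np.ndarray
    mixing_controls: np.ndarray
    profiles_cases: np.ndarray  # (k_cases, m, 3)
    profiles_controls: np.ndarray  # (k_controls, m, 3)
    missing_rate: np.ndarray | float = 0.0  # scalar or per-SNP vector
    male_prev_cases: np.ndarray | None = None  # (k_cases,)
    location_probs_cases: np.ndarray | None = None  # (k_cases, 3) colon/ileum/ileocolonic
    phenotype_prev_cases: dict[str, np.ndarray] = field(default_factory=dict)
    phenotype_missing_rate: float = 0.0
    age_median: float = 24.0
    age_log_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "m_snps", "k_cases", "k_controls"):
            if getattr(self, name) < 1:
                raise DesignError(f"{name} must be positive")
        self.mixing_cases = np.asarray(self.mixing_cases, dtype=float)
        self.mixing_controls = np.asarray(self.mixing_controls, dtype=float)
        if self.mixing_cases.shape != (self.k_cases,):
            raise DesignError("mixing_cases has wrong length")
        if self.mixing_controls.shape != (self.k_controls,):
            raise DesignError("mixing_controls has wrong length")
        _check_simplex(self.mixing_cases, "mixing_cases")
        _check_simplex(self.mixing_controls, "mixing_controls")
        self.profiles_cases = np.asarray(self.profiles_cases, dtype=float)
        self.profiles_controls = np.asarray(self.profiles_controls, dtype=float)
        if self.profiles_cases.shape != (self.k_cases, self.m_snps, 3):
            raise DesignError("profiles_cases must have shape (k_cases, m, 3)")
        if self.profiles_controls.shape != (self.k_controls, self.m_snps, 3):
            raise DesignError("profiles_controls must have shape (k_controls, m, 3)")
        _check_simplex(self.profiles_cases, "profiles_cases")
        _check_simplex(self.profiles_controls, "profiles_controls")
        self.missing_rate = np.broadcast_to(
            np.asarray(self.missing_rate, dtype=float), (self.m_snps,)
        ).copy()
        if (self.missing_rate < 0).any() or (self.missing_rate > 1).any():
            raise DesignError("missing_rate must lie in [0, 1]")
        if self.male_prev_cases is not None:
            self.male_prev_cases = np.asarray(self.male_prev_cases, dtype=float)
            if self.male_prev_cases.shape != (self.k_cases,):
                raise DesignError("male_prev_cases has wrong length")
        if self.location_probs_cases is not None:
            self.location_probs_cases = np.asarray(
                self.location_probs_cases, dtype=float
            )
            if self.location_probs_cases.shape != (self.k_cases, 3):
                raise DesignError("location_probs_cases must be (k_cases, 3)")
            _check_simplex(self.location_probs_cases, "location_probs_cases")
        for name, prev in self.phenotype_prev_cases.items():
            prev = np.asarray(prev, dtype=float)
            if prev.shape != (self.k_cases,):
                raise DesignError(f"prevalence vector for {name!r} has wrong length")
            if (prev < 0).any() or (prev > 1).any():
                raise DesignError(f"prevalences for {name!r} must lie in [0, 1]")
            self.phenotype_prev_cases[name] = prev
        if not 0.0 <= self.phenotype_missing_rate <= 1.0:
            raise DesignError("phenotype_missing_rate must lie in [0, 1]")


@dataclass
class SimulatedCohort:
    """Output bundle of :func:`simulate_cohort`."""

    genotypes: GenotypeMatrix  # cases first, then controls; status set
    true_labels_cases: np.ndarray
    true_labels_controls: np.ndarray
    phenotypes: PhenotypeTable  # cases only

    def cases(self) -> GenotypeMatrix:
        return self.genotypes.by_status("case")

    def controls(self) -> GenotypeMatrix:
        return self.genotypes.by_status("control")


def _sample_categorical(rng, probs_rows: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw; probs_rows is (..., c)."""
    cum = np.cumsum(probs_rows, axis=-1)
    u = rng.random(probs_rows.shape[:-1])
    return (u[..., None] > cum).sum(axis=-1).astype(np.int8)


def _simulate_group(rng, n, mixing, profiles) -> tuple[np.ndarray, np.ndarray]:
    labels = rng.choice(len(mixing), size=n, p=mixing)
    geno = _sample_categorical(rng, profiles[labels])  # (n, m)
    return geno, labels


def apply_missingness_pattern(
    gm: GenotypeMatrix, per_snp_rates, seed: int | None = None
) -> GenotypeMatrix:
    """Mask entries MCAR at the given per-SNP rates; returns a copy."""
    rates = np.asarray(per_snp_rates, dtype=float)
    if rates.shape != (gm.m,):
        raise DesignError(f"rate vector has length {rates.size}, expected {gm.m}")
    if (rates < 0).any() or (rates > 1).any():
        raise DesignError("missingness rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random((gm.n, gm.m)) < rates[None, :]
    values = gm.values.copy()
    values[mask] = MISSING
    return GenotypeMatrix(
        individual_ids=list(gm.individual_ids),
        snps=list(gm.snps),
        values=values,
        status=None if gm.status is None else gm.status.copy(),
    )


def simulate_cohort(design: SimulationDesign, seed: int | None = None) -> SimulatedCohort:
    """Draw one cohort from the design (deterministic given the seed).

    Cases precede controls in the returned genotype matrix; the
    ``status`` column distinguishes them.  Clinical phenotypes are
    generated for cases only, with prevalences conditioned on the true
    latent class.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    m = design.m_snps

    geno_cases, lab_cases = _simulate_group(
        rng, design.n_cases, design.mixing_cases, design.profiles_cases
    )
    geno_ctrl, lab_ctrl = _simulate_group(
        rng, design.n_controls, design.mixing_controls, design.profiles_controls
    )
    values = np.vstack([geno_cases, geno_ctrl])
    miss = rng.random(values.shape) < design.missing_rate[None, :]
    values[miss] = MISSING

    ids = [f"case_{i+1:04d}" for i in range(design.n_cases)] + [
        f"ctrl_{i+1:04d}" for i in range(design.n_controls)
    ]
    status = np.array(
        ["case"] * design.n_cases + ["control"] * design.n_controls, dtype=object
    )
    snps = [
        SnpInfo(snp_id=f"SNP_{j+1:03d}", locus_label=f"locus_{j+1:03d}")
        for j in range(m)
    ]
    gm = GenotypeMatrix(individual_ids=ids, snps=snps, values=values, status=status)

    phenotypes = _simulate_phenotypes(rng, design, lab_cases, ids[: design.n_cases])
    return SimulatedCohort(
        genotypes=gm,
        true_labels_cases=lab_cases,
        true_labels_controls=lab_ctrl,
        phenotypes=phenotypes,
    )


def _simulate_phenotypes(rng, design, labels, ids) -> PhenotypeTable:
    n = len(labels)
    k = design.k_cases
    male_prev = (
        design.male_prev_cases
        if design.male_prev_cases is not None
        else np.full(k, 0.5)
    )
    loc_probs = (
        design.location_probs_cases
        if design.location_probs_cases is not None
        else np.full((k, 3), 1.0 / 3.0)
    )
    df = pd.DataFrame({"individual_id": ids})
    df["gender"] = np.where(rng.random(n) < male_prev[labels], "male", "female")
    ages = np.exp(rng.normal(np.log(design.age_median), design.age_log_sd, size=n))
    df["age_at_diagnosis"] = np.round(ages, 1)
    loc_draw = _sample_categorical(rng, loc_probs[labels])
    df["location"] = np.array(["colon", "ileum", "ileocolonic"], dtype=object)[loc_draw]
    for col in BINARY_PHENOTYPES:
        prev = design.phenotype_prev_cases.get(col)
        if prev is None:
            prev = np.full(k, 0.3)
        df[col] = pd.array(
            (rng.random(n) < prev[labels]).astype(int), dtype="Int64"
        )
    if design.phenotype_missing_rate > 0:
        for col in ("gender", "location") + BINARY_PHENOTYPES:
            mask = rng.random(n) < design.phenotype_missing_rate
            df.loc[mask, col] = pd.NA
        mask = rng.random(n) < design.phenotype_missing_rate
        df.loc[mask, "age_at_diagnosis"] = np.nan
    for col in BINARY_PHENOTYPES:
        df[col] = df[col].astype("Int64")
    return PhenotypeTable(df)


# ----------------------------------------------------------------------
# paper-scale preset
# ----------------------------------------------------------------------

#: published cluster sizes of the 875-patient cohort (clusters A..F)
_CASE_CLUSTER_SIZES = np.array([302, 96, 62, 117, 59, 239], dtype=float)

#: per-cluster clinical prevalences from the published characteristics table
_PRESET_PHENOTYPE_PREV = {
    "anal": [0.39, 0.34, 0.42, 0.44, 0.25, 0.37],
    "inflammatory": [0.48, 0.59, 0.37, 0.51, 0.51, 0.49],
    "stenosing": [0.38, 0.34, 0.50, 0.31, 0.31, 0.40],
    "non_perianal_fistulae": [0.27, 0.17, 0.29, 0.28, 0.27, 0.26],
    "perianal_fistulae": [0.29, 0.32, 0.42, 0.29, 0.29, 0.31],
    "surgery": [0.57, 0.56, 0.73, 0.53, 0.53, 0.54],
}

_PRESET_MALE_PREV = [0.40, 0.46, 0.48, 0.44, 0.42, 0.37]

_PRESET_LOCATION_COUNTS = [
    (34, 107, 161),
    (15, 36, 44),
    (3, 32, 27),
    (17, 46, 54),
    (9, 19, 31),
    (35, 86, 116),
]

#: fixed design constant; NOT a tunable seed (cohort randomness comes
#: from SimulationDesign.seed)
_PRESET_PROFILE_RNG = 20100923


def signature_block_mafs(
    k: int,
    m: int,
    rng: np.random.Generator,
    base_low: float = 0.08,
    base_high: float = 0.20,
    signature_maf: float = 0.45,
) -> np.ndarray:
    """Per-class MAFs with round-robin signature SNP blocks.

    All classes share a common baseline MAF per SNP; SNP j is the
    signature of class ``j mod k``, where that class's MAF is raised to
    ``signature_maf``.  Any two classes then differ at ~2m/k SNPs, which
    guarantees a minimum separation between every pair — a structure an
    iid draw does not provide (chance near-duplicate classes make the
    smallest classes statistically unidentifiable at cohort scale).
    """
    base = rng.uniform(base_low, base_high, size=m)
    mafs = np.tile(base, (k, 1))
    for j in range(m):
        mafs[j % k, j] = signature_maf
    return mafs


def three_class_demo_design(seed: int = 0, n: int = 2000) -> SimulationDesign:
    """Well-separated 3-class cohort used for parameter-recovery checks.

    Six SNPs; every class carries a mostly-major-homozygote baseline
    profile (0.85, 0.10, 0.05) and swaps to a minor-homozygote-enriched
    profile (0.05, 0.10, 0.85) on its round-robin signature block, so
    any two classes differ sharply at >= 4 SNPs.  The profiles
    deliberately avoid genotype categories near probability 0.5, which
    keeps the sampling error of every estimated category probability
    small at cohort scale.  Equal mixing; 5% MCAR missingness.
    """
    k, m = 3, 6
    base = np.array([0.85, 0.10, 0.05])
    sig = np.array([0.05, 0.10, 0.85])
    prof = np.tile(base, (k, m, 1))
    for j in range(m):
        prof[j % k, j] = sig
    return SimulationDesign(
        n_cases=n,
        n_controls=2,
        m_snps=m,
        k_cases=k,
        k_controls=1,
        mixing_cases=np.full(k, 1.0 / k),
        mixing_controls=np.array([1.0]),
        profiles_cases=prof,
        profiles_controls=profiles_from_mafs(np.full((1, m), 0.1)),
        missing_rate=0.05,
        seed=seed,
    )


def single_class_null_design(seed: int = 0, n: int = 500, m: int = 10) -> SimulationDesign:
    """Homogeneous (1-class) cohort for null calibration of the LRT.

    Per-SNP minor-allele frequencies are a fixed draw from U(0.1, 0.4)
    under Hardy-Weinberg proportions; 3% MCAR missingness.
    """
    rng = np.random.default_rng(4242)  # design constant, not a data seed
    mafs = rng.uniform(0.1, 0.4, size=(1, m))
    return SimulationDesign(
        n_cases=n,
        n_controls=2,
        m_snps=m,
        k_cases=1,
        k_controls=1,
        mixing_cases=np.array([1.0]),
        mixing_controls=np.array([1.0]),
        profiles_cases=profiles_from_mafs(mafs),
        profiles_controls=profiles_from_mafs(np.full((1, m), 0.2)),
        missing_rate=0.03,
        seed=seed,
    )


def paper_scale_design(seed: int = 0) -> SimulationDesign:
    """Preset mirroring the published cohort's scale and structure.

    875 cases in 6 latent classes (class sizes proportional to the
    published cluster sizes A-F), 367 controls in 5 classes, 46 SNPs,
    2% per-entry missingness.  Per-class minor-allele frequencies follow
    the signature-block construction (a fixed draw, under Hardy-Weinberg
    proportions) — a synthetic panel, not the published one.  Clinical
    prevalences per case class follow the published characteristics
    table.
    """
    m, k_cases, k_controls = 46, 6, 5
    rng = np.random.default_rng(_PRESET_PROFILE_RNG)
    mafs_cases = signature_block_mafs(k_cases, m, rng)
    mafs_controls = signature_block_mafs(k_controls, m, rng)
    loc = np.asarray(_PRESET_LOCATION_COUNTS, dtype=float)
    loc_probs = loc / loc.sum(axis=1, keepdims=True)
    return SimulationDesign(
        n_cases=875,
        n_controls=367,
        m_snps=m,
        k_cases=k_cases,
        k_controls=k_controls,
        mixing_cases=_CASE_CLUSTER_SIZES / _CASE_CLUSTER_SIZES.sum(),
        mixing_controls=np.array([0.30, 0.25, 0.20, 0.15, 0.10]),
        profiles_cases=profiles_from_mafs(mafs_cases),
        profiles_controls=profiles_from_mafs(mafs_controls),
        missing_rate=0.02,
        male_prev_cases=np.asarray(_PRESET_MALE_PREV),
        location_probs_cases=loc_probs,
        phenotype_prev_cases={
            k: np.asarray(v) for k, v in _PRESET_PHENOTYPE_PREV.items()
        },
        phenotype_missing_rate=0.004,
        seed=seed,
    )
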