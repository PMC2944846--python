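"""Choosing the number of latent classes by parametric-bootstrap LRT.

The test of "k classes suffice" against "k+1 classes" compares the
observed likelihood-ratio statistic 2*(ll_{k+1} - ll_k) to its
distribution over datasets simulated from the *fitted* k-class model
(a parametric bootstrap).  Per replicate, per-SNP missingness is
re-imposed at the rates observed in the original sample, so the null
datasets carry the same percentages of missingness.  The p-value uses
the standard (1 + #{boot >= observed}) / (B + 1) estimator.

Model building proceeds stepwise: k = 1, 2, ... until the first test
that fails to reject (p >= alpha), and individuals can be tracked as
they redistribute between successive models via cross-tabulation
("cluster flow").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import MISSING, GenotypeMatrix
from .lca import (
    LatentClassModel,
    MembershipMatrix,
    em_fit,
    sample_from_model,
    split_class_init,
)



@dataclass
class BootstrapLRTResult:
    k_null: int
    k_alt: int
    observed_lr: float
    bootstrap_lrs: np.ndarray
    p_value: float
    B: int
    seed: int | None

    def __post_init__(self) -> None:
        self.bootstrap_lrs = np.asarray(self.bootstrap_lrs, dtype=float)
        if self.bootstrap_lrs.shape != (self.B,):
            raise ValueError("bootstrap_lrs must have length B")


def bootstrap_p_value(observed_lr: float, bootstrap_lrs) -> float:
    """(1 + #{boot >= observed}) / (B + 1); always in (0, 1]."""
    boots = np.asarray(bootstrap_lrs, dtype=float)
    return float((1 + (boots >= observed_lr).sum()) / (boots.size + 1))


def _seed_from(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def bootstrap_lrt(
    data,
    k_null: int,
    B: int = 20,
    seed: int | None = None,
    em_kwargs: dict | None = None,
    replicate_em_kwargs: dict | None = None,
    missingness: str = "rates",
    null_fit: tuple[LatentClassModel, MembershipMatrix] | None = None,
    alt_fit: tuple[LatentClassModel, MembershipMatrix] | None = None,
) -> BootstrapLRTResult:
    """Parametric-bootstrap LRT of k_null vs k_null + 1 classes.

    ``missingness="rates"`` re-imposes per-SNP MCAR missingness at the
    original per-SNP rates on every replicate; ``"pattern"`` copies the
    original entry-level missing mask instead.  Precomputed fits of the
    null/alternative models may be passed to avoid refitting.

    Replicate refits default to the *same* EM settings as the observed
    fits: the test compares the observed statistic to replicate
    statistics produced by an identical procedure, and an asymmetric
    (cheaper or more thorough) replicate optimizer would bias the
    comparison.  ``replicate_em_kwargs`` can still override this.
    All fits are additionally warm-started from the nested model.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if k_null < 1:
        raise ValueError("k_null must be >= 1")
    if missingness not in ("rates", "pattern"):
        raise ValueError("missingness must be 'rates' or 'pattern'")
    values = data.values if isinstance(data, GenotypeMatrix) else np.asarray(data)
    n, m = values.shape
    em_kwargs = dict(em_kwargs or {})
    rep_kwargs = dict(em_kwargs if replicate_em_kwargs is None else replicate_em_kwargs)

    ss = np.random.SeedSequence(seed)
    ss_null, ss_alt, ss_boot = ss.spawn(3)
    if null_fit is None:
        null_fit = em_fit(data, k_null, seed=_seed_from(ss_null), **em_kwargs)
    null_model, _ = null_fit
    if alt_fit is None:
        alt_fit = em_fit(
            data,
            k_null + 1,
            seed=_seed_from(ss_alt),
            extra_inits=[
                split_class_init(null_model, np.random.default_rng(ss_alt))
            ],
            **em_kwargs,
        )
    alt_model, _ = alt_fit
    observed_lr = 2.0 * (alt_model.log_likelihood - null_model.log_likelihood)

    if (null_model.mixing < 1.0 / n).any():
        warnings.warn(
            f"fitted {k_null}-class null has a near-empty class "
            "(mixing proportion below 1/n); bootstrap replicates still drawn"
        )

    miss_rates = (values == MISSING).mean(axis=0)
    miss_mask = values == MISSING
    boot_lrs = np.empty(B)
    for b, child in enumerate(ss_boot.spawn(B)):
        rng = np.random.default_rng(child)
        sim, _ = sample_from_model(null_model, n, rng)
        if missingness == "rates":
            mask = rng.random((n, m)) < miss_rates[None, :]
        else:
            mask = miss_mask
        sim[mask] = MISSING
        s0, s1 = child.spawn(2)
        # warm starts from the generating model stabilize the refits:
        # a replicate fit stuck in a poor local optimum would otherwise
        # inject a spurious outlier into the null LR distribution
        m0, _ = em_fit(
            sim, k_null, seed=_seed_from(s0),
            extra_inits=[(null_model.mixing, null_model.category_probs)],
            **rep_kwargs,
        )
        m1, _ = em_fit(
            sim, k_null + 1, seed=_seed_from(s1),
            extra_inits=[split_class_init(null_model, np.random.default_rng(s1))],
            **rep_kwargs,
        )
        boot_lrs[b] = 2.0 * (m1.log_likelihood - m0.log_likelihood)

    return BootstrapLRTResult(
        k_null=k_null,
        k_alt=k_null + 1,
        observed_lr=observed_lr,
        bootstrap_lrs=boot_lrs,
        p_value=bootstrap_p_value(observed_lr, boot_lrs),
        B=B,
        seed=seed,
    )


@dataclass
class SelectionResult:
    """Outcome of stepwise class-count selection."""

    chosen_k: int
    tests: list[BootstrapLRTResult]
    models: dict[int, LatentClassModel] = field(default_factory=dict)
    memberships: dict[int, MembershipMatrix] = field(default_factory=dict)
    exhausted: bool = False


def select_num_classes(
    data,
    alpha: float = 0.05,
    k_max: int = 10,
    B: int = 20,
    seed: int | None = None,
    em_kwargs: dict | None = None,
    replicate_em_kwargs: dict | None = None,
    missingness: str = "rates",
) -> SelectionResult:
    """Stepwise bootstrap-LRT selection of the number of latent classes.

    Tests k vs k+1 for k = 1, 2, ... and stops at the first k whose
    p-value is >= alpha (that k is chosen).  If every test up to k_max-1
    rejects, k_max is returned with a warning.  ``alpha >= 1`` accepts
    k = 1 immediately: the bootstrap p-value estimator only reaches 1.0
    when every replicate beats the observed statistic, so no rejection
    is possible at that level.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    em_kwargs = dict(em_kwargs or {})
    ss = np.random.SeedSequence(seed)
    fit_seeds = ss.spawn(k_max + 1)
    test_seeds = ss.spawn(k_max + 1)

    result = SelectionResult(chosen_k=1, tests=[])

    def fit(k: int):
        if k not in result.models:
            extra = (
                [
                    split_class_init(
                        result.models[k - 1],
                        np.random.default_rng(fit_seeds[k - 1]),
                    )
                ]
                if k - 1 in result.models
                else None
            )
            model, mem = em_fit(
                data, k, seed=_seed_from(fit_seeds[k - 1]),
                extra_inits=extra, **em_kwargs
            )
            result.models[k] = model
            result.memberships[k] = mem
        return result.models[k], result.memberships[k]

    if alpha >= 1.0:
        fit(1)
        result.chosen_k = 1
        return result

    for k in range(1, k_max + 1):
        if k == k_max:
            warnings.warn(
                f"all tests up to k_max={k_max} rejected; returning k_max"
            )
            result.chosen_k = k_max
            result.exhausted = True
            return result
        test = bootstrap_lrt(
            data,
            k_null=k,
            B=B,
            seed=_seed_from(test_seeds[k - 1]),
            em_kwargs=em_kwargs,
            replicate_em_kwargs=replicate_em_kwargs,
            missingness=missingness,
            null_fit=fit(k),
            alt_fit=fit(k + 1),
        )
        result.tests.append(test)
        if test.p_value >= alpha:
            result.chosen_k = k
            return result
    return result  # pragma: no cover


# ----------------------------------------------------------------------
# cluster flow between successive models
# ----------------------------------------------------------------------

@dataclass
class ClusterFlow:
    """Joint cross-tabulation of assignments under two nested models."""

    counts: np.ndarray  # (k_i, k_i1)
    sizes_i: np.ndarray
    sizes_i1: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def cluster_flow(labels_i, labels_i1) -> ClusterFlow:
    """Count individuals flowing from clusters of Model i to Model i+1."""
    a = np.asarray(labels_i)
    b = np.asarray(labels_i1)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(
            f"label vectors must be 1-D and equal length, got {a.shape} vs {b.shape}"
        )
    ka = int(a.max()) + 1 if a.size else 0
    kb = int(b.max()) + 1 if b.size else 0
    counts = np.zeros((ka, kb), dtype=int)
    np.add.at(counts, (a, b), 1)
    return ClusterFlow(
        counts=counts,
        sizes_i=counts.sum(axis=1),
        sizes_i1=counts.sum(axis=0),
    )
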