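"""Canonical discriminant analysis and MANOVA group comparison.

Canonical discriminant analysis finds linear combinations of the coded
genotypes that maximize between-cluster relative to within-cluster
variation: the generalized eigenproblem B v = lambda W v with B the
between-group and W the pooled within-group scatter.  Axes are scaled
so the pooled within-group variance of each canonical variable is 1,
and scores are centered at the derivation sample's overall mean — so
derivation-sample canonical means are 0 up to floating-point noise.

A second population can be pushed through a derivation population's
rule unchanged (centering and coefficients frozen), and the canonical
means of the two populations compared by a Wilks' lambda MANOVA with
Rao's F approximation (exact for two groups).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats


@dataclass
class CDAResult:
    coefficients: np.ndarray  # (m, r): centered inputs -> canonical variables
    eigenvalues: np.ndarray  # (r,), non-increasing, >= 0
    centering: np.ndarray  # (m,) derivation-sample mean
    group_means: dict  # label -> (r,) canonical means
    groups: list
    derivation_label: str = ""
    scores: np.ndarray | None = None  # derivation-sample scores (n, r)

    @property
    def r(self) -> int:
        return self.coefficients.shape[1]


def _scatter_matrices(X: np.ndarray, labels: np.ndarray):
    groups = np.unique(labels)
    mu = X.mean(axis=0)
    m = X.shape[1]
    W = np.zeros((m, m))
    B = np.zeros((m, m))
    for g in groups:
        Xg = X[labels == g]
        mg = Xg.mean(axis=0)
        D = Xg - mg
        W += D.T @ D
        d = (mg - mu)[:, None]
        B += Xg.shape[0] * (d @ d.T)
    return W, B, mu, groups


def fit_cda(data, labels, derivation_label: str = "") -> CDAResult:
    """Fit canonical discriminant axes for cluster labels.

    ``data`` is an (n, m) numeric matrix (coded genotypes with missing
    entries already resolved, e.g. mean-imputed).  Requires >= 2 groups
    of >= 2 members each.  A singular within-group scatter is ridged
    with eps = 1e-8 * trace(W)/m on the diagonal (with a warning).
    """
    X = np.asarray(data, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("data must be 2-D")
    if y.shape != (X.shape[0],):
        raise ValueError("labels length mismatch")
    if np.isnan(X).any():
        raise ValueError("data contains missing values; impute before CDA")
    groups, counts = np.unique(y, return_counts=True)
    if groups.size < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 members")

    n, m = X.shape
    k = groups.size
    W, B, mu, _ = _scatter_matrices(X, y)
    eigs_w = np.linalg.eigvalsh(W)
    if eigs_w[0] <= 1e-12 * max(np.trace(W), 1.0):
        eps = 1e-8 * np.trace(W) / m
        warnings.warn(
            f"within-group scatter is singular; adding ridge {eps:.3e} to the diagonal"
        )
        W = W + eps * np.eye(m)

    eigvals, eigvecs = linalg.eigh(B, W)  # ascending, v' W v = 1
    order = np.argsort(eigvals)[::-1]
    r = min(k - 1, m)
    eigvals = np.clip(eigvals[order][:r], 0.0, None)
    V = eigvecs[:, order][:, :r]
    # pooled within-group covariance of each canonical variable = 1
    V = V * np.sqrt(n - k)
    # deterministic sign: largest-|coefficient| entry positive per axis
    for a in range(r):
        lead = np.argmax(np.abs(V[:, a]))
        if V[lead, a] < 0:
            V[:, a] = -V[:, a]

    scores = (X - mu) @ V
    group_means = {g: scores[y == g].mean(axis=0) for g in groups}
    return CDAResult(
        coefficients=V,
        eigenvalues=eigvals,
        centering=mu,
        group_means=group_means,
        groups=list(groups),
        derivation_label=derivation_label,
        scores=scores,
    )


def project(cda: CDAResult, other) -> np.ndarray:
    """Apply a derivation sample's discriminant rule to another sample.

    Uses the derivation centering and coefficients unchanged; projected
    scores need not be zero-mean.
    """
    X = np.asarray(other, dtype=float)
    if X.ndim != 2 or X.shape[1] != cda.centering.size:
        raise ValueError(
            f"sample has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"derivation panel has {cda.centering.size}"
        )
    if np.isnan(X).any():
        raise ValueError("data contains missing values; impute before projecting")
    return (X - cda.centering) @ cda.coefficients


def separation_ratio(scores: np.ndarray, labels, axes: int = 2) -> float:
    """Between/within variance ratio of the first canonical axes.

    A scalar summary (trace of B relative to trace of W on those axes)
    of how well a set of scores separates the given clusters.
    """
    S = np.asarray(scores, dtype=float)[:, :axes]
    W, B, _, _ = _scatter_matrices(S, np.asarray(labels))
    return float(np.trace(B) / np.trace(W))


@dataclass
class ManovaResult:
    wilks_lambda: float
    f_stat: float
    df_num: float
    df_den: float
    p_value: float


def manova_wilks(scores_a, scores_b) -> ManovaResult:
    """Two-group MANOVA on canonical scores via Wilks' lambda.

    Both inputs are (n_g, p) score matrices on the *same* axes with
    p >= 2 responses and >= 3 members per group.  Rao's F approximation
    is exact for two groups: F = ((1 - L)/L) * (n - p - 1)/p on
    (p, n - p - 1) degrees of freedom.  Symmetric in group order;
    identical groups give lambda = 1, p = 1.
    """
    A = np.atleast_2d(np.asarray(scores_a, dtype=float))
    Bm = np.atleast_2d(np.asarray(scores_b, dtype=float))
    if A.shape[1] != Bm.shape[1]:
        raise ValueError("score matrices must share the response axes")
    p = A.shape[1]
    if p < 2:
        raise ValueError("need at least 2 response columns")
    if A.shape[0] < 3 or Bm.shape[0] < 3:
        raise ValueError("each group needs at least 3 members")

    X = np.vstack([A, Bm])
    y = np.array([0] * A.shape[0] + [1] * Bm.shape[0])
    E, H, _, _ = _scatter_matrices(X, y)  # within (error) and between
    n = X.shape[0]
    g = 2
    lam = float(linalg.det(E) / linalg.det(E + H))
    lam = min(max(lam, np.finfo(float).tiny), 1.0)

    q = g - 1
    v_e = n - g
    denom = p * p + q * q - 5
    if p * p * q * q - 4 > 0 and denom > 0:
        s = np.sqrt((p * p * q * q - 4) / denom)
    else:
        s = 1.0
    df1 = p * q
    df2 = s * (v_e - (p - q + 1) / 2.0) - (p * q - 2) / 2.0
    lam_s = lam ** (1.0 / s)
    f_stat = ((1.0 - lam_s) / lam_s) * (df2 / df1)
    p_value = float(stats.f.sf(f_stat, df1, df2)) if f_stat > 0 else 1.0
    return ManovaResult(
        wilks_lambda=lam, f_stat=float(f_stat), df_num=df1, df_den=float(df2),
        p_value=p_value,
    )


def mean_impute(values: np.ndarray, missing: int = -1) -> np.ndarray:
    """Replace missing coded genotypes by the per-SNP observed mean.

    Used only to prepare input for CDA; the latent class model itself
    never imputes.
    """
    X = np.asarray(values, dtype=float)
    X = np.where(X == missing, np.nan, X)
    col_means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    nan_idx = np.isnan(X)
    X[nan_idx] = np.broadcast_to(col_means, X.shape)[nan_idx]
    return X
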