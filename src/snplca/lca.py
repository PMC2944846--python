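"""Latent class analysis of additively coded genotypes.

The model is a finite mixture of independent per-SNP multinomials:
an individual belongs to latent class k with probability pi_k, and
given the class its genotype at SNP j is category g in {0, 1, 2} with
probability theta[k, j, g], independently across SNPs.  Missing
genotypes are marginalized out (missing-at-random): a missing entry
simply contributes no factor to the class-conditional likelihood, so
all individuals — including those with missing genotypes — are used.

Fitting is by expectation-maximization with multiple random starts.
All per-individual computations run in log space, which keeps products
over dozens of SNPs away from underflow.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data_io import MISSING, GenotypeMatrix

#: stand-in for log(0) that stays finite through matrix products
_NEG = -1.0e30
#: M-step smoothing added to category counts (avoids zero probabilities
#: and hence -inf likelihoods on bootstrap replicates)
_SMOOTH = 1e-10


def _as_values(data) -> np.ndarray:
    if isinstance(data, GenotypeMatrix):
        return data.values
    values = np.asarray(data, dtype=np.int8)
    if values.ndim != 2:
        raise ValueError("genotype data must be 2-D")
    return values


def _one_hot(values: np.ndarray) -> np.ndarray:
    """(n, m) coded genotypes -> (n, 3m) one-hot floats, zero where missing."""
    n, m = values.shape
    observed = values != MISSING
    H = np.zeros((n, m, 3))
    idx_n, idx_m = np.nonzero(observed)
    H[idx_n, idx_m, values[idx_n, idx_m]] = 1.0
    return H.reshape(n, 3 * m)


@dataclass
class LatentClassModel:
    """A fitted (or hand-built) latent class model.

    ``category_probs`` has shape (k, m, 3); ``mixing`` is the k-simplex
    of class proportions.  ``n_params`` counts free parameters:
    k - 1 mixing weights plus 2 free category probabilities per class
    and SNP.
    """

    k: int
    mixing: np.ndarray
    category_probs: np.ndarray
    log_likelihood: float = float("nan")
    converged: bool = False
    n_iterations: int = 0
    seed: int | None = None
    snp_ids: list[str] | None = None
    ll_trace: list[float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.category_probs = np.asarray(self.category_probs, dtype=float)
        if self.mixing.shape != (self.k,):
            raise ValueError("mixing must have length k")
        if self.category_probs.ndim != 3 or self.category_probs.shape[0] != self.k:
            raise ValueError("category_probs must have shape (k, m, 3)")
        if not np.isclose(self.mixing.sum(), 1.0, atol=1e-10):
            raise ValueError("mixing proportions must sum to 1")
        sums = self.category_probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-10):
            raise ValueError("category probabilities must sum to 1 per (class, SNP)")

    @property
    def m(self) -> int:
        return self.category_probs.shape[1]

    @property
    def n_params(self) -> int:
        return self.k - 1 + self.k * self.m * 2

    def permuted(self, order) -> "LatentClassModel":
        """Relabel classes; the likelihood is invariant to this."""
        order = np.asarray(order)
        return LatentClassModel(
            k=self.k,
            mixing=self.mixing[order],
            category_probs=self.category_probs[order],
            log_likelihood=self.log_likelihood,
            converged=self.converged,
            n_iterations=self.n_iterations,
            seed=self.seed,
            snp_ids=self.snp_ids,
        )

    # -- serialization (documented plain-text format) -------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "mixing": self.mixing.tolist(),
                "category_probs": self.category_probs.tolist(),
                "log_likelihood": self.log_likelihood,
                "converged": self.converged,
                "n_iterations": self.n_iterations,
                "seed": self.seed,
                "snp_ids": self.snp_ids,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "LatentClassModel":
        d = json.loads(text)
        return cls(
            k=d["k"],
            mixing=np.array(d["mixing"]),
            category_probs=np.array(d["category_probs"]),
            log_likelihood=d["log_likelihood"],
            converged=d["converged"],
            n_iterations=d["n_iterations"],
            seed=d["seed"],
            snp_ids=d["snp_ids"],
        )


@dataclass
class MembershipMatrix:
    """Posterior class probabilities with hard (argmax) assignments."""

    posterior: np.ndarray  # (n, k), rows sum to 1
    assignment: np.ndarray  # (n,), ties broken toward the lowest index
    max_posterior: np.ndarray  # (n,)

    @classmethod
    def from_posterior(cls, posterior: np.ndarray) -> "MembershipMatrix":
        assignment = np.argmax(posterior, axis=1)
        return cls(
            posterior=posterior,
            assignment=assignment,
            max_posterior=posterior[np.arange(len(posterior)), assignment],
        )


@dataclass
class MembershipSummary:
    """How clear-cut the hard assignments are."""

    n: int
    n_above_high: int
    frac_above_high: float
    n_below_low: int
    frac_below_low: float
    high: float
    low: float


def _log_theta(category_probs: np.ndarray) -> np.ndarray:
    """log of theta flattened to (3m, k); zeros mapped to a huge negative."""
    with np.errstate(divide="ignore"):
        lt = np.log(category_probs)
    lt[~np.isfinite(lt)] = _NEG
    k = category_probs.shape[0]
    return lt.reshape(k, -1).T  # (3m, k)


def _log_joint(model: LatentClassModel, H: np.ndarray) -> np.ndarray:
    """(n, k) array of log pi_k + sum_j log theta[k, j, g_ij] over observed j."""
    return np.log(model.mixing)[None, :] + H @ _log_theta(model.category_probs)


def loglikelihood(model: LatentClassModel, data) -> float:
    """Observed-data log-likelihood sum_i log sum_k pi_k prod_j theta.

    Missing entries contribute no factor; an individual with every
    genotype missing contributes log sum_k pi_k = 0.  If some observed
    category has probability zero under every class, -inf is returned
    with a warning rather than raising.
    """
    values = _as_values(data)
    if values.shape[1] != model.m:
        raise ValueError(
            f"model has {model.m} SNPs but data has {values.shape[1]}"
        )
    L = _log_joint(model, _one_hot(values))
    per_ind = logsumexp(L, axis=1)
    dead = per_ind < _NEG / 2
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} individual(s) have zero probability under the "
            "model; log-likelihood is -inf"
        )
        return float("-inf")
    return float(per_ind.sum())


def posterior_memberships(model: LatentClassModel, data) -> MembershipMatrix:
    """Bayes-rule class memberships over observed entries only."""
    values = _as_values(data)
    if values.shape[1] != model.m:
        raise ValueError("model/data SNP dimension mismatch")
    L = _log_joint(model, _one_hot(values))
    lse = logsumexp(L, axis=1)
    dead = lse < _NEG / 2
    post = np.exp(L - lse[:, None])
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} individual(s) with all-zero unnormalized "
            "posterior; returning uniform membership for them"
        )
        post[dead] = 1.0 / model.k
    return MembershipMatrix.from_posterior(post)


def membership_summary(
    mem: MembershipMatrix, high: float = 0.9, low: float = 0.6
) -> MembershipSummary:
    """Count individuals with max posterior strictly above/below thresholds."""
    if not 0.0 <= low <= high <= 1.0:
        raise ValueError("need 0 <= low <= high <= 1")
    n = len(mem.max_posterior)
    n_hi = int((mem.max_posterior > high).sum())
    n_lo = int((mem.max_posterior < low).sum())
    return MembershipSummary(
        n=n,
        n_above_high=n_hi,
        frac_above_high=n_hi / n if n else float("nan"),
        n_below_low=n_lo,
        frac_below_low=n_lo / n if n else float("nan"),
        high=high,
        low=low,
    )


# ----------------------------------------------------------------------
# EM
# ----------------------------------------------------------------------

def _m_step(R: np.ndarray, H: np.ndarray, n: int, m: int):
    k = R.shape[1]
    counts = (R.T @ H).reshape(k, m, 3)
    denom = counts.sum(axis=2, keepdims=True)
    theta = (counts + _SMOOTH) / (denom + 3 * _SMOOTH)
    pi = (R.sum(axis=0) + _SMOOTH) / (n + k * _SMOOTH)
    return pi, theta


def _e_step(pi, theta, H):
    L = np.log(pi)[None, :] + H @ _log_theta(theta)
    lse = logsumexp(L, axis=1)
    R = np.exp(L - lse[:, None])
    return R, float(lse.sum())


def _run_em(pi, theta, H, n, m, tol, max_iter):
    """Iterate EM from the given parameters; returns the full trace."""
    trace: list[float] = []
    ll_prev = -np.inf
    converged = False
    it = 0
    R, ll = _e_step(pi, theta, H)
    trace.append(ll)
    for it in range(1, max_iter + 1):
        pi, theta = _m_step(R, H, n, m)
        R, ll = _e_step(pi, theta, H)
        trace.append(ll)
        if ll - ll_prev <= tol * abs(ll_prev) and it > 1:
            converged = True
            break
        ll_prev = ll
    return pi, theta, R, ll, it, converged, trace


def em_fit(
    data,
    k: int,
    n_starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int | None = None,
    burn_in: int = 25,
    extra_inits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[LatentClassModel, MembershipMatrix]:
    """Fit a k-class latent class model by multi-start EM.

    Starts are random responsibility matrices (Dirichlet(1) rows); any
    ``extra_inits`` (pi, theta) pairs — e.g. warm starts from a related
    model — join the pool as additional candidates.  When more than one
    candidate exists a short-run strategy is used: every candidate runs
    ``burn_in`` iterations and only the best by log-likelihood is
    refined to convergence (relative log-likelihood change below
    ``tol`` or ``max_iter`` iterations).  The log-likelihood is
    non-decreasing within every run; the best run is returned.
    """
    values = _as_values(data)
    n, m = values.shape
    n_informative = int((values != MISSING).any(axis=1).sum())
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_informative:
        raise ValueError(
            f"k={k} exceeds the {n_informative} individuals with observed genotypes"
        )
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    H = _one_hot(values)
    rng = np.random.default_rng(seed)
    snp_ids = data.snp_ids if isinstance(data, GenotypeMatrix) else None

    if k == 1:
        pi = np.ones(1)
        theta = _m_step(np.ones((n, 1)), H, n, m)[1]
        pi, theta, R, ll, it, converged, trace = _run_em(
            pi, theta, H, n, m, tol, max_iter
        )
        model = LatentClassModel(
            k=1, mixing=pi, category_probs=theta, log_likelihood=ll,
            converged=converged, n_iterations=it, seed=seed, snp_ids=snp_ids,
            ll_trace=trace,
        )
        return model, posterior_memberships(model, values)

    # gather candidate starts: random responsibilities + warm starts
    starts: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(n_starts):
        R0 = rng.dirichlet(np.ones(k), size=n)
        starts.append(_m_step(R0, H, n, m))
    for pi_w, theta_w in extra_inits or []:
        pi_w = np.asarray(pi_w, dtype=float)
        theta_w = np.asarray(theta_w, dtype=float)
        if pi_w.shape != (k,) or theta_w.shape != (k, m, 3):
            raise ValueError("extra_inits must match (k,) and (k, m, 3)")
        starts.append((pi_w, theta_w))

    if len(starts) == 1:
        pi0, theta0 = starts[0]
    else:
        # short-run phase: burn in every candidate, keep the best
        candidates = []
        for pi_s, theta_s in starts:
            pi_b, theta_b, _, ll_b, _, _, _ = _run_em(
                pi_s, theta_s, H, n, m, tol, burn_in
            )
            candidates.append((ll_b, pi_b, theta_b))
        _, pi0, theta0 = max(
            candidates, key=lambda c: c[0] if np.isfinite(c[0]) else -np.inf
        )

    pi, theta, R, ll, it, converged, trace = _run_em(
        pi0, theta0, H, n, m, tol, max_iter
    )
    if not converged:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations (k={k}); "
            "returning the best non-converged model"
        )
    model = LatentClassModel(
        k=k, mixing=pi, category_probs=theta, log_likelihood=ll,
        converged=converged, n_iterations=it, seed=seed, snp_ids=snp_ids,
        ll_trace=trace,
    )
    return model, MembershipMatrix.from_posterior(R)


def split_class_init(
    model: LatentClassModel, rng: np.random.Generator, eps: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Warm (k+1)-class start: split the largest class of a k-class fit.

    The split class keeps the parent's genotype profile; its new twin is
    perturbed toward a random simplex point by ``eps`` so EM can break
    the symmetry.  Used to stabilize nested-model refits.
    """
    j = int(np.argmax(model.mixing))
    pi = np.concatenate([model.mixing, [model.mixing[j] / 2.0]])
    pi[j] /= 2.0
    pi /= pi.sum()
    noise = rng.dirichlet(np.ones(3), size=model.m)
    twin = (1.0 - eps) * model.category_probs[j] + eps * noise
    theta = np.concatenate([model.category_probs, twin[None]], axis=0)
    return pi, theta


def sample_from_model(
    model: LatentClassModel, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n individuals (genotypes, class labels) from a fitted model."""
    labels = rng.choice(model.k, size=n, p=model.mixing)
    probs = model.category_probs[labels]  # (n, m, 3)
    cum = np.cumsum(probs, axis=-1)
    u = rng.random((n, model.m))
    values = (u[..., None] > cum).sum(axis=-1).astype(np.int8)
    return values, labels
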