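import itertools
import math
import warnings

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import softmax

from snplca import (
    MISSING,
    LatentClassModel,
    em_fit,
    loglikelihood,
    membership_summary,
    posterior_memberships,
    sample_from_model,
)
from snplca.lca import MembershipMatrix

from .conftest import make_gm, random_genotypes


# ----------------------------------------------------------------------
# independent oracles
# ----------------------------------------------------------------------

def brute_force_loglik(pi, theta, values):
    """Explicit class-enumeration likelihood, pure python."""
    total = 0.0
    for row in values:
        mix = 0.0
        for k in range(len(pi)):
            p = pi[k]
            for j, g in enumerate(row):
                if g != MISSING:
                    p *= theta[k][j][g]
            mix += p
        total += math.log(mix)
    return total


def _unpack(params, k, m):
    """Unconstrained vector -> (pi, theta) via softmax."""
    pi = softmax(np.concatenate([[0.0], params[: k - 1]]))
    rest = params[k - 1 :].reshape(k, m, 2)
    theta = np.zeros((k, m, 3))
    for kk in range(k):
        for j in range(m):
            theta[kk, j] = softmax(np.concatenate([[0.0], rest[kk, j]]))
    return pi, theta


def direct_max_loglik(values, k, n_starts=40, seed=0):
    """Direct numerical maximization of the mixture likelihood.

    Independent of the EM path: optimizes an unconstrained softmax
    parametrization with BFGS from many random starts.
    """
    n, m = values.shape
    dim = (k - 1) + k * m * 2

    def neg_ll(x):
        pi, theta = _unpack(x, k, m)
        total = 0.0
        for row in values:
            mix = 0.0
            for kk in range(k):
                p = pi[kk]
                for j, g in enumerate(row):
                    if g != MISSING:
                        p *= theta[kk][j][g]
                mix += p
            total += math.log(max(mix, 1e-300))  # clamp for line searches
        return -total

    rng = np.random.default_rng(seed)
    best = -np.inf
    for _ in range(n_starts):
        x0 = rng.normal(scale=1.5, size=dim)
        res = minimize(
            neg_ll, x0, method="BFGS", options={"maxiter": 500, "gtol": 1e-10}
        )
        best = max(best, brute_force_loglik(*_unpack(res.x, k, m), values))
    return best


# ----------------------------------------------------------------------
# log-likelihood evaluation
# ----------------------------------------------------------------------

def test_loglik_hand_example_single_class():
    model = LatentClassModel(
        k=1, mixing=np.array([1.0]),
        category_probs=np.array([[[0.5, 0.3, 0.2]]]),
    )
    gm = make_gm([[0], [1]])
    assert loglikelihood(model, gm) == pytest.approx(math.log(0.5) + math.log(0.3))


def test_loglik_all_missing_is_zero():
    model = LatentClassModel(
        k=2, mixing=np.array([0.4, 0.6]),
        category_probs=np.tile([0.2, 0.5, 0.3], (2, 3, 1)),
    )
    gm = make_gm(np.full((4, 3), MISSING))
    assert loglikelihood(model, gm) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_loglik_matches_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    values = random_genotypes(rng, 5, 3, missing_rate=0.25)
    k = 2 + seed % 2
    mixing = rng.dirichlet(np.ones(k))
    theta = rng.dirichlet(np.ones(3), size=(k, 3))
    model = LatentClassModel(k=k, mixing=mixing, category_probs=theta)
    assert loglikelihood(model, values) == pytest.approx(
        brute_force_loglik(mixing, theta, values), abs=1e-9
    )


def test_zero_probability_category_returns_minus_inf_with_warning():
    model = LatentClassModel(
        k=1, mixing=np.array([1.0]),
        category_probs=np.array([[[1.0, 0.0, 0.0]]]),
    )
    gm = make_gm([[2]])
    with pytest.warns(UserWarning, match="zero probability"):
        assert loglikelihood(model, gm) == -np.inf


# ----------------------------------------------------------------------
# posteriors and memberships
# ----------------------------------------------------------------------

def test_posterior_single_class_is_one():
    model = LatentClassModel(
        k=1, mixing=np.array([1.0]),
        category_probs=np.tile([0.6, 0.3, 0.1], (1, 2, 1)),
    )
    mem = posterior_memberships(model, make_gm([[0, 1], [2, MISSING]]))
    np.testing.assert_allclose(mem.posterior, 1.0)


def test_posterior_all_missing_individual_returns_prior():
    mixing = np.array([0.3, 0.7])
    model = LatentClassModel(
        k=2, mixing=mixing, category_probs=np.tile([0.5, 0.4, 0.1], (2, 2, 1))
    )
    mem = posterior_memberships(model, make_gm([[MISSING, MISSING]]))
    np.testing.assert_allclose(mem.posterior[0], mixing, atol=1e-12)


def test_posterior_bayes_hand_example():
    model = LatentClassModel(
        k=2,
        mixing=np.array([0.5, 0.5]),
        category_probs=np.array([[[0.9, 0.05, 0.05]], [[0.1, 0.45, 0.45]]]),
    )
    mem = posterior_memberships(model, make_gm([[0]]))
    assert mem.posterior[0, 0] == pytest.approx(0.9)
    assert mem.assignment[0] == 0


def test_posterior_rows_sum_to_one_and_argmax_ties_go_low(rng):
    values = random_genotypes(rng, 30, 4, missing_rate=0.2)
    model, mem = em_fit(values, 3, n_starts=3, seed=0)
    np.testing.assert_allclose(mem.posterior.sum(axis=1), 1.0, atol=1e-10)
    assert np.all(
        mem.max_posterior == mem.posterior[np.arange(30), mem.assignment]
    )
    tie = MembershipMatrix.from_posterior(np.array([[0.5, 0.5]]))
    assert tie.assignment[0] == 0


def test_membership_summary_counts():
    mem = MembershipMatrix.from_posterior(
        np.array([[0.95, 0.05], [0.7, 0.3], [0.5, 0.5]])
    )
    s = membership_summary(mem)
    assert (s.n_above_high, s.n_below_low) == (1, 1)
    assert s.frac_above_high == pytest.approx(1 / 3)
    assert s.frac_below_low == pytest.approx(1 / 3)
    uniform = MembershipMatrix.from_posterior(np.full((5, 6), 1 / 6))
    s6 = membership_summary(uniform)
    assert s6.n_below_low == 5 and s6.n_above_high == 0
    sure = MembershipMatrix.from_posterior(np.eye(4))
    s1 = membership_summary(sure)
    assert s1.n_above_high == 4 and s1.n_below_low == 0


# ----------------------------------------------------------------------
# EM fitting
# ----------------------------------------------------------------------

def test_em_single_class_matches_closed_form(rng):
    values = random_genotypes(rng, 50, 4, missing_rate=0.2)
    model, mem = em_fit(values, 1, seed=0)
    # theta = observed per-SNP category frequencies
    for j in range(4):
        col = values[:, j]
        obs = col[col != MISSING]
        freq = np.array([(obs == g).mean() for g in range(3)])
        np.testing.assert_allclose(model.category_probs[0, j], freq, atol=1e-8)
    # closed-form log-likelihood sum_j sum_g n_jg log(n_jg / n_obs_j)
    closed = 0.0
    for j in range(4):
        col = values[:, j]
        obs = col[col != MISSING]
        for g in range(3):
            njg = (obs == g).sum()
            if njg:
                closed += njg * math.log(njg / obs.size)
    assert model.log_likelihood == pytest.approx(closed, abs=1e-6)
    np.testing.assert_allclose(mem.posterior, 1.0)


def test_em_loglik_never_decreases(rng):
    """Monotonicity of the EM trace, asserted on every recorded iteration."""
    for seed in range(3):
        values = random_genotypes(rng, 60, 5, missing_rate=0.15)
        model, _ = em_fit(values, 3, n_starts=4, seed=seed)
        trace = np.array(model.ll_trace)
        assert np.all(np.diff(trace) >= -1e-7 * np.abs(trace[:-1]))


def test_em_beats_coarse_grid_search():
    """On a 6x2 toy, EM reaches at least the best coarse-grid likelihood."""
    values = np.array([[0, 0], [0, 1], [1, 0], [2, 2], [2, 1], [2, 2]], dtype=np.int8)
    model, _ = em_fit(values, 2, n_starts=20, seed=0)

    # independent coarse grid over pi and per-class/SNP simplices
    simplex = [
        np.array(t)
        for t in itertools.product(np.arange(0, 1.25, 0.25), repeat=3)
        if abs(sum(t) - 1.0) < 1e-9
    ]
    best = -np.inf
    for pi0 in np.arange(0.1, 1.0, 0.2):
        pi = [pi0, 1 - pi0]
        for t_combo in itertools.product(range(len(simplex)), repeat=4):
            theta = [
                [simplex[t_combo[0]], simplex[t_combo[1]]],
                [simplex[t_combo[2]], simplex[t_combo[3]]],
            ]
            try:
                ll = brute_force_loglik(pi, theta, values)
            except ValueError:  # a zero-probability observed category
                continue
            best = max(best, ll)
    assert model.log_likelihood >= best - 1e-6


@pytest.mark.parametrize("seed,n,m,k", [(0, 5, 2, 2), (1, 6, 3, 2), (2, 6, 2, 1)])
def test_em_matches_direct_maximization_oracle(seed, n, m, k):
    rng = np.random.default_rng(seed + 10)
    values = random_genotypes(rng, n, m, missing_rate=0.2)
    model, _ = em_fit(values, k, n_starts=40, seed=seed)
    oracle = direct_max_loglik(values, k, n_starts=40, seed=seed)
    assert model.log_likelihood == pytest.approx(oracle, abs=1e-6)


def test_em_permutation_invariance(rng):
    values = random_genotypes(rng, 40, 4)
    model, mem = em_fit(values, 3, n_starts=5, seed=1)
    perm = [2, 0, 1]
    permuted = model.permuted(perm)
    assert loglikelihood(permuted, values) == pytest.approx(
        loglikelihood(model, values), abs=1e-9
    )
    mem_p = posterior_memberships(permuted, values)
    np.testing.assert_allclose(mem_p.posterior, mem.posterior[:, perm], atol=1e-9)


def test_missing_only_column_changes_nothing(rng):
    values = random_genotypes(rng, 30, 3, missing_rate=0.1)
    augmented = np.column_stack([values, np.full(30, MISSING, dtype=np.int8)])
    m1, mem1 = em_fit(values, 2, n_starts=4, seed=5)
    m2, mem2 = em_fit(augmented, 2, n_starts=4, seed=5)
    assert m1.log_likelihood == pytest.approx(m2.log_likelihood, abs=1e-6)
    np.testing.assert_allclose(mem1.posterior, mem2.posterior, atol=1e-6)


def test_em_rejects_k_larger_than_informative_n():
    values = np.array([[0], [1], [MISSING]], dtype=np.int8)
    with pytest.raises(ValueError, match="k=3"):
        em_fit(values, 3)


def test_n_params_formula():
    model = LatentClassModel(
        k=4, mixing=np.full(4, 0.25), category_probs=np.tile([0.5, 0.3, 0.2], (4, 7, 1))
    )
    assert model.n_params == 3 + 4 * 7 * 2


def test_model_json_roundtrip(rng):
    values = random_genotypes(rng, 25, 3)
    model, _ = em_fit(values, 2, n_starts=3, seed=2)
    back = LatentClassModel.from_json(model.to_json())
    np.testing.assert_allclose(back.mixing, model.mixing)
    np.testing.assert_allclose(back.category_probs, model.category_probs)
    assert back.log_likelihood == model.log_likelihood
    assert back.k == model.k


def test_sample_from_model_reproduces_profile():
    theta = np.array([[[0.7, 0.2, 0.1]]])
    model = LatentClassModel(k=1, mixing=np.array([1.0]), category_probs=theta)
    values, labels = sample_from_model(model, 20_000, np.random.default_rng(0))
    freq = np.array([(values == g).mean() for g in range(3)])
    np.testing.assert_allclose(freq, theta[0, 0], atol=0.02)
    assert set(labels) == {0}
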