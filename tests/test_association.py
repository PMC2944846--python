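import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snplca import (
    SeparationError,
    association_table,
    contingency_from_counts,
    fisher_exact,
    logistic_backward,
    odds_ratio_woolf,
    pearson_chi2,
    two_by_two,
)


# ----------------------------------------------------------------------
# odds ratios with Woolf intervals — published-table reconstructions
# ----------------------------------------------------------------------

# (a, b, c, d) reconstructed from the cohort characteristics table:
# cluster members with/without the trait vs all other clusters.
PUBLISHED_TABLES = [
    # cluster B, inflammatory behavior (one behavior value missing overall)
    ((57, 39, 373, 405), 1.59, 1.03, 2.44),
    # cluster B, non-perianal fistulae
    ((16, 80, 211, 568), 0.54, 0.31, 0.94),
    # cluster C, stenosing behavior (the behavior-missing subject stays
    # in the comparator margin; 514 there does not reproduce the print)
    ((31, 31, 298, 515), 1.73, 1.03, 2.90),
    # cluster C, perianal fistulae
    ((26, 36, 241, 571), 1.71, 1.01, 2.90),
    # cluster C, surgery (four surgery values missing overall)
    ((45, 17, 448, 361), 2.13, 1.20, 3.79),
]


@pytest.mark.parametrize("counts,or_exp,lo_exp,hi_exp", PUBLISHED_TABLES)
def test_woolf_interval_reproduces_published_values(counts, or_exp, lo_exp, hi_exp):
    or_, lo, hi = odds_ratio_woolf(*counts)
    assert round(or_, 2) == pytest.approx(or_exp)
    assert round(lo, 2) == pytest.approx(lo_exp)
    assert round(hi, 2) == pytest.approx(hi_exp)


def test_null_table_or_one_chi2_zero():
    or_, lo, hi = odds_ratio_woolf(1, 1, 1, 1)
    assert or_ == 1.0 and lo < 1.0 < hi
    stat, p = pearson_chi2(1, 1, 1, 1)
    assert stat == 0.0 and p == pytest.approx(1.0)


def test_symmetric_table_or_exactly_one():
    or_, lo, hi = odds_ratio_woolf(7, 7, 7, 7)
    assert or_ == 1.0 and lo < 1.0 < hi


def test_zero_cell_gets_haldane_correction():
    with pytest.warns(UserWarning, match="Haldane"):
        or_, lo, hi = odds_ratio_woolf(0, 5, 5, 5)
    expected = (0.5 * 5.5) / (5.5 * 5.5)
    assert or_ == pytest.approx(expected)
    assert np.isfinite(lo) and np.isfinite(hi)


def test_or_invariance_under_table_symmetries(rng):
    a, b, c, d = rng.integers(1, 50, size=4)
    or0 = odds_ratio_woolf(a, b, c, d)[0]
    # swapping both rows and both columns leaves the OR unchanged
    assert odds_ratio_woolf(d, c, b, a)[0] == pytest.approx(or0)
    # swapping one (columns) inverts it
    assert odds_ratio_woolf(b, a, d, c)[0] == pytest.approx(1 / or0)


# ----------------------------------------------------------------------
# chi-square
# ----------------------------------------------------------------------

def test_chi2_surgery_cluster_rounds_to_published_p():
    _, p = pearson_chi2(45, 17, 448, 361)
    assert round(p, 3) == 0.008


@pytest.mark.parametrize(
    "counts,p_published",
    [
        ((16, 80, 211, 568), 0.03),
        ((31, 31, 298, 515), 0.04),
        ((26, 36, 241, 571), 0.04),
    ],
)
def test_chi2_published_behavior_tables(counts, p_published):
    _, p = pearson_chi2(*counts)
    assert round(p, 2) == pytest.approx(p_published)


def test_inflammatory_cluster_significance():
    """The borderline cluster-vs-rest inflammatory difference: the
    uncorrected chi-square is significant, and the printed p of 0.04
    corresponds to the Fisher exact value for the same table."""
    _, p = pearson_chi2(57, 39, 373, 405)
    assert p < 0.05
    assert round(fisher_exact(57, 39, 373, 405), 2) == 0.04


def test_chi2_matches_scipy_oracle(rng):
    for _ in range(25):
        a, b, c, d = rng.integers(1, 50, size=4)
        stat, p = pearson_chi2(a, b, c, d)
        oracle = stats.chi2_contingency([[a, b], [c, d]], correction=False)
        assert stat == pytest.approx(oracle.statistic, abs=1e-10)
        assert p == pytest.approx(oracle.pvalue, abs=1e-12)


def test_chi2_zero_margin_is_error():
    with pytest.raises(ValueError, match="margin"):
        pearson_chi2(0, 0, 3, 4)


# ----------------------------------------------------------------------
# Fisher exact
# ----------------------------------------------------------------------

def hypergeom_two_sided(a, b, c, d):
    """Exhaustive enumeration over all tables with the observed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    pmf = {x: stats.hypergeom.pmf(x, n, r1, c1) for x in range(lo, hi + 1)}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


def test_fisher_all_off_diagonal():
    assert fisher_exact(0, 5, 5, 0) == pytest.approx(2 / 252)


def test_fisher_null_table():
    assert fisher_exact(1, 1, 1, 1) == pytest.approx(1.0)


def test_fisher_matches_enumeration_for_all_small_tables():
    for n in range(1, 21):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    assert fisher_exact(a, b, c, d) == pytest.approx(
                        hypergeom_two_sided(a, b, c, d), abs=1e-9
                    )


# ----------------------------------------------------------------------
# two_by_two
# ----------------------------------------------------------------------

def test_two_by_two_excludes_missing_and_reconstructs_margins():
    labels = np.array([0] * 6 + [1] * 6)
    pheno = pd.array([1, 1, 0, 0, pd.NA, 1, 0, 1, 0, 0, pd.NA, pd.NA], dtype="Int64")
    res = two_by_two(labels, 0, pheno)
    assert res.n_missing_excluded == 3
    assert (res.a, res.b, res.c, res.d) == (3, 2, 1, 3)
    assert res.n == 12 - 3
    assert res.odds_ratio == pytest.approx((3 * 3) / (2 * 1))


def test_two_by_two_fisher_triggered_by_small_expected_count():
    labels = np.array([0] * 4 + [1] * 40)
    pheno = np.array([1, 1, 1, 0] + [0] * 36 + [1] * 4)
    res = two_by_two(labels, 0, pheno)
    assert res.fisher_p is not None  # expected counts < 5 somewhere
    big = two_by_two(np.repeat([0, 1], 100), 0, np.tile([0, 1], 100))
    assert big.fisher_p is None


def test_two_by_two_empty_cluster_is_error():
    with pytest.raises(ValueError, match="empty"):
        two_by_two(np.array([0, 0, 1]), 2, np.array([1, 0, 1]))


def test_association_table_has_adjusted_columns():
    rng = np.random.default_rng(4)
    labels = rng.integers(0, 3, 120)
    pheno = pd.DataFrame(
        {
            "surgery": rng.integers(0, 2, 120),
            "anal": rng.integers(0, 2, 120),
        }
    )
    table = association_table(labels, pheno)
    assert len(table) == 6  # 3 clusters x 2 phenotypes
    assert {"chi2_p_bonferroni", "chi2_p_fdr_bh"} <= set(table.columns)
    assert (table["chi2_p_bonferroni"] >= table["chi2_p"] - 1e-12).all()


# ----------------------------------------------------------------------
# backward logistic regression
# ----------------------------------------------------------------------

def test_single_binary_predictor_matches_two_by_two_or():
    rng = np.random.default_rng(0)
    x = rng.integers(0, 2, 500)
    logit_p = -0.5 + 1.2 * x
    y = rng.random(500) < 1 / (1 + np.exp(-logit_p))
    fit = logistic_backward(pd.DataFrame({"x": x}), y.astype(float), p_remove=0.99)
    a = int(((x == 1) & y).sum())
    b = int(((x == 1) & ~y).sum())
    c = int(((x == 0) & y).sum())
    d = int(((x == 0) & ~y).sum())
    sample_or, lo, hi = odds_ratio_woolf(a, b, c, d)
    row = fit.retained.iloc[0]
    assert row["odds_ratio"] == pytest.approx(sample_or, abs=1e-6)
    assert row["ci_low"] == pytest.approx(lo, abs=0.01)
    assert row["ci_high"] == pytest.approx(hi, abs=0.01)


def test_independent_predictor_is_eliminated():
    rng = np.random.default_rng(1)
    x = rng.integers(0, 2, 2000)
    y = rng.integers(0, 2, 2000).astype(float)  # outcome independent of x
    fit = logistic_backward(pd.DataFrame({"x": x}), y, p_remove=0.10)
    assert len(fit.retained) == 0
    assert fit.elimination_trace[0][0] == "x"


def test_duplicate_column_raises_collinearity_error():
    rng = np.random.default_rng(2)
    x = rng.integers(0, 2, 100).astype(float)
    design = pd.DataFrame({"x1": x, "x2": x})
    y = rng.integers(0, 2, 100).astype(float)
    with pytest.raises(SeparationError, match="collinear"):
        logistic_backward(design, y)


def test_perfect_separation_names_predictor():
    x = np.array([0] * 50 + [1] * 50).astype(float)
    y = x.copy()  # outcome == predictor: perfect separation
    noise = np.tile([0.0, 1.0], 50)
    with pytest.raises(SeparationError):
        logistic_backward(pd.DataFrame({"sep": x, "noise": noise}), y)


def test_backward_trace_is_nested_sequence():
    rng = np.random.default_rng(3)
    n = 1500
    x1 = rng.integers(0, 2, n)
    x2 = rng.integers(0, 2, n)
    x3 = rng.integers(0, 2, n)
    logit_p = -0.3 + 1.0 * x1
    y = (rng.random(n) < 1 / (1 + np.exp(-logit_p))).astype(float)
    fit = logistic_backward(
        pd.DataFrame({"x1": x1, "x2": x2, "x3": x3}), y, p_remove=0.10
    )
    retained = set(fit.retained["predictor"])
    removed = {name for name, _ in fit.elimination_trace}
    assert retained | removed == {"x1", "x2", "x3"}
    assert retained & removed == set()
    assert "x1" in retained  # the true signal survives
    for _, p in fit.elimination_trace:
        assert p > 0.10


# ----------------------------------------------------------------------
# contingency_from_counts battery
# ----------------------------------------------------------------------

def test_contingency_bundle_consistency():
    res = contingency_from_counts(45, 17, 448, 361, n_missing_excluded=4)
    assert res.n == 871
    assert res.ci_low <= res.odds_ratio <= res.ci_high
    assert round(res.chi2_p, 3) == 0.008
    assert res.n_missing_excluded == 4
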