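"""Cluster-membership versus clinical-phenotype association statistics.

One cluster at a time is compared against all other clusters on a
binary trait via the 2x2 table

    a = in cluster, trait present      b = in cluster, trait absent
    c = other clusters, trait present  d = other clusters, trait absent

with the odds ratio ad/bc, the Woolf 95% confidence interval
exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)), a Pearson chi-square
without continuity correction, and a Fisher exact p-value whenever any
expected cell count is below 5.  Individuals with a missing trait value
are excluded (and counted).  Multivariable analysis is a backward-
elimination logistic regression on Wald p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

Z_95 = 1.96  # normal quantile used by the Woolf interval


@dataclass
class ContingencyResult:
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2_stat: float
    chi2_p: float
    fisher_p: float | None
    n_missing_excluded: int
    haldane: bool = False  # +0.5 applied to all cells (some cell was 0)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def odds_ratio_woolf(a, b, c, d) -> tuple[float, float, float]:
    """Odds ratio with the Woolf (log) 95% confidence interval.

    Any zero cell triggers the Haldane-Anscombe correction (+0.5 to all
    four cells) with a warning; degenerate tables are never fatal.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if min(a, b, c, d) == 0:
        warnings.warn(
            "zero cell in 2x2 table; applying Haldane-Anscombe +0.5 correction"
        )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_or = np.log(or_)
    return (
        float(or_),
        float(np.exp(log_or - Z_95 * se)),
        float(np.exp(log_or + Z_95 * se)),
    )


def pearson_chi2(a, b, c, d) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction.

    statistic = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("zero margin: chi-square statistic undefined")
    stat = n * (a * d - b * c) ** 2 / margins
    return float(stat), float(stats.chi2.sf(stat, df=1))


def fisher_exact(a, b, c, d) -> float:
    """Two-sided Fisher exact p (sum of tables as or less probable)."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def _expected_counts(a, b, c, d) -> np.ndarray:
    n = a + b + c + d
    rows = np.array([a + b, c + d], dtype=float)
    cols = np.array([a + c, b + d], dtype=float)
    return np.outer(rows, cols) / n


def contingency_from_counts(a, b, c, d, n_missing_excluded: int = 0) -> ContingencyResult:
    """Full battery of statistics for explicit 2x2 counts."""
    or_, lo, hi = odds_ratio_woolf(a, b, c, d)
    chi2_stat, chi2_p = pearson_chi2(a, b, c, d)
    fisher_p = (
        fisher_exact(a, b, c, d)
        if (_expected_counts(a, b, c, d) < 5).any()
        else None
    )
    return ContingencyResult(
        a=int(a), b=int(b), c=int(c), d=int(d),
        odds_ratio=or_, ci_low=lo, ci_high=hi,
        chi2_stat=chi2_stat, chi2_p=chi2_p, fisher_p=fisher_p,
        n_missing_excluded=int(n_missing_excluded),
        haldane=min(a, b, c, d) == 0,
    )


def two_by_two(cluster_labels, cluster_id, phenotype) -> ContingencyResult:
    """Cluster-vs-rest association with a binary trait.

    ``phenotype`` is a 0/1 vector that may contain missing values (NaN
    or pandas NA); missing individuals are excluded from the table and
    counted in ``n_missing_excluded``.
    """
    labels = np.asarray(cluster_labels)
    pheno = pd.array(phenotype, dtype="Float64")
    if labels.shape[0] != len(pheno):
        raise ValueError("label and phenotype vectors differ in length")
    in_cluster = labels == cluster_id
    if not in_cluster.any() or in_cluster.all():
        raise ValueError(
            f"cluster {cluster_id!r} is empty or spans the whole cohort; "
            "2x2 margins undefined"
        )
    observed = ~pd.isna(pheno)
    obs = np.asarray(observed)
    trait = np.asarray(pheno.fillna(0).astype(float) > 0.5)
    a = int((in_cluster & obs & trait).sum())
    b = int((in_cluster & obs & ~trait).sum())
    c = int((~in_cluster & obs & trait).sum())
    d = int((~in_cluster & obs & ~trait).sum())
    if (a + b) == 0 or (c + d) == 0:
        raise ValueError("a margin is empty after excluding missing values")
    return contingency_from_counts(a, b, c, d, n_missing_excluded=int((~obs).sum()))


def association_table(cluster_labels, binary_phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster, per-phenotype table of 2x2 statistics.

    ``binary_phenotypes`` holds one 0/1 (possibly missing) column per
    trait; every cluster label present is tested against the rest.
    Supplementary Bonferroni and Benjamini-Hochberg adjusted chi-square
    p-values are appended (no correction is applied to the primary
    columns).
    """
    labels = np.asarray(cluster_labels)
    rows = []
    for cluster in np.unique(labels):
        for col in binary_phenotypes.columns:
            try:
                res = two_by_two(labels, cluster, binary_phenotypes[col])
            except ValueError:
                continue
            rows.append(
                {
                    "cluster": cluster,
                    "phenotype": col,
                    "a": res.a, "b": res.b, "c": res.c, "d": res.d,
                    "n_missing_excluded": res.n_missing_excluded,
                    "odds_ratio": res.odds_ratio,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "chi2_stat": res.chi2_stat,
                    "chi2_p": res.chi2_p,
                    "fisher_p": res.fisher_p,
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        from statsmodels.stats.multitest import multipletests

        table["chi2_p_bonferroni"] = np.minimum(
            table["chi2_p"] * len(table), 1.0
        )
        table["chi2_p_fdr_bh"] = multipletests(
            table["chi2_p"].to_numpy(), method="fdr_bh"
        )[1]
    return table


# ----------------------------------------------------------------------
# backward-selection logistic regression
# ----------------------------------------------------------------------

class SeparationError(ValueError):
    """Perfect separation or collinearity makes the logistic MLE diverge."""


@dataclass
class LogisticFit:
    retained: pd.DataFrame  # predictor, coef, odds_ratio, ci_low, ci_high, wald_p
    elimination_trace: list[tuple[str, float]]  # (removed predictor, p at removal)
    intercept: float | None


def _check_design(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        corr = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
        np.fill_diagonal(np.atleast_2d(corr), 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise SeparationError(
            f"design matrix is rank-deficient (collinear predictors, e.g. "
            f"{X.columns[i]!r} and {X.columns[j]!r})"
        )


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    import statsmodels.api as sm

    design = sm.add_constant(X.astype(float), has_constant="add")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception as exc:  # PerfectSeparationError and kin
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    sep_warned = any("separat" in str(w.message).lower() for w in caught)
    big = fit.params.drop("const").abs()
    if sep_warned or (len(big) and big.max() > 20):
        culprit = big.idxmax() if len(big) else "?"
        raise SeparationError(
            f"perfect or quasi-perfect separation involving predictor {culprit!r}"
        )
    return fit


def logistic_backward(design, outcome, p_remove: float = 0.10) -> LogisticFit:
    """Backward-elimination logistic regression on Wald p-values.

    Starting from the full model, the predictor with the largest Wald
    p-value above ``p_remove`` is dropped and the model refit until all
    remaining predictors satisfy p <= p_remove.  May return an empty
    model.  Raises :class:`SeparationError` on collinear designs or
    perfect separation, naming a predictor involved.
    """
    X = pd.DataFrame(design).astype(float)
    y = np.asarray(outcome, dtype=float)
    if y.shape != (len(X),):
        raise ValueError("outcome length mismatch")
    if len(X) <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    _check_design(X)

    trace: list[tuple[str, float]] = []
    cols = list(X.columns)
    fit = None
    while cols:
        fit = _fit_logit(y, X[cols])
        pvals = fit.pvalues.drop("const")
        worst = pvals.idxmax()
        if pvals[worst] <= p_remove:
            break
        trace.append((str(worst), float(pvals[worst])))
        cols.remove(worst)
        fit = None

    if not cols:
        retained = pd.DataFrame(
            columns=["predictor", "coef", "odds_ratio", "ci_low", "ci_high", "wald_p"]
        )
        return LogisticFit(retained=retained, elimination_trace=trace, intercept=None)

    conf = fit.conf_int()
    rows = []
    for name in cols:
        rows.append(
            {
                "predictor": str(name),
                "coef": float(fit.params[name]),
                "odds_ratio": float(np.exp(fit.params[name])),
                "ci_low": float(np.exp(conf.loc[name, 0])),
                "ci_high": float(np.exp(conf.loc[name, 1])),
                "wald_p": float(fit.pvalues[name]),
            }
        )
    return LogisticFit(
        retained=pd.DataFrame(rows),
        elimination_trace=trace,
        intercept=float(fit.params["const"]),
    )
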