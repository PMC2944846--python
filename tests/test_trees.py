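import itertools

import numpy as np
import pytest

from snplca import (
    MISSING,
    UNALLOCATED,
    drop_down,
    drop_down_report,
    fit_forest,
    grow_tree,
    predict_many,
)

from .conftest import make_gm


# ----------------------------------------------------------------------
# independent split oracle
# ----------------------------------------------------------------------

def gini(labels):
    labels = np.asarray(labels)
    if labels.size == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return 1.0 - np.sum(p**2)


def best_split_oracle(values, labels):
    """Exhaustive enumeration of every (SNP, genotype-subset) split.

    Returns (decrease, snp, left_subset) maximizing the root-scaled Gini
    decrease over individuals observed at the SNP; same tie-break order
    as the implementation (feature index, then canonical subset order).
    """
    n = len(labels)
    best = None
    for j in range(values.shape[1]):
        col = values[:, j]
        obs = col != MISSING
        vo, yo = col[obs], np.asarray(labels)[obs]
        cats = sorted(set(vo.tolist()))
        if len(cats) < 2:
            continue
        first, rest = cats[0], cats[1:]
        subsets = []
        for r in range(len(rest) + 1):
            for combo in itertools.combinations(rest, r):
                left = frozenset((first, *combo))
                if 0 < len(left) < len(cats):
                    subsets.append(left)
        for left in subsets:
            inl = np.isin(vo, sorted(left))
            nl, nr = inl.sum(), (~inl).sum()
            if nl == 0 or nr == 0:
                continue
            dec = (vo.size / n) * (
                gini(yo)
                - (nl / vo.size) * gini(yo[inl])
                - (nr / vo.size) * gini(yo[~inl])
            )
            if best is None or dec > best[0] + 1e-12:
                best = (dec, j, left)
    return best


# ----------------------------------------------------------------------
# tree growth
# ----------------------------------------------------------------------

def test_separable_rule_recovered_exactly():
    values = np.array([[0], [0], [0], [1], [2], [1], [2], [2]], dtype=np.int8)
    labels = np.where(values[:, 0] == 0, "A", "B")
    tree = grow_tree(values, labels, min_split=2, cp=0.01)
    root = tree.root
    assert not root.is_leaf
    assert root.feature == 0
    assert root.left_categories == frozenset({0})
    report = drop_down_report(tree, values, labels)
    assert report.n_misclassified == 0 and report.n_unallocated == 0


@pytest.mark.parametrize("seed", range(6))
def test_root_split_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    n, m = rng.integers(6, 11), rng.integers(2, 4)
    values = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    values[rng.random((n, m)) < 0.1] = MISSING
    labels = rng.integers(0, 3, size=n)
    tree = grow_tree(values, labels, min_split=2, cp=1e-9)
    expected = best_split_oracle(values, labels)
    if expected is None or expected[0] <= 1e-12:
        assert tree.root.is_leaf
    else:
        assert tree.root.feature == expected[1]
        assert tree.root.left_categories == expected[2]
        assert tree.root.decrease == pytest.approx(expected[0], abs=1e-12)


def test_single_class_input_gives_single_leaf():
    values = np.array([[0, 1], [1, 2], [2, 0]], dtype=np.int8)
    tree = grow_tree(values, ["x", "x", "x"], min_split=2)
    assert tree.root.is_leaf
    assert tree.root.prediction == "x"
    assert tree.n_leaves == 1


def test_accepted_splits_satisfy_cp_contract(rng):
    """Every internal node's (root-scaled) decrease >= cp * root impurity."""
    values = rng.integers(0, 3, size=(200, 5)).astype(np.int8)
    labels = (values[:, 0] + rng.integers(0, 2, 200)).clip(0, 2)
    cp = 0.02
    tree = grow_tree(values, labels, min_split=10, cp=cp)

    def walk(node):
        if not node.is_leaf:
            assert node.decrease >= cp * tree.root_impurity - 1e-12
            walk(node.left)
            walk(node.right)

    walk(tree.root)


def test_tree_deterministic(rng):
    values = rng.integers(0, 3, size=(80, 4)).astype(np.int8)
    labels = rng.integers(0, 2, 80)
    t1 = grow_tree(values, labels)
    t2 = grow_tree(values, labels)
    assert t1.to_dict() == t2.to_dict()
    assert t1.to_text() == t2.to_text()


def test_labels_length_checked(rng):
    with pytest.raises(ValueError, match="labels length"):
        grow_tree(rng.integers(0, 3, size=(5, 2)).astype(np.int8), [0, 1])


# ----------------------------------------------------------------------
# drop-down semantics
# ----------------------------------------------------------------------

def _one_split_tree():
    values = np.array([[0], [0], [1], [2]], dtype=np.int8)
    labels = ["A", "A", "B", "B"]
    return grow_tree(values, labels, min_split=2, cp=0.01)


def test_missing_at_decision_snp_is_unallocated():
    tree = _one_split_tree()
    assert drop_down(tree, np.array([MISSING], dtype=np.int8)) == UNALLOCATED
    assert drop_down(tree, np.array([0], dtype=np.int8)) == "A"
    assert drop_down(tree, np.array([2], dtype=np.int8)) == "B"


def test_single_leaf_tree_allocates_everyone():
    values = np.array([[0], [1]], dtype=np.int8)
    tree = grow_tree(values, ["z", "z"])
    # no decision SNP is visited, so even fully missing rows are routed
    assert drop_down(tree, np.array([MISSING], dtype=np.int8)) == "z"


def test_dropdown_report_counts_partition_n():
    tree = _one_split_tree()
    data = np.array([[0], [1], [MISSING], [2]], dtype=np.int8)
    ref = np.array(["A", "B", "A", "A"])
    report = drop_down_report(tree, data, ref)
    assert report.n_total == 4
    assert report.n_unallocated == 1
    assert report.n_misclassified == 1  # the last row: predicted B, ref A
    assert report.n_correct == 2
    assert (
        report.n_correct + report.n_misclassified + report.n_unallocated
        == report.n_total
    )


def test_dropdown_report_matches_confusion_oracle(rng):
    values = rng.integers(0, 3, size=(100, 3)).astype(np.int8)
    values[rng.random((100, 3)) < 0.1] = MISSING
    labels = rng.integers(0, 2, 100)
    tree = grow_tree(values, labels, min_split=5, cp=0.001)
    report = drop_down_report(tree, values, labels)
    preds = [drop_down(tree, values[i]) for i in range(100)]
    n_unalloc = sum(p == UNALLOCATED for p in preds)
    n_correct = sum(
        p != UNALLOCATED and p == labels[i] for i, p in enumerate(preds)
    )
    assert report.n_unallocated == n_unalloc
    assert report.n_correct == n_correct
    assert sum(report.confusion.values()) == 100 - n_unalloc
    np.testing.assert_array_equal(predict_many(tree, values), np.array(preds, dtype=object))


def test_genotype_matrix_input_uses_snp_names(rng):
    gm = make_gm(rng.integers(0, 3, size=(60, 3)), snp_ids=["rsA", "rsB", "rsC"])
    labels = gm.values[:, 1].clip(0, 1)
    tree = grow_tree(gm, labels, min_split=5, cp=0.01)
    assert set(tree.decision_features()) <= {"rsA", "rsB", "rsC"}
    assert "rsB" in tree.decision_features()


# ----------------------------------------------------------------------
# random forest
# ----------------------------------------------------------------------

def test_forest_planted_signal_small(rng):
    n = 300
    X = rng.integers(0, 3, size=(n, 5))
    y = X[:, 0].copy()  # labels are a copy of feature 0
    rep = fit_forest(X, y, n_trees=80, seed=1)
    assert rep.oob_error_rate < 0.05
    assert np.argmax(rep.importance_mda) == 0
    assert np.argmax(rep.importance_gini) == 0


def test_forest_constant_feature_importance_exactly_zero(rng):
    n = 120
    X = np.column_stack([rng.integers(0, 3, n), np.zeros(n, dtype=int)])
    y = X[:, 0]
    with pytest.warns(UserWarning, match="zero variance"):
        rep = fit_forest(X, y, n_trees=30, seed=0)
    assert rep.importance_mda[1] == 0.0


def test_forest_deterministic_given_seed(rng):
    X = rng.integers(0, 3, size=(80, 4))
    y = rng.integers(0, 2, 80)
    a = fit_forest(X, y, n_trees=25, seed=42)
    b = fit_forest(X, y, n_trees=25, seed=42)
    assert a.oob_error_rate == b.oob_error_rate
    np.testing.assert_array_equal(a.importance_mda, b.importance_mda)
    np.testing.assert_array_equal(a.importance_gini, b.importance_gini)


def test_forest_mtry_validation(rng):
    X = rng.integers(0, 3, size=(30, 3))
    with pytest.raises(ValueError, match="mtry"):
        fit_forest(X, rng.integers(0, 2, 30), n_trees=5, mtry=4)


def test_forest_numeric_feature_with_missing_rejected(rng):
    X = rng.normal(size=(30, 2))
    X[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        fit_forest(
            X, rng.integers(0, 2, 30), n_trees=5,
            feature_types=["numeric", "numeric"],
        )


def test_forest_categorical_missing_becomes_category(rng):
    X = rng.integers(0, 3, size=(100, 3)).astype(float)
    y = (X[:, 0] > 0).astype(int)
    X[rng.random((100, 3)) < 0.1] = MISSING
    rep = fit_forest(X, y, n_trees=20, seed=3)
    assert 0.0 <= rep.oob_error_rate <= 1.0


def test_forest_numeric_threshold_split(rng):
    x = rng.normal(size=200)
    y = (x > 0).astype(int)
    X = np.column_stack([x, rng.normal(size=200)])
    rep = fit_forest(
        X, y, n_trees=60, seed=2, feature_types=["numeric", "numeric"]
    )
    assert rep.oob_error_rate < 0.1
    assert np.argmax(rep.importance_mda) == 0
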