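"""Classification trees and random forests over SNP genotypes.

The explanation tree is a CART-style recursive binary partition with
*categorical subset* splits: a decision node sends genotypes belonging
to a subset of {0, 1, 2} left and the rest right (e.g. "genotype 1
and/or 2").  Splits are chosen to maximize the decrease in Gini
impurity, evaluated over the individuals *observed* at the candidate
SNP.  There are no surrogate splits: an individual missing the genotype
at any decision node it visits cannot be routed and is reported as
UNALLOCATED — this mirrors how model-based cluster assignments are
audited by "dropping individuals down" the tree.

The random forest bags these trees (bootstrap samples, ``mtry`` random
candidate features per split, grown to purity) and reports the
out-of-bag (OOB) error plus two importance measures: permutation mean
decrease in accuracy (MDA) and mean decrease in Gini impurity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .data_io import MISSING, GenotypeMatrix

#: sentinel returned when a decision genotype is missing
UNALLOCATED = "UNALLOCATED"


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p * p).sum())


def _as_feature_matrix(data) -> np.ndarray:
    if isinstance(data, GenotypeMatrix):
        return data.values.astype(np.int64)
    X = np.asarray(data)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    return X


@dataclass
class TreeNode:
    counts: np.ndarray  # training class counts reaching the node
    prediction: object  # majority class label (ties -> smallest label)
    n: int
    impurity: float
    feature: int | None = None
    feature_name: str | None = None
    left_categories: frozenset | None = None  # categorical split
    threshold: float | None = None  # numeric split
    decrease: float = 0.0  # root-scaled Gini decrease of the split
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "counts": self.counts.tolist(),
            "prediction": self.prediction,
        }
        if not self.is_leaf:
            d["feature"] = self.feature
            d["feature_name"] = self.feature_name
            if self.left_categories is not None:
                d["left_categories"] = sorted(int(c) for c in self.left_categories)
            else:
                d["threshold"] = self.threshold
            d["decrease"] = self.decrease
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d


@dataclass
class ClassificationTree:
    root: TreeNode
    classes_: np.ndarray
    feature_names: list[str]
    min_split: int
    cp: float
    root_impurity: float
    feature_types: list[str] = field(default_factory=list)

    @property
    def depth(self) -> int:
        def _d(node):
            return 0 if node.is_leaf else 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    @property
    def n_leaves(self) -> int:
        def _c(node):
            return 1 if node.is_leaf else _c(node.left) + _c(node.right)

        return _c(self.root)

    def decision_features(self) -> list[str]:
        """Names of the features used at decision nodes (tree order)."""
        out: list[str] = []

        def _walk(node):
            if not node.is_leaf:
                if node.feature_name not in out:
                    out.append(node.feature_name)
                _walk(node.left)
                _walk(node.right)

        _walk(self.root)
        return out

    def to_text(self) -> str:
        """Indented rendering: SNP + genotype subset per decision node."""
        lines: list[str] = []

        def fmt_counts(node):
            pairs = ", ".join(
                f"{c}:{int(x)}" for c, x in zip(self.classes_, node.counts)
            )
            return f"n={node.n} [{pairs}]"

        def _walk(node, indent, prefix):
            if node.is_leaf:
                lines.append(
                    f"{'  ' * indent}{prefix}cluster {node.prediction} ({fmt_counts(node)})"
                )
                return
            if node.left_categories is not None:
                cats = " and/or ".join(
                    str(c) for c in sorted(node.left_categories)
                )
                cond = f"{node.feature_name} genotype {cats}"
            else:
                cond = f"{node.feature_name} < {node.threshold:g}"
            lines.append(f"{'  ' * indent}{prefix}[{cond}?] ({fmt_counts(node)})")
            _walk(node.left, indent + 1, "yes: ")
            _walk(node.right, indent + 1, "no:  ")

        _walk(self.root, 0, "")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes_],
            "feature_names": self.feature_names,
            "min_split": self.min_split,
            "cp": self.cp,
            "root_impurity": self.root_impurity,
            "root": self.root.to_dict(),
        }


def _candidate_partitions(cats: np.ndarray):
    """Canonical proper bipartitions of a category set (2^(c-1)-1 of them)."""
    cats = list(cats)
    first, rest = cats[0], cats[1:]
    for r in range(len(cats)):
        for combo in combinations(rest, r):
            left = frozenset((first, *combo))
            if len(left) < len(cats):
                yield left


def _split_candidates_for_feature(v, y, n_classes, ftype):
    """Yield (impurity_after_weighted, partition spec, n_obs, obs_impurity)."""
    obs = ~_is_missing(v)
    vo, yo = v[obs], y[obs]
    n_obs = vo.size
    if n_obs < 2:
        return
    counts_obs = np.bincount(yo, minlength=n_classes)
    g_obs = _gini(counts_obs)
    if ftype == "categorical":
        cats = np.unique(vo)
        if cats.size < 2:
            return
        cat_index = np.searchsorted(cats, vo)
        joint = np.zeros((cats.size, n_classes), dtype=np.int64)
        np.add.at(joint, (cat_index, yo), 1)
        for left in _candidate_partitions(cats):
            lmask = np.isin(cats, sorted(left))
            cl = joint[lmask].sum(axis=0)
            cr = counts_obs - cl
            nl, nr = cl.sum(), cr.sum()
            if nl == 0 or nr == 0:
                continue
            w = (nl * _gini(cl) + nr * _gini(cr)) / n_obs
            yield g_obs - w, ("categorical", left), n_obs
    else:  # numeric threshold splits
        order = np.argsort(vo, kind="stable")
        vs, ys = vo[order], yo[order]
        uniq = np.unique(vs)
        if uniq.size < 2:
            return
        for t in (uniq[:-1] + uniq[1:]) / 2.0:
            lmask = vs <= t
            cl = np.bincount(ys[lmask], minlength=n_classes)
            cr = counts_obs - cl
            nl, nr = cl.sum(), cr.sum()
            if nl == 0 or nr == 0:
                continue
            w = (nl * _gini(cl) + nr * _gini(cr)) / n_obs
            yield g_obs - w, ("numeric", float(t)), n_obs


def _is_missing(v: np.ndarray) -> np.ndarray:
    if v.dtype.kind == "f":
        return np.isnan(v)
    return v == MISSING


def _best_split(X, y, idx, features, n_classes, n_root, feature_types):
    """Exhaustive best (feature, partition) by root-scaled Gini decrease.

    The decrease is (n_obs / n_root) * (gini(observed-at-node) -
    weighted child gini); ties break toward the lower feature index and
    the earlier canonical partition.
    """
    best = None  # (decrease, feature, spec)
    for j in features:
        v = X[idx, j]
        for local_decrease, spec, n_obs in _split_candidates_for_feature(
            v, y[idx], n_classes, feature_types[j]
        ):
            decrease = (n_obs / n_root) * local_decrease
            if best is None or decrease > best[0] + 1e-12:
                best = (decrease, j, spec)
    return best


def _grow(
    X, y, idx, n_classes, classes, n_root, root_impurity, min_split, cp,
    feature_types, rng=None, mtry=None,
):
    counts = np.bincount(y[idx], minlength=n_classes)
    node = TreeNode(
        counts=counts,
        prediction=classes[int(np.argmax(counts))],
        n=int(idx.size),
        impurity=_gini(counts),
    )
    if node.impurity == 0.0 or idx.size < min_split:
        return node
    if rng is not None and mtry is not None and mtry < X.shape[1]:
        features = np.sort(rng.choice(X.shape[1], size=mtry, replace=False))
    else:
        features = np.arange(X.shape[1])
    best = _best_split(X, y, idx, features, n_classes, n_root, feature_types)
    if best is None:
        return node
    decrease, j, (kind, spec) = best
    if decrease < cp * root_impurity or decrease <= 0.0:
        return node
    v = X[idx, j]
    obs = ~_is_missing(v)
    if kind == "categorical":
        go_left = np.zeros(idx.size, dtype=bool)
        go_left[obs] = np.isin(v[obs], sorted(spec))
        node.left_categories = spec
    else:
        go_left = np.zeros(idx.size, dtype=bool)
        go_left[obs] = v[obs] <= spec
        node.threshold = spec
    # individuals missing at the decision SNP are dropped from both
    # children (no surrogate splits)
    left_idx = idx[go_left & obs]
    right_idx = idx[~go_left & obs]
    if left_idx.size == 0 or right_idx.size == 0:
        return node
    node.feature = int(j)
    node.decrease = float(decrease)
    node.left = _grow(
        X, y, left_idx, n_classes, classes, n_root, root_impurity,
        min_split, cp, feature_types, rng, mtry,
    )
    node.right = _grow(
        X, y, right_idx, n_classes, classes, n_root, root_impurity,
        min_split, cp, feature_types, rng, mtry,
    )
    return node


def _attach_names(node: TreeNode, names: list[str]) -> None:
    if not node.is_leaf:
        node.feature_name = names[node.feature]
        _attach_names(node.left, names)
        _attach_names(node.right, names)


def grow_tree(
    data,
    labels,
    min_split: int = 20,
    cp: float = 0.01,
    feature_names: list[str] | None = None,
    feature_types: list[str] | None = None,
) -> ClassificationTree:
    """Grow a CART-style tree explaining cluster labels from genotypes.

    Growth stops at node purity, below ``min_split`` individuals, or
    when the best root-scaled impurity decrease falls below
    ``cp * root_impurity``.  A single-class input yields a single-leaf
    tree.
    """
    X = _as_feature_matrix(data)
    y_raw = np.asarray(labels)
    if y_raw.shape != (X.shape[0],):
        raise ValueError(
            f"labels length {y_raw.size} does not match {X.shape[0]} individuals"
        )
    classes, y = np.unique(y_raw, return_inverse=True)
    if feature_names is None:
        feature_names = (
            data.snp_ids
            if isinstance(data, GenotypeMatrix)
            else [f"f{j}" for j in range(X.shape[1])]
        )
    if feature_types is None:
        feature_types = ["categorical"] * X.shape[1]
    idx = np.arange(X.shape[0])
    root_counts = np.bincount(y, minlength=classes.size)
    root_impurity = _gini(root_counts)
    root = _grow(
        X, y, idx, classes.size, classes, X.shape[0], root_impurity,
        min_split, cp, feature_types,
    )
    _attach_names(root, list(feature_names))
    return ClassificationTree(
        root=root,
        classes_=classes,
        feature_names=list(feature_names),
        min_split=min_split,
        cp=cp,
        root_impurity=root_impurity,
        feature_types=list(feature_types),
    )


# ----------------------------------------------------------------------
# drop-down prediction and goodness-of-fit
# ----------------------------------------------------------------------

def drop_down(tree: ClassificationTree, genotypes) -> object:
    """Route one individual to a leaf; UNALLOCATED on a missing decision SNP."""
    x = np.asarray(genotypes)
    node = tree.root
    while not node.is_leaf:
        v = x[node.feature]
        if (np.isnan(v) if isinstance(v, float) else v == MISSING):
            return UNALLOCATED
        if node.left_categories is not None:
            node = node.left if int(v) in node.left_categories else node.right
        else:
            node = node.left if v <= node.threshold else node.right
    return node.prediction


def predict_many(tree: ClassificationTree, data) -> np.ndarray:
    """Vectorized drop-down for an (n, m) matrix; object array output."""
    X = _as_feature_matrix(data)
    out = np.empty(X.shape[0], dtype=object)

    def _route(node, idx):
        if idx.size == 0:
            return
        if node.is_leaf:
            out[idx] = node.prediction
            return
        v = X[idx, node.feature]
        miss = _is_missing(v)
        out[idx[miss]] = UNALLOCATED
        keep = idx[~miss]
        vk = v[~miss]
        if node.left_categories is not None:
            go_left = np.isin(vk, sorted(node.left_categories))
        else:
            go_left = vk <= node.threshold
        _route(node.left, keep[go_left])
        _route(node.right, keep[~go_left])

    _route(tree.root, np.arange(X.shape[0]))
    return out


@dataclass
class DropDownReport:
    """Agreement between tree predictions and model-based assignments."""

    n_total: int
    n_correct: int
    n_misclassified: int
    n_unallocated: int
    confusion: dict  # (reference, predicted) -> count, allocated only

    def __post_init__(self) -> None:
        if self.n_correct + self.n_misclassified + self.n_unallocated != self.n_total:
            raise ValueError("drop-down counts must partition n_total")

    @property
    def misclassified_fraction(self) -> float:
        return self.n_misclassified / self.n_total if self.n_total else float("nan")

    @property
    def unallocated_fraction(self) -> float:
        return self.n_unallocated / self.n_total if self.n_total else float("nan")


def drop_down_report(tree: ClassificationTree, data, reference_labels) -> DropDownReport:
    """Drop every individual down the tree and compare to reference labels."""
    X = _as_feature_matrix(data)
    ref = np.asarray(reference_labels)
    if ref.shape != (X.shape[0],):
        raise ValueError("reference labels length mismatch")
    pred = predict_many(tree, X)
    unallocated = pred == UNALLOCATED
    correct = (~unallocated) & (pred == ref.astype(object))
    confusion: dict = {}
    for r, p in zip(ref[~unallocated], pred[~unallocated]):
        key = (r, p)
        confusion[key] = confusion.get(key, 0) + 1
    return DropDownReport(
        n_total=int(X.shape[0]),
        n_correct=int(correct.sum()),
        n_misclassified=int((~unallocated).sum() - correct.sum()),
        n_unallocated=int(unallocated.sum()),
        confusion=confusion,
    )


# ----------------------------------------------------------------------
# random forest
# ----------------------------------------------------------------------

@dataclass
class ForestReport:
    n_trees: int
    mtry: int
    oob_error_rate: float
    importance_mda: np.ndarray
    importance_gini: np.ndarray
    seed: int | None
    feature_names: list[str]
    classes_: np.ndarray


def _encode_forest_features(X, feature_types):
    """Categorical columns get missing recoded as an extra category."""
    X = np.array(X, dtype=float, copy=True)
    for j, ftype in enumerate(feature_types):
        col = X[:, j]
        miss = np.isnan(col) | (col == MISSING)
        if ftype == "categorical":
            if miss.any():
                col[miss] = col[~miss].max() + 1 if (~miss).any() else 0
                X[:, j] = col
        elif miss.any():
            raise ValueError(
                f"numeric feature {j} contains missing values; impute first"
            )
    return X


def _gini_importance(node: TreeNode, acc: np.ndarray) -> None:
    if not node.is_leaf:
        acc[node.feature] += node.decrease
        _gini_importance(node.left, acc)
        _gini_importance(node.right, acc)


def fit_forest(
    features,
    labels,
    n_trees: int = 500,
    mtry: int | None = None,
    seed: int | None = None,
    feature_types: list[str] | None = None,
    feature_names: list[str] | None = None,
    min_split: int = 2,
) -> ForestReport:
    """Bagged subset-split trees with OOB error and two importances.

    ``importance_gini`` is the per-feature sum of root-scaled impurity
    decreases averaged over trees; ``importance_mda`` is the mean OOB
    accuracy drop after permuting each feature within the OOB sample.
    """
    X = _as_feature_matrix(features).astype(float)
    y_raw = np.asarray(labels)
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if y_raw.shape != (n,):
        raise ValueError("labels length mismatch")
    if feature_types is None:
        feature_types = ["categorical"] * m
    if feature_names is None:
        feature_names = (
            features.snp_ids
            if isinstance(features, GenotypeMatrix)
            else [f"f{j}" for j in range(m)]
        )
    if mtry is None:
        mtry = max(1, int(np.floor(np.sqrt(m))))
    if mtry > m:
        raise ValueError(f"mtry={mtry} exceeds {m} features")
    X = _encode_forest_features(X, feature_types)

    constant = np.array([np.unique(X[:, j]).size < 2 for j in range(m)])
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} feature(s) with zero variance; "
            "their importances are 0"
        )

    classes, y = np.unique(y_raw, return_inverse=True)
    k = classes.size
    rng = np.random.default_rng(seed)
    votes = np.zeros((n, k))
    mda = np.zeros(m)
    mda_trees = np.zeros(m)  # trees contributing an OOB sample
    gini_imp = np.zeros(m)

    all_idx = np.arange(n)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(all_idx, boot, assume_unique=False)
        Xb, yb = X[boot], y[boot]
        root_counts = np.bincount(yb, minlength=k)
        root = _grow(
            Xb, yb, np.arange(n), k, classes, n, _gini(root_counts),
            min_split, 0.0, feature_types, rng=rng, mtry=mtry,
        )
        tree = ClassificationTree(
            root=root, classes_=classes, feature_names=list(feature_names),
            min_split=min_split, cp=0.0, root_impurity=_gini(root_counts),
            feature_types=list(feature_types),
        )
        _gini_importance(root, gini_imp)
        if oob.size == 0:
            continue
        pred = predict_many(tree, X[oob])
        class_idx = {c: i for i, c in enumerate(classes)}
        for o, p in zip(oob, pred):
            if p != UNALLOCATED:
                votes[o, class_idx[p]] += 1
        acc = float(np.mean(pred == classes[y[oob]].astype(object)))
        for j in range(m):
            if constant[j]:
                continue
            Xp = X[oob].copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            pred_p = predict_many(tree, Xp)
            acc_p = float(np.mean(pred_p == classes[y[oob]].astype(object)))
            mda[j] += acc - acc_p
            mda_trees[j] += 1

    voted = votes.sum(axis=1) > 0
    oob_pred = np.argmax(votes, axis=1)
    oob_error = (
        float(np.mean(oob_pred[voted] != y[voted])) if voted.any() else float("nan")
    )
    with np.errstate(invalid="ignore"):
        mda = np.where(mda_trees > 0, mda / np.maximum(mda_trees, 1), 0.0)
    return ForestReport(
        n_trees=n_trees,
        mtry=mtry,
        oob_error_rate=oob_error,
        importance_mda=mda,
        importance_gini=gini_imp / n_trees,
        seed=seed,
        feature_names=list(feature_names),
        classes_=classes,
    )
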