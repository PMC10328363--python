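"""CART on threshold-binarized classifiers: Gini growth, cost-complexity
pruning, repeated cross-validation and purity-filtered rule extraction.

The tree operates on binary features only — each feature is the indicator
of one Youden-thresholded classifier (e.g. "HDL <= 1.425 mmol/L") — so a
split is a yes/no question, no variable can usefully appear twice on a
path, and every root-to-leaf path reads as an if-then clinical rule. Node
impurity is the Gini index 1 - sum(p_i^2); the grown tree is pruned by
weakest-link cost-complexity with the penalty chosen by stratified
cross-validated misclassification; rules are retained when the leaf holds
at least ``min_leaf`` participants with a positive-class proportion
strictly above ``rate_floor``.

This implementation is authored here by design; scikit-learn's tree serves
only as an independent oracle in the test suite.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .screening import ThresholdedClassifier, rank_auc

__all__ = [
    "CartParams",
    "TreeNode",
    "DecisionRule",
    "gini_impurity",
    "binarize_features",
    "grow_tree",
    "prune_tree",
    "prune_at_alpha",
    "cost_complexity_alphas",
    "repeated_cv",
    "extract_rules",
    "GiniTreeClassifier",
]


def gini_impurity(counts) -> float:
    """Binary Gini impurity 1 - p0^2 - p1^2 of a (n_neg, n_pos) node."""
    n_neg, n_pos = counts
    n = n_neg + n_pos
    if n < 1:
        raise ValueError("empty node has no impurity")
    p_neg, p_pos = n_neg / n, n_pos / n
    return 1.0 - p_neg * p_neg - p_pos * p_pos


@dataclass
class CartParams:
    """Tuning constants of the tree stage.

    min_leaf: smallest admissible child (and the rule-retention floor);
    rate_floor: strict lower bound on a retained rule's positive rate;
    max_depth: None means "number of binarized features";
    cv_splits / cv_test_fraction: Monte-Carlo splits for repeated_cv;
    prune_cv_folds: stratified folds used to pick the pruning penalty.
    """

    min_leaf: int = 20
    rate_floor: float = 0.70
    max_depth: int | None = None
    cv_splits: int = 100
    cv_test_fraction: float = 0.2
    prune_cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if not 0.0 < self.cv_test_fraction < 1.0:
            raise ValueError("cv_test_fraction must lie in (0, 1)")


@dataclass
class TreeNode:
    node_id: int
    depth: int
    counts: tuple[int, int]  # (n_negative, n_positive)
    gini: float
    split_variable: str | None = None
    split_feature: int | None = None
    left: "TreeNode | None" = None  # condition false
    right: "TreeNode | None" = None  # condition true

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def n(self) -> int:
        return self.counts[0] + self.counts[1]

    @property
    def positive_rate(self) -> float:
        return self.counts[1] / self.n

    @property
    def majority(self) -> int:
        # deterministic tie-break: exact 50/50 predicts the negative class
        return int(self.counts[1] > self.counts[0])

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def node_count(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + self.left.node_count() + self.right.node_count()

    def to_dict(self) -> dict:
        out = {
            "node_id": self.node_id,
            "depth": self.depth,
            "counts": list(self.counts),
            "gini": self.gini,
        }
        if not self.is_leaf:
            out["split_variable"] = self.split_variable
            out["left"] = self.left.to_dict()
            out["right"] = self.right.to_dict()
        else:
            out["positive_rate"] = self.positive_rate
        return out


def binarize_features(
    analysis: pd.DataFrame, thresholds: list[ThresholdedClassifier]
) -> pd.DataFrame:
    """Indicator table of the thresholded classifiers, one 0/1 column each.

    Values exactly at a cutpoint satisfy the inclusive comparator (>= / <=).
    Column order is alphabetical by variable for deterministic tie-breaks.
    """
    cols = {}
    for thr in sorted(thresholds, key=lambda t: t.variable):
        if thr.variable not in analysis.columns:
            raise KeyError(f"missing variable column {thr.variable!r}")
        cols[thr.variable] = thr.indicator(analysis[thr.variable])
    return pd.DataFrame(cols, index=analysis.index)


# ---------------------------------------------------------------------------
# growth


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    depth: int,
    used: frozenset[int],
    feature_names: list[str],
    params: CartParams,
    counter: list[int],
) -> TreeNode:
    n = len(idx)
    n_pos = int(y[idx].sum())
    n_neg = n - n_pos
    node = TreeNode(
        node_id=counter[0],
        depth=depth,
        counts=(n_neg, n_pos),
        gini=gini_impurity((n_neg, n_pos)),
    )
    counter[0] += 1
    max_depth = params.max_depth if params.max_depth is not None else X.shape[1]
    if node.gini == 0.0 or depth >= max_depth:
        return node
    best = None  # key = (-gain, name): min gives max gain, alphabetical ties
    for f in range(X.shape[1]):
        if f in used:
            continue
        is_right = X[idx, f] == 1
        n_r = int(is_right.sum())
        n_l = n - n_r
        if n_r < params.min_leaf or n_l < params.min_leaf:
            continue
        pos_r = int(y[idx[is_right]].sum())
        pos_l = n_pos - pos_r
        child_gini = (
            n_l * gini_impurity((n_l - pos_l, pos_l))
            + n_r * gini_impurity((n_r - pos_r, pos_r))
        ) / n
        gain = node.gini - child_gini  # always >= 0 for binary Gini
        key = (-gain, feature_names[f])
        if best is None or key < best[0]:
            best = (key, f, is_right)
    if best is None:
        return node
    _, f, is_right = best
    node.split_feature = f
    node.split_variable = feature_names[f]
    child_used = used | {f}
    node.left = _grow(
        X, y, idx[~is_right], depth + 1, child_used, feature_names, params, counter
    )
    node.right = _grow(
        X, y, idx[is_right], depth + 1, child_used, feature_names, params, counter
    )
    return node


def grow_tree(features: pd.DataFrame, labels, params: CartParams) -> TreeNode:
    """Grow a CART by recursive best-Gini binary splitting.

    Splits whenever the node is impure and an admissible split exists
    (both children >= min_leaf, depth < max_depth, feature unused on the
    path); ties in Gini decrease break alphabetically by feature name, so
    interaction-only structure (e.g. XOR, zero marginal gain) is still
    explored and left for pruning to arbitrate. Raises if only one class is
    present at the root; a root with no admissible split yields a
    single-leaf tree with a warning.
    """
    X = features.to_numpy(dtype=np.int8)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present at the root")
    names = [str(c) for c in features.columns]
    tree = _grow(X, y, np.arange(len(y)), 0, frozenset(), names, params, [0])
    if tree.is_leaf:
        warnings.warn("no valid split at the root; returning a single-leaf tree")
    return tree


def _leaf_apply(tree: TreeNode, X: np.ndarray, value) -> np.ndarray:
    """Vectorised routing: assign value(leaf) to every row."""
    out = np.empty(len(X), dtype=float)

    def descend(node: TreeNode, idx: np.ndarray):
        if node.is_leaf:
            out[idx] = value(node)
            return
        is_right = X[idx, node.split_feature] == 1
        descend(node.left, idx[~is_right])
        descend(node.right, idx[is_right])

    descend(tree, np.arange(len(X)))
    return out


def _as_int_matrix(features) -> np.ndarray:
    return (
        features.to_numpy(dtype=np.int8)
        if isinstance(features, pd.DataFrame)
        else np.asarray(features, dtype=np.int8)
    )


def predict_rates(tree: TreeNode, features) -> np.ndarray:
    """Training positive-proportion of the leaf each row falls into."""
    return _leaf_apply(tree, _as_int_matrix(features), lambda n: n.positive_rate)


def predict_classes(tree: TreeNode, features) -> np.ndarray:
    return _leaf_apply(tree, _as_int_matrix(features), lambda n: n.majority).astype(int)


# ---------------------------------------------------------------------------
# cost-complexity pruning


def _resubstitution_error(node: TreeNode, n_total: int) -> float:
    """Misclassification contribution of a node treated as a leaf."""
    return min(node.counts) / n_total


def _subtree_error(node: TreeNode, n_total: int) -> float:
    return sum(_resubstitution_error(leaf, n_total) for leaf in node.leaves())


def cost_complexity_alphas(tree: TreeNode) -> list[float]:
    """Weakest-link penalty sequence (increasing) of a grown tree."""
    n_total = tree.n
    work = copy.deepcopy(tree)
    alphas: list[float] = []
    while not work.is_leaf:
        weakest: list[tuple[float, TreeNode]] = []

        def visit(node: TreeNode) -> tuple[float, int]:
            """Bottom-up (subtree error, leaf count); records g per internal node."""
            if node.is_leaf:
                return _resubstitution_error(node, n_total), 1
            err_l, leaves_l = visit(node.left)
            err_r, leaves_r = visit(node.right)
            err, leaves = err_l + err_r, leaves_l + leaves_r
            g = (_resubstitution_error(node, n_total) - err) / (leaves - 1)
            weakest.append((g, node))
            return err, leaves

        visit(work)
        g_min = min(g for g, _ in weakest)
        alphas.append(max(g_min, 0.0))
        for g, node in weakest:
            if g <= g_min + 1e-15 and not node.is_leaf:
                node.left = node.right = None
                node.split_variable = node.split_feature = None
    return sorted(set(alphas))


def prune_at_alpha(tree: TreeNode, alpha: float) -> TreeNode:
    """Smallest optimally pruned subtree for penalty ``alpha`` (a copy)."""
    n_total = tree.n
    pruned = copy.deepcopy(tree)

    def collapse(node: TreeNode) -> tuple[float, int]:
        """Returns (error, n_leaves) of the optimally pruned subtree."""
        if node.is_leaf:
            return _resubstitution_error(node, n_total), 1
        err_l, leaves_l = collapse(node.left)
        err_r, leaves_r = collapse(node.right)
        err, leaves = err_l + err_r, leaves_l + leaves_r
        here = _resubstitution_error(node, n_total)
        if here - err <= alpha * (leaves - 1) + 1e-15:
            node.left = node.right = None
            node.split_variable = node.split_feature = None
            return here, 1
        return err, leaves

    collapse(pruned)
    return pruned


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    fold = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def prune_tree(
    tree: TreeNode,
    features: pd.DataFrame,
    labels,
    params: CartParams,
    rng: np.random.Generator | None = None,
) -> tuple[TreeNode, float]:
    """Cost-complexity pruning with the penalty picked by cross-validation.

    Candidate penalties are the geometric means of the weakest-link
    sequence of the input tree (plus 0 and infinity); each candidate is
    scored by stratified ``prune_cv_folds``-fold misclassification of trees
    grown on the training folds and pruned at that penalty; the selected
    penalty is the largest one within one standard error of the minimum CV
    error (the 1-SE rule, favouring the smaller tree). Returns
    (pruned tree, alpha). The pruned tree is a rooted subtree of the input.
    """
    if tree.is_leaf:
        return copy.deepcopy(tree), 0.0
    rng = rng or np.random.default_rng(params.seed)
    y = np.asarray(labels, dtype=int)
    X = features
    alphas = cost_complexity_alphas(tree)
    positives = [a for a in alphas if a > 0]
    candidates = [0.0]
    if positives:
        lo = min(positives) / 2.0
        candidates.append(lo)
        candidates.extend(
            float(np.sqrt(a * b)) for a, b in zip(positives[:-1], positives[1:])
        )
        candidates.extend(positives)
    candidates.append(np.inf)
    candidates = sorted(set(candidates))

    folds = _stratified_folds(y, params.prune_cv_folds, rng)
    errors = np.zeros(len(candidates))
    for k in range(params.prune_cv_folds):
        train, test = folds != k, folds == k
        if len(np.unique(y[train])) < 2 or test.sum() == 0:
            continue
        fold_tree = grow_tree(X.loc[train] if isinstance(X, pd.DataFrame) else X[train],
                              y[train], params)
        X_test = X.loc[test] if isinstance(X, pd.DataFrame) else X[test]
        for i, alpha in enumerate(candidates):
            sub = prune_at_alpha(fold_tree, alpha)
            errors[i] += int((predict_classes(sub, X_test) != y[test]).sum())
    # 1-SE rule: the largest alpha within one binomial SE of the minimum CV
    # error (ties in noisy error curves otherwise pick arbitrary subtrees)
    n_scored = len(y)
    best_error = errors.min()
    p_hat = best_error / n_scored
    se = np.sqrt(max(p_hat * (1.0 - p_hat), 0.0) * n_scored)
    best_alpha = max(a for a, e in zip(candidates, errors) if e <= best_error + se + 1e-9)
    return prune_at_alpha(tree, best_alpha), float(best_alpha)


# ---------------------------------------------------------------------------
# repeated cross-validation


def repeated_cv(
    features: pd.DataFrame,
    labels,
    params: CartParams,
    rng: np.random.Generator | None = None,
) -> tuple[float, list[float]]:
    """Mean AUC over seeded stratified Monte-Carlo train/test splits.

    Each of ``cv_splits`` splits holds out ``cv_test_fraction`` of each
    class, grows and prunes a tree on the rest, scores the held-out rows by
    the training positive-proportion of their leaf, and computes the AUC. A
    degenerate split (a class absent) is resampled with a warning.
    """
    rng = rng or np.random.default_rng(params.seed)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    aucs: list[float] = []
    attempts = 0
    while len(aucs) < params.cv_splits:
        attempts += 1
        if attempts > 10 * params.cv_splits:
            raise RuntimeError("too many degenerate cross-validation splits")
        test = np.zeros(len(y), dtype=bool)
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            n_test = max(1, int(round(params.cv_test_fraction * len(idx))))
            test[idx[:n_test]] = True
        train = ~test
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            warnings.warn("degenerate split resampled")
            continue
        tree = grow_tree(features.loc[train], y[train], params)
        pruned, _ = prune_tree(tree, features.loc[train], y[train], params, rng)
        scores = predict_rates(pruned, features.loc[test])
        if len(np.unique(scores)) == 1:
            aucs.append(0.5)  # root-only tree carries no discrimination
        else:
            aucs.append(rank_auc(scores, y[test]))
    return float(np.mean(aucs)), aucs


# ---------------------------------------------------------------------------
# rule extraction


@dataclass
class DecisionRule:
    """Root-to-leaf condition path with its subgroup sizes and rates."""

    conditions: list[tuple[str, str, float]]  # (variable, comparator, cutpoint)
    leaf_n: int
    positive_rate: float
    first_step_n: int
    first_step_rate: float

    _COMPARATORS = {"ge": ">=", "le": "<=", "gt": ">", "lt": "<"}

    def to_dict(self) -> dict:
        return {
            "conditions": [
                {"variable": v, "comparator": self._COMPARATORS[d], "cutpoint": c}
                for v, d, c in self.conditions
            ],
            "leaf_n": self.leaf_n,
            "positive_rate": self.positive_rate,
            "first_step_n": self.first_step_n,
            "first_step_rate": self.first_step_rate,
        }

    def describe(self) -> str:
        conds = ", ".join(
            f"{v} {self._COMPARATORS[d]} {c:g}" for v, d, c in self.conditions
        )
        return (
            f"If {conds}: N = {self.leaf_n}, "
            f"positive rate = {100 * self.positive_rate:.1f}%"
        )


def extract_rules(
    tree: TreeNode,
    thresholds: dict[str, ThresholdedClassifier],
    params: CartParams,
) -> list[DecisionRule]:
    """One candidate rule per leaf, filtered by size and purity.

    A right branch restates the oriented threshold (inclusive comparator);
    a left branch is its strict complement. Retained rules have
    ``leaf_n >= min_leaf`` and ``positive_rate > rate_floor`` (strict).
    Rules are ordered by descending positive rate, then leaf size.
    """
    rules: list[DecisionRule] = []

    def walk(node: TreeNode, path: list[tuple[str, str, float]], first: TreeNode | None):
        if node.is_leaf:
            if node.n >= params.min_leaf and node.positive_rate > params.rate_floor:
                fs = first if first is not None else node
                rules.append(
                    DecisionRule(
                        conditions=list(path),
                        leaf_n=node.n,
                        positive_rate=node.positive_rate,
                        first_step_n=fs.n,
                        first_step_rate=fs.positive_rate,
                    )
                )
            return
        thr = thresholds[node.split_variable]
        left_cond = (node.split_variable, thr.complement_direction(), thr.cutpoint)
        right_cond = (node.split_variable, thr.direction, thr.cutpoint)
        walk(node.left, path + [left_cond], first if first is not None else node.left)
        walk(node.right, path + [right_cond], first if first is not None else node.right)

    walk(tree, [], None)
    rules.sort(key=lambda r: (-r.positive_rate, -r.leaf_n))
    return rules


def rules_to_json(rules: list[DecisionRule]) -> str:
    return json.dumps([r.to_dict() for r in rules], indent=2)


# ---------------------------------------------------------------------------
# estimator facade


class GiniTreeClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style CART classifier over binary (thresholded) features.

    Parameters mirror :class:`CartParams`. Fitted attributes:
    ``tree_`` (grown), ``pruned_tree_``, ``alpha_`` (selected penalty),
    ``feature_names_in_``, ``classes_``.
    """

    def __init__(
        self,
        min_leaf: int = 20,
        max_depth: int | None = None,
        prune: bool = True,
        prune_cv_folds: int = 10,
        random_state: int = 0,
    ):
        self.min_leaf = min_leaf
        self.max_depth = max_depth
        self.prune = prune
        self.prune_cv_folds = prune_cv_folds
        self.random_state = random_state

    def _params(self) -> CartParams:
        return CartParams(
            min_leaf=self.min_leaf,
            max_depth=self.max_depth,
            prune_cv_folds=self.prune_cv_folds,
            seed=self.random_state,
        )

    def fit(self, X: pd.DataFrame, y) -> "GiniTreeClassifier":
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        params = self._params()
        self.feature_names_in_ = np.asarray([str(c) for c in X.columns])
        self.classes_ = np.unique(np.asarray(y))
        self.tree_ = grow_tree(X, y, params)
        if self.prune:
            self.pruned_tree_, self.alpha_ = prune_tree(self.tree_, X, y, params)
        else:
            self.pruned_tree_, self.alpha_ = self.tree_, 0.0
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        rate = predict_rates(self.pruned_tree_, X)
        return np.column_stack([1.0 - rate, rate])

    def predict(self, X) -> np.ndarray:
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        return predict_classes(self.pruned_tree_, X)
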