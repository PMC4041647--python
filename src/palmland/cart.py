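"""Classification trees (CART) with Gini splits and cross-validated
cost-complexity pruning, written from first principles.

The induction procedure is the classical one: binary recursive partitioning
on numeric predictors, choosing at each node the axis-aligned split that
maximises the weighted Gini impurity decrease, searched exhaustively over
midpoints between consecutive distinct values.  Ties are broken by predictor
declaration order, then by the lower threshold, which together with stable
sorting makes induction fully deterministic.

Pruning follows Breiman's minimal cost-complexity scheme: the weakest-link
sequence of nested subtrees is computed, the complexity parameter is chosen
by stratified K-fold cross-validated misclassification with the
one-standard-error rule, and the full tree is pruned at that parameter.

Ordinal predictors (the 1-4 soil suitability scale) are split as numeric;
a split pair 1.5 < soil <= 2.5 is how a single named soil class appears in
an extracted rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf, sqrt

import numpy as np
import pandas as pd

from .suitability import Condition, Rule, RuleSet

__all__ = [
    "gini",
    "best_split",
    "grow_tree",
    "prune_tree_cv",
    "extract_rules",
    "DecisionTree",
    "Node",
]

LEAF = None  # sentinel: no valid split


def gini(labels) -> float:
    """Gini impurity 1 - sum_k p_k**2 of a multiset of class labels.

    Raises
    ------
    ValueError
        On empty input.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("gini impurity of an empty multiset is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(1.0 - np.sum(p * p))


def _gini_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


@dataclass
class Node:
    counts: np.ndarray               # per-class training counts reaching here
    depth: int
    feature: int | None = None       # None for a leaf
    threshold: float = float("nan")
    left: "Node | None" = None
    right: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def prediction(self) -> int:
        """Majority class index; ties go to the lower class index."""
        return int(np.argmax(self.counts))

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def internal_nodes(self) -> list["Node"]:
        if self.is_leaf:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()

    def copy(self) -> "Node":
        return Node(
            counts=self.counts.copy(), depth=self.depth, feature=self.feature,
            threshold=self.threshold,
            left=self.left.copy() if self.left else None,
            right=self.right.copy() if self.right else None,
        )

    def to_leaf(self) -> None:
        self.feature = None
        self.threshold = float("nan")
        self.left = None
        self.right = None


@dataclass
class DecisionTree:
    """A fitted classification tree.

    ``classes`` maps class indices to labels (sorted label order);
    ``features`` names the predictor columns in declaration order.
    ``cv_accuracy`` is populated by :func:`prune_tree_cv`.
    """

    root: Node
    classes: tuple
    features: tuple[str, ...]
    min_leaf: int = 5
    max_depth: int | None = 10
    cv_accuracy: float | None = None

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.features)
        out_idx = np.empty(len(X), dtype=np.int64)
        self._predict_into(self.root, X, np.arange(len(X)), out_idx)
        return np.asarray(self.classes, dtype=object)[out_idx]

    def _predict_into(self, node: Node, X, idx, out) -> None:
        if node.is_leaf:
            out[idx] = node.prediction
            return
        go_left = X[idx, node.feature] <= node.threshold
        self._predict_into(node.left, X, idx[go_left], out)
        self._predict_into(node.right, X, idx[~go_left], out)

    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def depth(self) -> int:
        return max(leaf.depth for leaf in self.root.leaves())

    def thresholds(self) -> dict[str, list[float]]:
        """Split thresholds present in the tree, keyed by feature name."""
        out: dict[str, list[float]] = {}
        for nd in self.root.internal_nodes():
            out.setdefault(self.features[nd.feature], []).append(nd.threshold)
        return {k: sorted(v) for k, v in out.items()}

    def training_accuracy(self, samples: pd.DataFrame, label_col: str = "label") -> float:
        pred = self.predict(samples)
        return float(np.mean(pred == samples[label_col].to_numpy()))

    def describe(self) -> str:
        lines: list[str] = []

        def walk(node: Node, indent: str) -> None:
            if node.is_leaf:
                lines.append(
                    f"{indent}-> {self.classes[node.prediction]} "
                    f"(n={node.n}, counts={node.counts.tolist()})"
                )
                return
            name = self.features[node.feature]
            lines.append(f"{indent}{name} <= {node.threshold:g}?")
            walk(node.left, indent + "  ")
            lines.append(f"{indent}{name} > {node.threshold:g}?")
            walk(node.right, indent + "  ")

        walk(self.root, "")
        return "\n".join(lines)


def _as_matrix(X, features) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.loc[:, list(features)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    return X


def _encode(samples: pd.DataFrame, features, label_col):
    X = _as_matrix(samples, features)
    labels = samples[label_col].to_numpy()
    classes = tuple(sorted(pd.unique(labels)))
    lut = {c: i for i, c in enumerate(classes)}
    y = np.fromiter((lut[v] for v in labels), dtype=np.int64, count=len(labels))
    return X, y, classes


def _search_split(X, y, n_classes: int, min_leaf: int):
    """Exhaustive midpoint search over all features.

    Returns (feature, threshold, impurity_decrease) or ``None`` when no
    split produces a strictly positive decrease under the min_leaf
    constraint.  Ties: first feature in declaration order, then the lowest
    threshold.
    """
    n = len(y)
    parent_counts = np.bincount(y, minlength=n_classes)
    g_parent = _gini_from_counts(parent_counts)
    best = None
    for j in range(X.shape[1]):
        xj = X[:, j]
        order = np.argsort(xj, kind="stable")
        xs = xj[order]
        ys = y[order]
        # cumulative class counts over the sorted prefix
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), ys] = 1.0
        cum = np.cumsum(onehot, axis=0)
        i = np.arange(1, n)                      # split after position i-1
        valid = xs[1:] > xs[:-1]
        if min_leaf > 1:
            valid &= (i >= min_leaf) & (n - i >= min_leaf)
        if not valid.any():
            continue
        nl = i[valid].astype(float)
        nr = n - nl
        cl = cum[:-1][valid]
        cr = parent_counts - cl
        g_left = 1.0 - np.sum((cl / nl[:, None]) ** 2, axis=1)
        g_right = 1.0 - np.sum((cr / nr[:, None]) ** 2, axis=1)
        decrease = g_parent - (nl / n) * g_left - (nr / n) * g_right
        k = int(np.argmax(decrease))             # first max = lowest threshold
        if decrease[k] <= 1e-12:
            continue
        thr = 0.5 * (xs[i[valid][k] - 1] + xs[i[valid][k]])
        if best is None or decrease[k] > best[2] + 1e-12:
            best = (j, float(thr), float(decrease[k]))
    return best


def best_split(samples: pd.DataFrame, candidate_vars: list[str],
               label_col: str = "label", min_leaf: int = 1):
    """Best axis-aligned split of a labelled sample table.

    Returns ``(variable_name, threshold, impurity_decrease)``, or ``None``
    (the leaf sentinel) when no split with positive impurity decrease exists
    — e.g. pure labels, or conflicting labels at identical coordinates.

    Raises
    ------
    ValueError
        With fewer than two samples.
    """
    if len(samples) < 2:
        raise ValueError("best_split needs at least 2 samples")
    X, y, classes = _encode(samples, candidate_vars, label_col)
    if len(classes) < 2:
        return LEAF
    found = _search_split(X, y, len(classes), min_leaf)
    if found is None:
        return LEAF
    j, thr, dec = found
    return (candidate_vars[j], thr, dec)


def _grow(X, y, n_classes, depth, min_leaf, max_depth) -> Node:
    counts = np.bincount(y, minlength=n_classes)
    node = Node(counts=counts, depth=depth)
    if (counts > 0).sum() < 2:
        return node
    if max_depth is not None and depth >= max_depth:
        return node
    if len(y) < 2 * min_leaf:
        return node
    found = _search_split(X, y, n_classes, min_leaf)
    if found is None:
        return node
    j, thr, _ = found
    go_left = X[:, j] <= thr
    node.feature = j
    node.threshold = thr
    node.left = _grow(X[go_left], y[go_left], n_classes, depth + 1, min_leaf, max_depth)
    node.right = _grow(X[~go_left], y[~go_left], n_classes, depth + 1, min_leaf, max_depth)
    return node


def grow_tree(samples: pd.DataFrame, features: list[str] | None = None,
              label_col: str = "label", min_leaf: int = 5,
              max_depth: int | None = 10) -> DecisionTree:
    """Grow a classification tree by recursive Gini partitioning.

    Partitioning stops at purity, at ``max_depth``, or when a node cannot be
    split with both children holding at least ``min_leaf`` samples; a sample
    table smaller than ``2 * min_leaf`` yields a single-leaf tree.
    Deterministic: stable sorts and fixed tie-breaking.
    """
    if features is None:
        features = [c for c in samples.columns if c != label_col]
    X, y, classes = _encode(samples, features, label_col)
    root = _grow(X, y, len(classes), 0, min_leaf, max_depth)
    return DecisionTree(root=root, classes=classes, features=tuple(features),
                        min_leaf=min_leaf, max_depth=max_depth)


# ---------------------------------------------------------------------------
# minimal cost-complexity pruning


def _subtree_risk(node: Node, n_total: int) -> tuple[float, int]:
    """(training misclassification risk of the subtree, leaf count)."""
    if node.is_leaf:
        return (node.n - node.counts.max()) / n_total, 1
    rl, ll = _subtree_risk(node.left, n_total)
    rr, lr = _subtree_risk(node.right, n_total)
    return rl + rr, ll + lr


def _weakest_links(root: Node, n_total: int) -> tuple[float, list[Node]]:
    """Minimum g(t) = (R(t) - R(T_t)) / (leaves - 1) and the nodes attaining it."""
    best_g = inf
    nodes: list[Node] = []
    for t in root.internal_nodes():
        r_node = (t.n - t.counts.max()) / n_total
        r_sub, leaves = _subtree_risk(t, n_total)
        g = (r_node - r_sub) / (leaves - 1)
        if g < best_g - 1e-15:
            best_g, nodes = g, [t]
        elif abs(g - best_g) <= 1e-15:
            nodes.append(t)
    return best_g, nodes


def pruning_path(tree: DecisionTree) -> list[tuple[float, DecisionTree]]:
    """Weakest-link sequence [(alpha_0=0, T_0), (alpha_1, T_1), ...] of
    nested subtrees ending at the root-only tree; alphas are nondecreasing."""
    n_total = tree.root.n
    work = tree.root.copy()
    path = [(0.0, DecisionTree(work.copy(), tree.classes, tree.features,
                               tree.min_leaf, tree.max_depth))]
    while not work.is_leaf:
        alpha, nodes = _weakest_links(work, n_total)
        for t in nodes:
            t.to_leaf()
        path.append((max(0.0, alpha),
                     DecisionTree(work.copy(), tree.classes, tree.features,
                                  tree.min_leaf, tree.max_depth)))
    return path


def prune_at(tree: DecisionTree, alpha: float) -> DecisionTree:
    """Smallest subtree in the weakest-link sequence whose alpha <= ``alpha``."""
    chosen = None
    for a, sub in pruning_path(tree):
        if a <= alpha + 1e-15:
            chosen = sub
        else:
            break
    return chosen


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator):
    """Fold id per sample, stratified by class, seeded."""
    assign = np.empty(len(y), dtype=np.int64)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


def prune_tree_cv(tree: DecisionTree, samples: pd.DataFrame,
                  folds: int = 10, seed: int = 0,
                  label_col: str = "label") -> DecisionTree:
    """Cost-complexity pruning with the complexity parameter chosen by
    stratified K-fold cross-validated misclassification and the
    one-standard-error rule.

    Candidate parameters are the geometric means of consecutive alphas on
    the full tree's weakest-link path.  The returned tree carries the pooled
    cross-validated accuracy of the chosen parameter in ``cv_accuracy``.
    Deterministic for a given seed.

    Raises
    ------
    ValueError
        If ``folds`` < 2.
    """
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    path = pruning_path(tree)
    alphas = [a for a, _ in path]
    candidates = [0.0]
    for a0, a1 in zip(alphas[:-1], alphas[1:]):
        candidates.append(sqrt(max(a0, 0.0) * max(a1, 0.0)) if a0 > 0 else a1 / 2.0)
    candidates.append(alphas[-1] * 2.0 + 1.0)  # root-only regime
    candidates = sorted(set(candidates))

    X, y_enc, classes = _encode(samples, tree.features, label_col)
    labels = samples[label_col].to_numpy()
    rng = np.random.default_rng(seed)
    fold_of = _stratified_folds(y_enc, folds, rng)

    fold_rates = np.full((folds, len(candidates)), np.nan)
    for f in range(folds):
        train = samples.loc[fold_of != f]
        test_mask = fold_of == f
        if test_mask.sum() == 0 or len(train) == 0:
            continue
        fold_tree = grow_tree(train, features=list(tree.features),
                              label_col=label_col, min_leaf=tree.min_leaf,
                              max_depth=tree.max_depth)
        test = samples.loc[test_mask]
        true = labels[test_mask]
        for k, alpha in enumerate(candidates):
            sub = prune_at(fold_tree, alpha)
            fold_rates[f, k] = np.mean(sub.predict(test) != true)

    rates = np.nanmean(fold_rates, axis=0)
    k_min = int(np.argmin(rates))
    # SE of the CV estimate from fold-to-fold variation (the CART convention)
    col = fold_rates[:, k_min]
    col = col[~np.isnan(col)]
    se = float(col.std(ddof=1) / sqrt(len(col))) if len(col) > 1 else 0.0
    # one-SE rule: largest (simplest) alpha within one SE of the minimum
    k_sel = max(k for k in range(len(candidates)) if rates[k] <= rates[k_min] + se + 1e-12)
    pruned = prune_at(tree, candidates[k_sel])
    pruned.cv_accuracy = float(1.0 - rates[k_sel])
    return pruned


# ---------------------------------------------------------------------------
# rule extraction


def extract_rules(tree: DecisionTree, minority_label=None) -> RuleSet:
    """Read a tree out as interval-conjunction rules.

    One rule per leaf predicting the minority class (by default the class
    with the smaller total training count; the majority class becomes the
    rule-set default).  Predictions of the extracted rule set equal the
    tree's own predictions on every input.
    """
    totals = tree.root.counts
    if minority_label is None:
        minority_idx = int(np.argmin(totals))
    else:
        minority_idx = tree.classes.index(minority_label)
    default = tree.classes[int(np.argmax(totals))] if len(tree.classes) > 1 else tree.classes[0]
    if len(tree.classes) > 1 and default == tree.classes[minority_idx]:
        # two-class tie or explicit minority choice: default is the other class
        default = next(c for i, c in enumerate(tree.classes) if i != minority_idx)

    rules: list[Rule] = []

    def walk(node: Node, bounds: dict[int, tuple[float, float]]) -> None:
        if node.is_leaf:
            if node.prediction == minority_idx:
                conds = tuple(
                    Condition(var=tree.features[j], low=lo, high=hi)
                    for j, (lo, hi) in sorted(bounds.items())
                    if lo != -inf or hi != inf
                )
                rules.append(Rule(conditions=conds, label=tree.classes[minority_idx]))
            return
        j, t = node.feature, node.threshold
        lo, hi = bounds.get(j, (-inf, inf))
        walk(node.left, {**bounds, j: (lo, min(hi, t))})
        walk(node.right, {**bounds, j: (max(lo, t), hi)})

    walk(tree.root, {})
    return RuleSet(rules=tuple(rules), default=default)
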