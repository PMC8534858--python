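"""A transparent, cost-sensitive decision-tree engine for count features.

The engine grows binary trees on per-patient code-occurrence counts with
three behavioural profiles mirroring the classical tree families used in
EHR phenotyping:

``cart``
    Gini criterion, a minimum node size for attempting a split
    (``min_split``), and cost-complexity pruning controlled by ``cp``.
``c50``
    Entropy criterion, a minimum child size (``min_child``, the smallest
    number of patients that must land in each side of a split), and
    asymmetric misclassification cost: every positive training patient is
    weighted by ``fn_cost`` in all counts, impurities, and leaf labels, so
    raising ``fn_cost`` pushes leaves toward predicting the rare positive
    class.
``ci``
    Significance-stopped growth: a split is only made if the chosen
    feature's chi-square association p-value, Bonferroni-corrected over the
    candidate features at the node, satisfies ``1 - p >= mincriterion``.

All profiles share the same split search: every (feature, threshold)
candidate is scored by cost-weighted impurity gain, with thresholds at
midpoints between distinct observed counts and the left branch taking
``count <= threshold``. Ties break toward the lowest feature index, then
the smallest threshold, so fits are exactly reproducible.

Leaves predict the class with the smaller expected misclassification cost
(ties go to the positive class). Every root-to-leaf path exports as one
human-readable rule.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError
from .io import CodeDictionary
from .represent import PatientTermMatrix

PROFILES = ("cart", "c50", "ci")
CRITERIA = ("gini", "entropy", "dkm")

_GAIN_EPS = 1e-12


def _impurity(criterion: str, w_pos: float, w_neg: float) -> float:
    n = w_pos + w_neg
    if n <= 0:
        return 0.0
    q = w_pos / n
    if criterion == "gini":
        return 2.0 * q * (1.0 - q)
    if criterion == "entropy":
        h = 0.0
        if 0.0 < q:
            h -= q * math.log2(q)
        if q < 1.0:
            h -= (1.0 - q) * math.log2(1.0 - q)
        return h
    if criterion == "dkm":
        return 2.0 * math.sqrt(max(q * (1.0 - q), 0.0))
    raise ConfigurationError(f"unknown criterion {criterion!r}")


@dataclasses.dataclass
class TreeNode:
    """One node of a fitted tree.

    ``class_counts`` are raw training patient counts (n_neg, n_pos) at the
    node; ``weighted_counts`` apply the false-negative cost to positives.
    Internal nodes carry a (feature, threshold) split with the left child
    taking ``count <= threshold``.
    """

    class_counts: tuple[int, int]
    weighted_counts: tuple[float, float]
    predicted: int
    depth: int
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()

    def n_nodes(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + self.left.n_nodes() + self.right.n_nodes()

    def max_depth(self) -> int:
        if self.is_leaf:
            return self.depth
        return max(self.left.max_depth(), self.right.max_depth())

    def risk(self) -> float:
        """Weighted misclassification cost if this node were a leaf."""
        w_neg, w_pos = self.weighted_counts
        return w_pos if self.predicted == 0 else w_neg

    def subtree_risk(self) -> float:
        if self.is_leaf:
            return self.risk()
        return self.left.subtree_risk() + self.right.subtree_risk()

    def to_dict(self) -> dict:
        d = {
            "class_counts": list(self.class_counts),
            "weighted_counts": list(self.weighted_counts),
            "predicted": self.predicted,
            "depth": self.depth,
        }
        if not self.is_leaf:
            d["feature"] = int(self.feature)
            d["threshold"] = float(self.threshold)
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(
            class_counts=tuple(d["class_counts"]),
            weighted_counts=tuple(d["weighted_counts"]),
            predicted=int(d["predicted"]),
            depth=int(d["depth"]),
        )
        if "feature" in d:
            node.feature = int(d["feature"])
            node.threshold = float(d["threshold"])
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


def _predict_label(w_neg: float, w_pos: float) -> int:
    # expected cost of predicting 0 is w_pos, of predicting 1 is w_neg;
    # ties go to the positive (rare) class
    return 1 if w_pos >= w_neg else 0


class PhenotypeDecisionTree(BaseEstimator, ClassifierMixin):
    """Cost-sensitive decision tree over code-count features.

    Parameters
    ----------
    profile : {"cart", "c50", "ci"}
        Behavioural profile; sets the stopping machinery (see module docs).
    criterion : {"gini", "entropy", "dkm"} or None
        Split impurity; None selects the profile default (gini for cart and
        ci, entropy for c50).
    min_split : int, default 2
        Smallest node (patient count) eligible for splitting.
    min_child : int, default 1
        Smallest allowed child node.
    fn_cost : float >= 1, default 1.0
        Cost of misclassifying a positive as negative, relative to a
        false-positive cost of 1. Implemented by weighting positive
        patients in every count, impurity and leaf label.
    cp : float in [0, 1], default 0.0
        Complexity parameter: after growth, cost-complexity pruning removes
        splits whose per-split relative risk reduction falls below ``cp``.
    mincriterion : float in (0, 1), default 0.95
        ci profile only: a split requires 1 - (Bonferroni-corrected
        chi-square p-value) >= mincriterion.
    max_depth : int or None
        Optional depth cap (root depth 0).
    seed : int, default 0
        Recorded for provenance; growth is deterministic.

    Attributes
    ----------
    tree_ : TreeNode
        Root of the fitted tree.
    classes_ : ndarray [0, 1]
    n_features_in_ : int
    feature_names_in_ : list of str, when fitted via code names
    n_fits_ : int, number of grow calls (always 1; kept for accounting)
    """

    def __init__(
        self,
        profile: str = "cart",
        criterion: str | None = None,
        min_split: int = 2,
        min_child: int = 1,
        fn_cost: float = 1.0,
        cp: float = 0.0,
        mincriterion: float = 0.95,
        max_depth: int | None = None,
        seed: int = 0,
    ):
        self.profile = profile
        self.criterion = criterion
        self.min_split = min_split
        self.min_child = min_child
        self.fn_cost = fn_cost
        self.cp = cp
        self.mincriterion = mincriterion
        self.max_depth = max_depth
        self.seed = seed

    # -- validation ---------------------------------------------------------

    def _validated(self):
        if self.profile not in PROFILES:
            raise ConfigurationError(f"unknown profile {self.profile!r}")
        criterion = self.criterion
        if criterion is None:
            criterion = "entropy" if self.profile == "c50" else "gini"
        if criterion not in CRITERIA:
            raise ConfigurationError(f"unknown criterion {criterion!r}")
        if self.min_split < 2:
            raise ConfigurationError("min_split must be >= 2")
        if self.min_child < 1:
            raise ConfigurationError("min_child must be >= 1")
        if self.fn_cost < 1:
            raise ConfigurationError("fn_cost must be >= 1")
        if not 0.0 <= self.cp <= 1.0:
            raise ConfigurationError("cp must lie in [0, 1]")
        if not 0.0 < self.mincriterion < 1.0:
            raise ConfigurationError("mincriterion must lie in (0, 1)")
        return criterion

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        criterion = self._validated()
        if sp.issparse(X):
            X = np.asarray(X.todense())
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if X.shape[1] == 0:
            raise ConfigurationError("cannot fit a tree with no features")
        y = np.asarray(y).astype(int).ravel()
        if len(y) != X.shape[0]:
            raise ValueError("X and y are misaligned")
        if X.shape[0] == 0:
            raise ValueError("cannot fit a tree on an empty dataset")
        if feature_names is not None and len(feature_names) != X.shape[1]:
            raise ValueError("feature_names length mismatch")

        self._criterion_ = criterion
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = list(feature_names) if feature_names is not None else None
        w = np.where(y == 1, float(self.fn_cost), 1.0)
        self.tree_ = self._grow(X, y, w, depth=0)
        if self.profile == "cart" and self.cp > 0:
            self.tree_ = _prune(self.tree_, self.cp)
        self.n_fits_ = 1
        return self

    def _make_leaf(self, y, w, depth) -> TreeNode:
        n_pos = int(np.sum(y == 1))
        n_neg = len(y) - n_pos
        w_pos = float(np.sum(w[y == 1]))
        w_neg = float(np.sum(w[y == 0]))
        return TreeNode(
            class_counts=(n_neg, n_pos),
            weighted_counts=(w_neg, w_pos),
            predicted=_predict_label(w_neg, w_pos),
            depth=depth,
        )

    def _grow(self, X, y, w, depth) -> TreeNode:
        node = self._make_leaf(y, w, depth)
        n_neg, n_pos = node.class_counts
        n = n_neg + n_pos
        if n_pos == 0 or n_neg == 0:
            return node
        if n < self.min_split:
            return node
        if self.max_depth is not None and depth >= self.max_depth:
            return node

        best = self._best_split(X, y, w)
        if best is None:
            return node
        j, thr, gain, n_candidates = best

        if self.profile == "ci":
            p = _split_pvalue(X[:, j], y, w, thr)
            p_adj = min(1.0, p * max(n_candidates, 1))
            if not (1.0 - p_adj >= self.mincriterion):
                return node

        left_mask = X[:, j] <= thr
        node.feature = int(j)
        node.threshold = float(thr)
        node.left = self._grow(X[left_mask], y[left_mask], w[left_mask], depth + 1)
        node.right = self._grow(X[~left_mask], y[~left_mask], w[~left_mask], depth + 1)
        return node

    def _best_split(self, X, y, w):
        """Exhaustive search over (feature, midpoint-threshold) candidates.

        Returns (feature, threshold, weighted-impurity gain, number of
        features with at least one admissible threshold) or None. Children
        must each contain >= min_child patients; gain must be positive.
        """
        wy = w * (y == 1)
        total_w = float(w.sum())
        total_wpos = float(wy.sum())
        parent_imp = _impurity(self._criterion_, total_wpos, total_w - total_wpos)

        best_gain = _GAIN_EPS
        best = None
        n_candidates = 0
        n = len(y)
        for j in range(X.shape[1]):
            v = X[:, j]
            order = np.argsort(v, kind="stable")
            vs = v[order]
            ws = w[order]
            wys = wy[order]
            # boundaries between distinct consecutive values
            boundary = np.nonzero(vs[1:] > vs[:-1])[0]
            if len(boundary) == 0:
                continue
            cut_n = boundary + 1  # patients on the left of each boundary
            admissible = (cut_n >= self.min_child) & (n - cut_n >= self.min_child)
            if not np.any(admissible):
                continue
            n_candidates += 1
            cw = np.cumsum(ws)
            cwy = np.cumsum(wys)
            for b, nl in zip(boundary[admissible], cut_n[admissible]):
                w_l = cw[b]
                wpos_l = cwy[b]
                w_r = total_w - w_l
                wpos_r = total_wpos - wpos_l
                gain = parent_imp - (
                    w_l / total_w * _impurity(self._criterion_, wpos_l, w_l - wpos_l)
                    + w_r / total_w * _impurity(self._criterion_, wpos_r, w_r - wpos_r)
                )
                if gain > best_gain:
                    best_gain = gain
                    best = (j, (vs[b] + vs[b + 1]) / 2.0, gain)
        if best is None:
            return None
        return (*best, n_candidates)

    # -- inference ----------------------------------------------------------

    def predict(self, X):
        check_is_fitted(self, "tree_")
        if sp.issparse(X):
            X = np.asarray(X.todense())
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0], dtype=int)
        for i in range(X.shape[0]):
            node = self.tree_
            while not node.is_leaf:
                node = node.left if X[i, node.feature] <= node.threshold else node.right
            out[i] = node.predicted
        return out

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y).astype(int).ravel()))

    # -- introspection ------------------------------------------------------

    @property
    def n_leaves_(self) -> int:
        check_is_fitted(self, "tree_")
        return self.tree_.n_leaves()

    @property
    def depth_(self) -> int:
        check_is_fitted(self, "tree_")
        return self.tree_.max_depth()

    def to_dict(self) -> dict:
        check_is_fitted(self, "tree_")
        return {
            "params": self.get_params(),
            "feature_names": self.feature_names_in_,
            "n_features": self.n_features_in_,
            "tree": self.tree_.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhenotypeDecisionTree":
        model = cls(**d["params"])
        model._criterion_ = model._validated()
        model.classes_ = np.array([0, 1])
        model.n_features_in_ = int(d["n_features"])
        model.feature_names_in_ = d["feature_names"]
        model.tree_ = TreeNode.from_dict(d["tree"])
        model.n_fits_ = 1
        return model


def _split_pvalue(v, y, w, thr) -> float:
    """Chi-square association p-value of the (<= thr) dichotomy vs outcome.

    Uses cost-weighted counts so the test sees the same data as the
    impurity search; df = 1, no continuity correction.
    """
    left = v <= thr
    wy = w * (y == 1)
    a = float(wy[left].sum())
    b = float(w[left].sum()) - a
    c = float(wy[~left].sum())
    d = float(w[~left].sum()) - c
    n = a + b + c + d
    den = (a + b) * (c + d) * (a + c) * (b + d)
    if den <= 0:
        return 1.0
    stat = n * (a * d - b * c) ** 2 / den
    return float(scipy.stats.chi2.sf(stat, df=1))


# -- pruning ---------------------------------------------------------------


def _clone_tree(node: TreeNode) -> TreeNode:
    return TreeNode.from_dict(node.to_dict())


def _weakest_link(node: TreeNode, root_risk: float):
    """Yield (g, node) for every internal node: per-split relative risk
    reduction of its subtree, normalised by the root risk."""
    out = []
    if node.is_leaf:
        return out
    reduction = node.risk() - node.subtree_risk()
    splits = node.n_leaves() - 1
    g = (reduction / splits) / root_risk if root_risk > 0 else math.inf
    out.append((g, node))
    out.extend(_weakest_link(node.left, root_risk))
    out.extend(_weakest_link(node.right, root_risk))
    return out


def _collapse(node: TreeNode) -> None:
    node.feature = None
    node.threshold = None
    node.left = None
    node.right = None


def _prune(root: TreeNode, cp: float) -> TreeNode:
    """Cost-complexity pruning: repeatedly collapse the weakest link while
    its per-split relative risk reduction is below ``cp``.

    ``cp = 0`` is the identity; ``cp >= 1`` collapses to the root leaf
    (no split can reduce risk by more than the whole root risk).
    """
    if cp < 0:
        raise ConfigurationError("cp must be >= 0")
    root = _clone_tree(root)
    if cp >= 1.0:
        _collapse(root)
        return root
    while not root.is_leaf:
        links = _weakest_link(root, root.risk())
        g_min, weakest = min(links, key=lambda t: t[0])
        if g_min < cp:
            for g, node in links:
                if g == g_min:
                    _collapse(node)
        else:
            break
    return root


def prune_tree(model: PhenotypeDecisionTree, cp: float) -> PhenotypeDecisionTree:
    """Return a pruned copy of a fitted tree (cost-complexity, see _prune)."""
    check_is_fitted(model, "tree_")
    if cp < 0:
        raise ConfigurationError("cp must be >= 0")
    pruned = PhenotypeDecisionTree.from_dict(model.to_dict())
    pruned.tree_ = _prune(model.tree_, cp)
    return pruned


# -- rule export -----------------------------------------------------------


@dataclasses.dataclass
class Rule:
    """One root-to-leaf path: a conjunction of count conditions."""

    literals: list[tuple[str, str, float]]  # (code, "<=" or ">", threshold)
    predicted: int
    support: int
    confidence: float

    def text(self, dictionary: CodeDictionary | None = None) -> str:
        def fmt(code, op, thr):
            # thresholds are midpoints between integers; display the
            # equivalent integer bound
            bound = int(math.floor(thr))
            label = code
            if dictionary is not None:
                desc = dictionary.get(code)
                if desc:
                    label = f"{code} [{desc}]"
            return f"{label} {op} {bound}"

        if self.literals:
            cond = " AND ".join(fmt(*lit) for lit in self.literals)
        else:
            cond = "TRUE"
        return (
            f"IF {cond} THEN {self.predicted} "
            f"(support={self.support}, confidence={self.confidence:.2f})"
        )


@dataclasses.dataclass
class RuleSet:
    """All leaf rules of a tree: mutually exclusive and exhaustive."""

    rules: list[Rule]
    dictionary: CodeDictionary | None = None

    def __len__(self) -> int:
        return len(self.rules)

    def to_lines(self) -> list[str]:
        return [r.text(self.dictionary) for r in self.rules]


def export_rules(
    model: PhenotypeDecisionTree, dictionary: CodeDictionary | None = None
) -> RuleSet:
    """Transform every root-to-leaf path into a readable rule.

    Support is the raw training patient count at the leaf; confidence the
    fraction of those patients matching the leaf's predicted class.
    """
    check_is_fitted(model, "tree_")
    names = model.feature_names_in_ or [f"x{j}" for j in range(model.n_features_in_)]
    rules: list[Rule] = []

    def walk(node: TreeNode, path: list[tuple[str, str, float]]):
        if node.is_leaf:
            n_neg, n_pos = node.class_counts
            support = n_neg + n_pos
            agree = n_pos if node.predicted == 1 else n_neg
            confidence = agree / support if support else float("nan")
            rules.append(
                Rule(list(path), node.predicted, support, confidence)
            )
            return
        name = names[node.feature]
        walk(node.left, path + [(name, "<=", node.threshold)])
        walk(node.right, path + [(name, ">", node.threshold)])

    walk(model.tree_, [])
    return RuleSet(rules, dictionary)


# -- matrix-level wrappers -------------------------------------------------


def fit_tree(
    train: PatientTermMatrix,
    features: Sequence[str],
    params: dict | None = None,
    **kwargs,
) -> PhenotypeDecisionTree:
    """Fit a tree on a patient-term matrix restricted to named codes."""
    if not features:
        raise ConfigurationError("empty feature list")
    opts = dict(params or {})
    opts.update(kwargs)
    X = train.dense_columns(features)
    model = PhenotypeDecisionTree(**opts)
    return model.fit(X, train.labels, feature_names=features)


def predict_matrix(model: PhenotypeDecisionTree, matrix: PatientTermMatrix) -> np.ndarray:
    """Predict labels for matrix patients; codes missing from the matrix
    vocabulary contribute count 0."""
    check_is_fitted(model, "tree_")
    names = model.feature_names_in_
    if names is None:
        raise ConfigurationError("model was not fitted with feature names")
    cols = np.zeros((matrix.n_patients, len(names)))
    for j, code in enumerate(names):
        if code in matrix.vocab:
            cols[:, j] = np.asarray(
                matrix.counts[:, matrix.vocab.index[code]].todense()
            ).ravel()
    return model.predict(cols)
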