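import itertools
import math

import numpy as np
import pytest

from phenotree import (
    CodeDictionary,
    ConfigurationError,
    PhenotypeDecisionTree,
    export_rules,
    fit_tree,
    predict_matrix,
    prune_tree,
)

# ---------------------------------------------------------------------------
# Independent oracle: a tiny, slow recursive tree builder that brute-forces
# every (feature, threshold) split by direct gini arithmetic. Written and
# kept separate from the engine under test.
# ---------------------------------------------------------------------------


def _oracle_gini(y):
    if len(y) == 0:
        return 0.0
    q = float(np.mean(y))
    return 2 * q * (1 - q)


def _oracle_tree(X, y, min_split=2, min_child=1):
    """Returns a nested dict tree by exhaustive split search (unit costs)."""
    node = {"pred": 1 if np.sum(y == 1) >= np.sum(y == 0) else 0}
    if len(y) < min_split or len(set(y)) == 1:
        return node
    n = len(y)
    best = None  # (gain, j, thr)
    for j in range(X.shape[1]):
        for thr in sorted(set((a + b) / 2 for a, b in itertools.pairwise(sorted(set(X[:, j]))))):
            left = X[:, j] <= thr
            nl = int(left.sum())
            if nl < min_child or n - nl < min_child:
                continue
            gain = _oracle_gini(y) - nl / n * _oracle_gini(y[left]) - (
                n - nl
            ) / n * _oracle_gini(y[~left])
            if gain > 1e-12 and (best is None or gain > best[0] + 1e-15):
                best = (gain, j, thr)
    if best is None:
        return node
    _, j, thr = best
    left = X[:, j] <= thr
    node.update(
        {
            "j": j,
            "thr": thr,
            "left": _oracle_tree(X[left], y[left], min_split, min_child),
            "right": _oracle_tree(X[~left], y[~left], min_split, min_child),
        }
    )
    return node


def _oracle_predict(node, x):
    while "j" in node:
        node = node["left"] if x[node["j"]] <= node["thr"] else node["right"]
    return node["pred"]


def _all_binary_inputs(n_features):
    return np.array(list(itertools.product([0, 1], repeat=n_features)))


def _datasets_2feat_upto4():
    """Every labelled dataset with 2..4 patients on 2 binary features."""
    for n in (2, 3, 4):
        for rows in itertools.product(range(4), repeat=n):
            X = np.array([[r >> 1 & 1, r & 1] for r in rows])
            for lab in itertools.product([0, 1], repeat=n):
                yield X, np.array(lab)


def test_cart_equals_exhaustive_split_oracle_enumerated():
    """With unit costs the cart profile reproduces a brute-force
    exhaustive-split search on every tiny 2-feature dataset."""
    grid = _all_binary_inputs(2)
    checked = 0
    for X, y in _datasets_2feat_upto4():
        if y.min() == y.max():
            continue  # pure labels: both build a single leaf trivially
        model = PhenotypeDecisionTree(profile="cart", criterion="gini").fit(X, y)
        oracle = _oracle_tree(X, y)
        for x in grid:
            assert model.predict(x[None, :])[0] == _oracle_predict(oracle, x)
        checked += 1
    assert checked > 500


def test_cart_equals_oracle_random_6x3():
    rng = np.random.default_rng(1908)
    grid = _all_binary_inputs(3)
    for _ in range(300):
        n = rng.integers(2, 7)
        X = rng.integers(0, 2, size=(n, 3))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            continue
        model = PhenotypeDecisionTree(profile="cart", criterion="gini").fit(X, y)
        oracle = _oracle_tree(X, y)
        for x in grid:
            assert model.predict(x[None, :])[0] == _oracle_predict(oracle, x)


# ---------------------------------------------------------------------------
# Contract tests
# ---------------------------------------------------------------------------


def test_perfect_code_gives_stump_with_training_accuracy_one():
    X = np.array([[0], [0], [1], [2]])
    y = np.array([0, 0, 1, 1])
    model = PhenotypeDecisionTree().fit(X, y)
    assert model.tree_.feature == 0
    assert model.tree_.left.is_leaf and model.tree_.right.is_leaf
    assert model.score(X, y) == 1.0


def test_pure_training_set_yields_root_leaf():
    X = np.array([[0], [3], [1]])
    y = np.array([1, 1, 1])
    model = PhenotypeDecisionTree().fit(X, y)
    assert model.tree_.is_leaf
    assert model.predict(X).tolist() == [1, 1, 1]


def test_fn_cost_flips_minority_leaf():
    # 1 positive vs 3 negatives in one leaf: predicting negative costs
    # fn_cost, predicting positive costs 3
    X = np.zeros((4, 1))
    y = np.array([1, 0, 0, 0])
    assert PhenotypeDecisionTree(fn_cost=1.0).fit(X, y).predict([[0]])[0] == 0
    assert PhenotypeDecisionTree(fn_cost=4.0).fit(X, y).predict([[0]])[0] == 1


def test_cost_tie_goes_to_positive():
    X = np.zeros((4, 1))
    y = np.array([1, 0, 0, 0])
    assert PhenotypeDecisionTree(fn_cost=3.0).fit(X, y).predict([[0]])[0] == 1


def test_child_counts_sum_to_parent_everywhere():
    rng = np.random.default_rng(7)
    X = rng.poisson(1.0, size=(80, 4))
    y = rng.integers(0, 2, size=80)
    model = PhenotypeDecisionTree(profile="c50", fn_cost=2.5).fit(X, y)

    def walk(node):
        if node.is_leaf:
            return
        for k in range(2):
            assert (
                node.left.class_counts[k] + node.right.class_counts[k]
                == node.class_counts[k]
            )
            assert node.left.weighted_counts[k] + node.right.weighted_counts[
                k
            ] == pytest.approx(node.weighted_counts[k])
        walk(node.left)
        walk(node.right)

    walk(model.tree_)


def test_increasing_fn_cost_never_shrinks_positive_predictions():
    rng = np.random.default_rng(3)
    X = rng.poisson(0.8, size=(120, 3))
    y = (rng.random(120) < 0.15).astype(int)
    # fixed structure: refit leaves only, via min_split large enough to keep
    # the same single stump across costs
    base = PhenotypeDecisionTree(profile="c50", min_split=200).fit(X, y)
    assert base.tree_.is_leaf
    previous = -1
    for cost in [1.0, 2.25, 5.0, 10.0, 20.0]:
        model = PhenotypeDecisionTree(profile="c50", min_split=200, fn_cost=cost).fit(X, y)
        n_pos = int(model.predict(X).sum())
        assert n_pos >= previous
        previous = n_pos


@pytest.mark.parametrize("criterion", ["gini", "entropy", "dkm"])
def test_all_criteria_reach_purity_on_separable_data(criterion):
    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, size=40)
    X = np.column_stack([y * (1 + rng.integers(0, 3, size=40)), rng.poisson(1, 40)])
    model = PhenotypeDecisionTree(criterion=criterion).fit(X, y)
    assert model.score(X, y) == 1.0


def test_ci_profile_blocks_insignificant_splits():
    rng = np.random.default_rng(11)
    X = rng.integers(0, 2, size=(40, 3))
    y = rng.integers(0, 2, size=40)
    strict = PhenotypeDecisionTree(profile="ci", mincriterion=0.99).fit(X, y)
    # pure noise at n=40 cannot pass a Bonferroni-corrected 0.01 threshold
    assert strict.tree_.is_leaf
    # a deterministic predictor passes even the strict threshold
    X2 = np.column_stack([np.repeat([0, 1], 20)])
    y2 = np.repeat([0, 1], 20)
    assert not PhenotypeDecisionTree(profile="ci", mincriterion=0.99).fit(X2, y2).tree_.is_leaf


def test_pruning_identity_collapse_and_monotonicity():
    rng = np.random.default_rng(13)
    X = rng.poisson(1.2, size=(100, 4))
    y = (X[:, 0] + rng.integers(0, 2, 100) > 1).astype(int)
    model = PhenotypeDecisionTree().fit(X, y)
    assert prune_tree(model, 0.0).tree_.n_nodes() == model.tree_.n_nodes()
    assert prune_tree(model, 1.0).tree_.is_leaf
    sizes = [prune_tree(model, cp).tree_.n_nodes() for cp in [0.0, 0.01, 0.05, 0.2, 1.0]]
    assert sizes == sorted(sizes, reverse=True)
    with pytest.raises(ConfigurationError):
        prune_tree(model, -0.1)


@pytest.mark.parametrize(
    "params",
    [
        {"profile": "nope"},
        {"criterion": "abc"},
        {"min_split": 1},
        {"min_child": 0},
        {"fn_cost": 0.5},
        {"cp": 1.5},
        {"mincriterion": 1.0},
    ],
)
def test_parameter_range_validation(params):
    with pytest.raises(ConfigurationError):
        PhenotypeDecisionTree(**params).fit(np.zeros((4, 1)), [0, 1, 0, 1])


def test_rule_export_partition_and_text(tiny_imbalanced_matrix):
    model = fit_tree(
        tiny_imbalanced_matrix,
        ["RARE1", "COMM1", "COMM2"],
        profile="c50",
        fn_cost=10.0,
    )
    rules = export_rules(model)
    assert len(rules) == model.tree_.n_leaves()
    # every training patient satisfies exactly one rule
    X = tiny_imbalanced_matrix.dense_columns(["RARE1", "COMM1", "COMM2"])
    names = {"RARE1": 0, "COMM1": 1, "COMM2": 2}
    for x in X:
        matching = 0
        for rule in rules.rules:
            ok = all(
                (x[names[c]] <= math.floor(t)) if op == "<=" else (x[names[c]] > math.floor(t))
                for c, op, t in rule.literals
            )
            matching += ok
        assert matching == 1
    text = rules.to_lines()[0]
    assert text.startswith("IF ") and "support=" in text


def test_rule_export_attaches_descriptions():
    X = np.array([[0], [0], [1], [2]])
    y = np.array([0, 0, 1, 1])
    model = PhenotypeDecisionTree().fit(X, y, feature_names=["N100."])
    rules = export_rules(model, CodeDictionary({"N100.": "ankylosing spondylitis"}))
    joined = "\n".join(rules.to_lines())
    assert "N100. [ankylosing spondylitis] > 0" in joined
    assert len(rules) == 2


def test_stump_threshold_semantics_and_zero_patient():
    X = np.array([[0], [0], [2], [3]])
    y = np.array([0, 0, 1, 1])
    model = PhenotypeDecisionTree().fit(X, y)
    assert model.predict([[2]])[0] == 1  # above threshold -> right branch
    assert model.predict([[0]])[0] == 0  # all-zero patient follows <= branches


def test_model_json_round_trip(tmp_path, tiny_imbalanced_matrix):
    from phenotree.io import load_model, save_model

    model = fit_tree(tiny_imbalanced_matrix, ["RARE1", "COMM1"], fn_cost=5.0)
    save_model(model, tmp_path / "m.json")
    back = load_model(tmp_path / "m.json")
    assert back.to_dict() == model.to_dict()
    np.testing.assert_array_equal(
        predict_matrix(back, tiny_imbalanced_matrix),
        predict_matrix(model, tiny_imbalanced_matrix),
    )


def test_predict_matrix_treats_missing_code_as_zero(toy_matrix):
    X = np.array([[0, 1], [1, 0], [2, 0], [0, 0]])
    y = np.array([0, 1, 1, 0])
    model = PhenotypeDecisionTree().fit(X, y, feature_names=["absent_code", "F440."])
    pred = predict_matrix(model, toy_matrix)
    assert pred.shape == (4,)


def test_empty_feature_list_raises(tiny_imbalanced_matrix):
    with pytest.raises(ConfigurationError):
        fit_tree(tiny_imbalanced_matrix, [])
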