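import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenotree import (
    AssociationRanker,
    ContingencyTable,
    DegenerateLabelsError,
    UnknownCodeError,
    binomial_score,
    chi2_score,
    contingency,
    dkm_gain,
    gini_gain,
    info_gain,
    rank_features,
)

# Expected values computed independently (closed forms / exact tail sums):
#   chi2(30,10,10,50)  = 100*(30*50-10*10)^2 / (40*60*40*60) = 34.02778
#   gini(30,10,10,50)  = 0.48 - 0.4*0.375 - 0.6*(5/18) = 0.1633333
#   ig(30,10,10,50)    = H(0.4) - 0.4*H(3/4) - 0.6*H(1/6)    = 0.2564259 bits
#   dkm(30,10,10,50)   = 2sqrt(20/81) - (4/9)2sqrt(3/16) - (5/9)2sqrt(4/25)
#   binom(5,0,5,10)    : P(X>=5 | n=5, p=0.5) = 1/32 -> -log10 = 1.5051500
#   binom(5,0,5,5)     : P(X>=5 | n=5, p=2/3) = (2/3)^5 -> 0.8804563


def H(q):
    return -q * math.log2(q) - (1 - q) * math.log2(1 - q) if 0 < q < 1 else 0.0


@pytest.mark.parametrize(
    "scorer,table,expected",
    [
        (chi2_score, (30, 10, 10, 50), 34.027777777777779),
        (chi2_score, (10, 10, 10, 10), 0.0),
        (chi2_score, (5, 0, 0, 5), 10.0),  # perfect association: chi2 = N
        (gini_gain, (30, 10, 10, 50), 0.16333333333333333),
        (gini_gain, (10, 10, 10, 10), 0.0),
        (info_gain, (30, 10, 10, 50), H(0.4) - 0.4 * H(0.75) - 0.6 * H(1 / 6)),
        (info_gain, (5, 0, 0, 5), 1.0),
        (info_gain, (10, 10, 10, 10), 0.0),
        (dkm_gain, (30, 10, 10, 50), 0.18617214009953785),
        (dkm_gain, (5, 0, 0, 5), 1.0),
        (dkm_gain, (10, 10, 10, 10), 0.0),
        (binomial_score, (5, 0, 5, 10), -math.log10(1 / 32)),
        (binomial_score, (5, 0, 5, 5), -5 * math.log10(2 / 3)),
        (binomial_score, (0, 5, 5, 5), 0.0),  # A=0: tail is 1
    ],
)
def test_index_values_against_closed_forms(scorer, table, expected):
    assert scorer(ContingencyTable(*table)) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("scorer", [chi2_score, gini_gain, info_gain, dkm_gain, binomial_score])
def test_degenerate_margins_score_zero(scorer):
    # code present in everyone / in no one carries no signal
    assert scorer(ContingencyTable(5, 7, 0, 0)) == 0.0
    assert scorer(ContingencyTable(0, 0, 5, 7)) == 0.0


def test_binomial_tail_monotone_in_A():
    # fixed n = A+B = 10 and prevalence pi = 0.5 (N = 40, A+C = 20)
    scores = [
        binomial_score(ContingencyTable(a, 10 - a, 20 - a, 10 + a)) for a in range(11)
    ]
    assert all(b >= a for a, b in zip(scores, scores[1:]))


tables = st.tuples(
    st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
).filter(lambda t: sum(t) > 0)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(tables)
def test_chi2_gini_identity(t):
    """gini_gain == chi2 * Gini(parent) / N exactly, so the two indices
    always rank features identically."""
    table = ContingencyTable(*t)
    N = table.N
    q = (table.A + table.C) / N
    parent_gini = 2 * q * (1 - q)
    assert gini_gain(table) == pytest.approx(
        chi2_score(table) * parent_gini / N, abs=1e-12
    )


@settings(max_examples=200, deadline=None, derandomize=True)
@given(tables)
def test_all_indices_nonnegative(t):
    table = ContingencyTable(*t)
    for scorer in (chi2_score, gini_gain, info_gain, dkm_gain, binomial_score):
        assert scorer(table) >= 0.0


def test_contingency_counts(toy_matrix):
    # N100.: p1 (pos, 2 events), p2 (pos, 1 event); absent in p3, p4 (neg)
    t = contingency(toy_matrix, "N100.")
    assert (t.A, t.B, t.C, t.D) == (2, 0, 0, 2)
    t = contingency(toy_matrix, "F440.")
    assert (t.A, t.B, t.C, t.D) == (1, 1, 1, 1)
    # subset restriction
    t = contingency(toy_matrix, "N100.", subset={"p1", "p3"})
    assert (t.A, t.B, t.C, t.D) == (1, 0, 0, 1)
    with pytest.raises(UnknownCodeError):
        contingency(toy_matrix, "nope")


@pytest.mark.parametrize("method", ["chi2", "gini", "info_gain", "dkm", "binomial"])
def test_rank_features_orders_perfect_code_first(toy_matrix, method):
    ranked = rank_features(toy_matrix, method=method)
    assert ranked.codes[0] == "N100."
    scores = [s for _, s in ranked.entries]
    assert scores == sorted(scores, reverse=True)
    assert len(ranked) == 2


def test_rank_features_tie_break_lexicographic():
    # two identical columns -> equal scores, lexicographic code order
    import pandas as pd

    from phenotree import EventTable, LabelTable, build_matrix, build_vocabulary

    rows = [("p1", "bbb"), ("p1", "aaa"), ("p2", "ccc")]
    events = EventTable(pd.DataFrame(rows, columns=["patient_id", "code"]))
    labels = LabelTable({"p1": 1, "p2": 0})
    matrix = build_matrix(events, labels, build_vocabulary(events))
    ranked = rank_features(matrix, method="chi2")
    assert ranked.codes[:2] == ["aaa", "bbb"]  # tied perfect codes


def test_rank_features_single_class_raises(toy_matrix):
    with pytest.raises(DegenerateLabelsError):
        rank_features(toy_matrix, subset={"p1", "p2"}, method="chi2")


def test_chi2_and_gini_rankings_identical_on_random_matrices():
    rng = np.random.default_rng(42)
    for _ in range(5):
        X = rng.poisson(0.5, size=(60, 25))
        y = rng.integers(0, 2, size=60)
        if y.min() == y.max():
            continue
        chi2 = AssociationRanker("chi2").fit(X, y)
        gini = AssociationRanker("gini").fit(X, y)
        np.testing.assert_array_equal(chi2.ranking_, gini.ranking_)


def test_ranker_transform_selects_top_columns():
    X = np.array([[2, 0, 1], [1, 0, 1], [0, 1, 1], [0, 2, 1]])
    y = np.array([1, 1, 0, 0])
    ranker = AssociationRanker("info_gain", k=2).fit(X, y)
    kept = ranker.transform(X).toarray()
    assert kept.shape == (4, 2)
    assert ranker.scores_[2] == 0.0  # constant column scores zero
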