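"""Code-outcome association indices and feature ranking.

Five indices score how well the presence of a clinical code separates
positive from negative patients, each computed on the 2x2 contingency table

    =============  ==========  ==========
                   positive    negative
    code present   A           B
    code absent    C           D
    =============  ==========  ==========

with N = A+B+C+D. Presence is binarized (count >= 1); occurrence counts are
kept for the downstream trees, which split on count thresholds.

Indices
-------
chi2
    Pearson chi-square statistic N(AD-BC)^2 / ((A+B)(C+D)(A+C)(B+D)).
gini
    Gini-impurity gain of splitting on presence, Gini(q) = 2q(1-q) on the
    positive-class proportion q. Satisfies the exact identity
    ``gini_gain = chi2 * Gini(parent) / N``, so chi2 and gini always produce
    the same ranking.
info_gain
    Shannon mutual information between presence and outcome, in bits.
dkm
    Impurity gain under the DKM (Dietterich-Kearns-Mansour) impurity
    2*sqrt(q(1-q)), structured like the Gini gain.
binomial
    -log10 of the one-sided exact binomial tail P(X >= A) with
    X ~ Binomial(A+B, (A+C)/N): how surprising the code's enrichment among
    positives is under the class-prevalence null.

Degenerate tables (a code present in every patient or in none) carry no
discriminative signal and score 0 under every index.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import scipy.sparse as sp
import scipy.stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError, DegenerateLabelsError, EmptyInputError, UnknownCodeError
from .represent import PatientTermMatrix

METHODS = ("chi2", "gini", "info_gain", "dkm", "binomial")

_LN10 = np.log(10.0)


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """2x2 presence-by-outcome table (A, B, C, D as documented above)."""

    A: int
    B: int
    C: int
    D: int

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.C, self.D) < 0:
            raise ConfigurationError("contingency counts must be non-negative")
        if self.N == 0:
            raise ConfigurationError("empty contingency table")

    @property
    def N(self) -> int:
        return self.A + self.B + self.C + self.D


def contingency(
    matrix: PatientTermMatrix, code: str, subset: Iterable[str] | None = None
) -> ContingencyTable:
    """Presence-by-outcome table for one code on a patient subset."""
    if code not in matrix.vocab:
        raise UnknownCodeError(code)
    view = matrix if subset is None else matrix.subset(subset)
    if view.n_patients == 0:
        raise EmptyInputError("empty patient subset")
    col = np.asarray(
        view.counts[:, matrix.vocab.index[code]].todense()
    ).ravel()
    present = col >= 1
    pos = view.labels == 1
    return ContingencyTable(
        A=int(np.sum(present & pos)),
        B=int(np.sum(present & ~pos)),
        C=int(np.sum(~present & pos)),
        D=int(np.sum(~present & ~pos)),
    )


def _as_arrays(t: ContingencyTable):
    return (np.array([t.A], float), np.array([t.B], float),
            np.array([t.C], float), np.array([t.D], float))


def _degenerate(A, B, C, D):
    # any zero margin: present-in-all, present-in-none, or single-class
    return (A + B == 0) | (C + D == 0) | (A + C == 0) | (B + D == 0)


def _chi2_vec(A, B, C, D):
    N = A + B + C + D
    with np.errstate(divide="ignore", invalid="ignore"):
        num = N * (A * D - B * C) ** 2
        den = (A + B) * (C + D) * (A + C) * (B + D)
        out = np.where(_degenerate(A, B, C, D), 0.0, num / np.where(den == 0, 1, den))
    return out


def _impurity_gain_vec(A, B, C, D, impurity):
    N = A + B + C + D
    with np.errstate(divide="ignore", invalid="ignore"):
        q_parent = (A + C) / N
        n_l, n_r = A + B, C + D
        q_l = np.where(n_l > 0, A / np.where(n_l == 0, 1, n_l), 0.0)
        q_r = np.where(n_r > 0, C / np.where(n_r == 0, 1, n_r), 0.0)
        gain = impurity(q_parent) - (n_l / N) * impurity(q_l) - (n_r / N) * impurity(q_r)
    return np.where(_degenerate(A, B, C, D), 0.0, np.maximum(gain, 0.0))


def _gini(q):
    return 2.0 * q * (1.0 - q)


def _entropy(q):
    q = np.clip(q, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(q > 0, q * np.log2(np.where(q > 0, q, 1)), 0.0) - np.where(
            q < 1, (1 - q) * np.log2(np.where(q < 1, 1 - q, 1)), 0.0
        )
    return h


def _dkm(q):
    return 2.0 * np.sqrt(np.clip(q * (1.0 - q), 0.0, None))


def _binomial_vec(A, B, C, D):
    N = A + B + C + D
    n = A + B
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = (A + C) / N
    # one-sided upper tail P(X >= A), exact, in log space for precision
    score = np.zeros_like(A, dtype=float)
    ok = ~_degenerate(A, B, C, D) & (A > 0)
    if np.any(ok):
        logsf = scipy.stats.binom.logsf(A[ok] - 1, n[ok], pi[ok])
        score[ok] = np.maximum(-logsf / _LN10, 0.0)
    return score


_SCORERS = {
    "chi2": _chi2_vec,
    "gini": lambda A, B, C, D: _impurity_gain_vec(A, B, C, D, _gini),
    "info_gain": lambda A, B, C, D: _impurity_gain_vec(A, B, C, D, _entropy),
    "dkm": lambda A, B, C, D: _impurity_gain_vec(A, B, C, D, _dkm),
    "binomial": _binomial_vec,
}


def chi2_score(t: ContingencyTable) -> float:
    """Pearson chi-square statistic; 0 on degenerate margins."""
    return float(_chi2_vec(*_as_arrays(t))[0])


def gini_gain(t: ContingencyTable) -> float:
    """Gini-impurity gain of the presence split."""
    return float(_SCORERS["gini"](*_as_arrays(t))[0])


def info_gain(t: ContingencyTable) -> float:
    """Mutual information between presence and outcome, in bits."""
    return float(_SCORERS["info_gain"](*_as_arrays(t))[0])


def dkm_gain(t: ContingencyTable) -> float:
    """DKM-impurity gain of the presence split."""
    return float(_SCORERS["dkm"](*_as_arrays(t))[0])


def binomial_score(t: ContingencyTable) -> float:
    """-log10 one-sided exact binomial enrichment tail; 0 when A = 0."""
    return float(_binomial_vec(*_as_arrays(t))[0])


@dataclasses.dataclass
class RankedFeatureList:
    """Codes ordered by decreasing score under one index."""

    method: str
    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown ranking method {self.method!r}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def codes(self) -> list[str]:
        return [c for c, _ in self.entries]

    def top(self, k: int) -> list[str]:
        return self.codes[:k]


class AssociationRanker(BaseEstimator):
    """Score and rank count features by outcome association.

    A scikit-learn style transformer: ``fit(X, y)`` computes one score per
    column under the chosen index (on the binarized presence matrix) and
    ``transform(X)`` keeps the ``k`` best columns (all, ordered, if ``k`` is
    None). Ties rank by lower column index.

    Parameters
    ----------
    method : one of ``chi2, gini, info_gain, dkm, binomial``.
    k : number of top features ``transform`` retains; None keeps all.

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
        Association score per column.
    ranking_ : ndarray of shape (n_features,)
        Column indices sorted by decreasing score (stable in column order).
    """

    def __init__(self, method: str = "chi2", k: int | None = None):
        self.method = method
        self.k = k

    def fit(self, X, y):
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown ranking method {self.method!r}")
        X = sp.csr_matrix(X)
        y = np.asarray(y).astype(int).ravel()
        if X.shape[0] != len(y):
            raise ValueError("X and y are misaligned")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise DegenerateLabelsError(
                f"need both outcome classes, got {classes.tolist()}"
            )
        present = X.copy()
        present.data = (present.data >= 1).astype(np.int64)
        pos = (y == 1).astype(np.int64)
        n_pos, n_neg = int(pos.sum()), int((1 - pos).sum())
        A = np.asarray(present.T @ pos, dtype=float).ravel()
        AB = np.asarray(present.sum(axis=0), dtype=float).ravel()
        B = AB - A
        C = n_pos - A
        D = n_neg - B
        self.scores_ = _SCORERS[self.method](A, B, C, D)
        order = np.lexsort((np.arange(len(self.scores_)), -self.scores_))
        self.ranking_ = order
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "ranking_")
        keep = self.ranking_ if self.k is None else self.ranking_[: self.k]
        return sp.csr_matrix(X)[:, keep]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


def rank_features(
    matrix: PatientTermMatrix,
    subset: Iterable[str] | None = None,
    method: str = "chi2",
) -> RankedFeatureList:
    """Rank every vocabulary code on a patient subset.

    Returns one score per code, descending; ties break lexicographically by
    code (the vocabulary is lexicographic, so column order suffices).
    """
    view = matrix if subset is None else matrix.subset(subset)
    ranker = AssociationRanker(method=method).fit(view.counts, view.labels)
    codes = matrix.vocab.codes
    order = np.lexsort((np.array(codes), -ranker.scores_))
    entries = [(codes[j], float(ranker.scores_[j])) for j in order]
    return RankedFeatureList(method=method, entries=entries)
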