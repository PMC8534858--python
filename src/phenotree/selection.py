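"""Forward selection of ranked features against a validation part.

Starting from the empty set, features are added one at a time in ranking
order; after each addition a classifier is trained on the training part
restricted to the current feature set and scored on the validation part.
The procedure stops early once the validation error (1 - accuracy) drops
to the tolerance, otherwise it runs to ``i_max`` features. The best and
second-best cut-offs — by validation accuracy, then F1, then fewer
features — are both carried forward, so a near-tie is not discarded.

Because features are pre-ranked, the whole sweep costs at most ``i_max``
classifier fits instead of the K(K+1)/2 fits of exhaustive forward
selection over K features.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, clone

from .errors import ConfigurationError, DegenerateLabelsError
from .metrics import ConfusionMatrix, performance
from .ranking import AssociationRanker, RankedFeatureList
from .represent import PatientTermMatrix
from .tree import PhenotypeDecisionTree


def default_learner() -> PhenotypeDecisionTree:
    """The inner classifier used to score growing feature sets: a plain
    entropy-criterion tree with no cost weighting."""
    return PhenotypeDecisionTree(profile="c50", criterion="entropy")


@dataclasses.dataclass
class SelectionTrace:
    """Validation curve of the forward sweep plus the chosen cut-offs."""

    method: str
    steps: list[tuple[int, float, float]]  # (i, accuracy_val, f1_val)
    best_cutoff: int
    second_cutoff: int | None
    tolerance: float
    n_fits: int = 0

    def step(self, i: int) -> tuple[int, float, float]:
        for s in self.steps:
            if s[0] == i:
                return s
        raise KeyError(i)


def _key(step: tuple[int, float, float]):
    i, acc, f1 = step
    return (acc, f1 if not math.isnan(f1) else -1.0, -i)


def _choose_cutoffs(steps) -> tuple[int, int | None]:
    ordered = sorted(steps, key=_key, reverse=True)
    best = ordered[0][0]
    second = ordered[1][0] if len(ordered) > 1 else None
    return best, second


class ForwardSelector(BaseEstimator):
    """Greedy rank-ordered feature selector scored on a validation set.

    scikit-learn style: ``fit(X, y, X_val=..., y_val=...)`` ranks columns
    (unless a precomputed order is supplied), sweeps nested prefixes of the
    ranking, and exposes the winning prefix; ``transform(X)`` keeps the
    selected columns.

    Parameters
    ----------
    method : ranking index for the built-in :class:`AssociationRanker`.
    estimator : classifier prototype cloned at every step (default: an
        entropy-criterion tree).
    i_max : largest prefix length examined (clipped to the column count).
    tolerance : stop as soon as validation error <= tolerance; 0 stops only
        on a perfect validation score.
    order : optional explicit column order overriding the ranking.
    step : sweep stride; 1 examines every prefix length.

    Attributes
    ----------
    trace_ : SelectionTrace
    best_cutoff_, second_cutoff_ : chosen prefix lengths
    support_ : boolean mask of the selected (best-prefix) columns
    ranking_ : column order used for the sweep
    n_fits_ : classifier fits performed (<= i_max)
    """

    def __init__(
        self,
        method: str = "chi2",
        estimator: BaseEstimator | None = None,
        i_max: int = 400,
        tolerance: float = 0.0,
        order: Sequence[int] | None = None,
        step: int = 1,
    ):
        self.method = method
        self.estimator = estimator
        self.i_max = i_max
        self.tolerance = tolerance
        self.order = order
        self.step = step

    def fit(self, X, y, X_val=None, y_val=None):
        if X_val is None or y_val is None:
            raise ConfigurationError("forward selection requires a validation set")
        if self.i_max < 1:
            raise ConfigurationError("i_max must be >= 1")
        if self.tolerance < 0:
            raise ConfigurationError("tolerance must be >= 0")
        if self.step < 1:
            raise ConfigurationError("step must be >= 1")
        X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
        X_val = np.asarray(X_val.todense()) if sp.issparse(X_val) else np.asarray(X_val)
        y = np.asarray(y).astype(int).ravel()
        y_val = np.asarray(y_val).astype(int).ravel()
        if len(np.unique(y)) < 2:
            raise DegenerateLabelsError("training labels contain a single class")

        if self.order is not None:
            order = np.asarray(self.order, dtype=int)
        else:
            order = AssociationRanker(method=self.method).fit(X, y).ranking_
        i_max = self.i_max
        if i_max > X.shape[1]:
            warnings.warn(
                f"i_max={i_max} exceeds the {X.shape[1]} available features; clipping",
                stacklevel=2,
            )
            i_max = X.shape[1]

        proto = self.estimator if self.estimator is not None else default_learner()
        steps: list[tuple[int, float, float]] = []
        n_fits = 0
        for i in range(1, i_max + 1):
            if self.step > 1 and i % self.step != 0 and i != i_max:
                continue
            cols = order[:i]
            model = clone(proto)
            model.fit(X[:, cols], y)
            n_fits += 1
            pred = np.asarray(model.predict(X_val[:, cols])).astype(int)
            report = performance(ConfusionMatrix.from_labels(y_val, pred))
            steps.append((i, report.accuracy, report.f1))
            if 1.0 - report.accuracy <= self.tolerance:
                break

        best, second = _choose_cutoffs(steps)
        self.trace_ = SelectionTrace(
            method=self.method,
            steps=steps,
            best_cutoff=best,
            second_cutoff=second,
            tolerance=float(self.tolerance),
            n_fits=n_fits,
        )
        self.best_cutoff_ = best
        self.second_cutoff_ = second
        self.ranking_ = order
        self.n_fits_ = n_fits
        support = np.zeros(X.shape[1], dtype=bool)
        support[order[:best]] = True
        self.support_ = support
        return self

    def transform(self, X):
        X = sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X)
        return X[:, self.ranking_[: self.best_cutoff_]]


def forward_select(
    ranked: RankedFeatureList,
    train: PatientTermMatrix,
    val: PatientTermMatrix,
    learner: Callable[[], BaseEstimator] | None = None,
    i_max: int = 400,
    tolerance: float = 0.0,
    step: int = 1,
) -> SelectionTrace:
    """Run the forward sweep on matrix views using a precomputed ranking.

    ``train`` and ``val`` must hold disjoint patient sets. The learner is a
    zero-argument factory so each step gets a fresh classifier.
    """
    overlap = set(train.patients) & set(val.patients)
    if overlap:
        raise ConfigurationError(
            f"train and validation share {len(overlap)} patient(s)"
        )
    codes = ranked.codes
    order = [train.vocab.index[c] for c in codes]
    proto = learner() if learner is not None else default_learner()
    selector = ForwardSelector(
        method=ranked.method,
        estimator=proto,
        i_max=i_max,
        tolerance=tolerance,
        order=order,
        step=step,
    )
    selector.fit(
        train.counts, train.labels, X_val=val.counts, y_val=val.labels
    )
    return selector.trace_


def feature_subsets_for_phase3(
    trace: SelectionTrace, ranked: RankedFeatureList
) -> tuple[list[str], list[str]]:
    """The best and second-best ranked prefixes, as code lists.

    The two cut-offs are guaranteed distinct; when the best precedes the
    second the subsets are nested.
    """
    best = ranked.top(trace.best_cutoff)
    second_cut = trace.second_cutoff
    if second_cut is None or second_cut == trace.best_cutoff:
        raise ConfigurationError("trace lacks a distinct second cut-off")
    return best, ranked.top(second_cut)
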