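"""Grid search with stratified cross-validation and final model selection.

For each candidate feature list from forward selection, every point of a
profile-specific parameter grid is scored by the overall agreement rate
(plain held-out accuracy) averaged over stratified k-fold cross-validation
on the training part. The winning parameters per feature list are refitted
on the full training part; the candidate with the best validation accuracy
(F1 then fewer-features tie-breaks) is the final model, reported once on
the untouched test part.

The default grids cover the three tree profiles' tuning levers:

* c50 — ``min_child`` 5..30 step 5; ``fn_cost`` 1..20 step 1.25.
* cart — ``min_split`` 10..40 step 5; ``cp`` 0.001..0.1 step 0.001.
* ci — ``mincriterion`` 0.1..0.9 step 0.1 plus 0.99; ``min_split`` 35..45
  step 5.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError, StratificationError
from .metrics import ConfusionMatrix, PerformanceReport, performance
from .represent import PatientTermMatrix
from .tree import PhenotypeDecisionTree, fit_tree, predict_matrix


def _frange(start: float, stop: float, step: float) -> list[float]:
    n = int(math.floor((stop - start) / step + 1e-9)) + 1
    return [round(start + i * step, 10) for i in range(n)]


_DEFAULT_AXES = {
    "c50": {
        "min_child": [5, 10, 15, 20, 25, 30],
        "fn_cost": _frange(1.0, 20.0, 1.25),
    },
    "cart": {
        "min_split": [10, 15, 20, 25, 30, 35, 40],
        "cp": _frange(0.001, 0.1, 0.001),
    },
    "ci": {
        "mincriterion": _frange(0.1, 0.9, 0.1) + [0.99],
        "min_split": [35, 40, 45],
    },
}


@dataclasses.dataclass
class ParamGrid:
    """Ordered parameter axes for one tree profile."""

    profile: str
    axes: dict[str, list]

    def __post_init__(self) -> None:
        if self.profile not in _DEFAULT_AXES:
            raise ConfigurationError(f"unknown profile {self.profile!r}")

    @classmethod
    def default(cls, profile: str) -> "ParamGrid":
        if profile not in _DEFAULT_AXES:
            raise ConfigurationError(f"unknown profile {profile!r}")
        return cls(profile, {k: list(v) for k, v in _DEFAULT_AXES[profile].items()})

    def points(self) -> list[dict]:
        """Grid points in axis order (first axis slowest)."""
        names = list(self.axes)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.axes[n] for n in names))
        ]


@dataclasses.dataclass
class GridResult:
    """Per-point cross-validated agreement rates and the winning point."""

    profile: str
    results: list[tuple[dict, float]]
    best: dict
    n_fits: int

    @property
    def best_score(self) -> float:
        for params, score in self.results:
            if params == self.best:
                return score
        raise KeyError("best point missing from results")


class TreeGridSearchCV(BaseEstimator, ClassifierMixin):
    """Cross-validated grid search over tree parameters.

    ``fit(X, y)`` evaluates every grid point by mean held-out accuracy over
    stratified k-fold CV, then refits the best point on all of ``(X, y)``.
    Ties resolve to the earliest point in axis order. Folds derive from
    ``seed`` only, so results are reproducible.

    Attributes
    ----------
    cv_results_ : list of (params, mean agreement rate)
    best_params_, best_score_, best_estimator_
    n_fits_ : folds x n-grid-points fit counter
    """

    def __init__(self, grid: ParamGrid, folds: int = 10, seed: int = 0):
        self.grid = grid
        self.folds = folds
        self.seed = seed

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        y = np.asarray(y).astype(int).ravel()
        for cls in (0, 1):
            if int(np.sum(y == cls)) < self.folds:
                raise StratificationError(
                    f"class {cls} has fewer members than {self.folds} folds"
                )
        skf = StratifiedKFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
        splits = list(skf.split(np.zeros(len(y)), y))
        points = self.grid.points()
        results: list[tuple[dict, float]] = []
        n_fits = 0
        X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
        for params in points:
            accs = []
            for tr, te in splits:
                model = PhenotypeDecisionTree(profile=self.grid.profile, **params)
                model.fit(X[tr], y[tr])
                accs.append(float(np.mean(model.predict(X[te]) == y[te])))
                n_fits += 1
            results.append((params, float(np.mean(accs))))
        best = max(results, key=lambda r: r[1])[1]
        best_params = next(p for p, s in results if s == best)
        self.cv_results_ = results
        self.best_params_ = best_params
        self.best_score_ = best
        self.best_estimator_ = PhenotypeDecisionTree(
            profile=self.grid.profile, **best_params
        ).fit(X, y, feature_names=feature_names)
        self.n_fits_ = n_fits
        return self

    def predict(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict(X)


def cross_validated_grid_search(
    train: PatientTermMatrix,
    features: Sequence[str],
    grid: ParamGrid,
    folds: int = 10,
    seed: int = 0,
) -> GridResult:
    """Grid search on a patient-term matrix restricted to named codes.

    Patients are put in canonical (patient-id sorted) order before fold
    assignment, so the result does not depend on incidental row order.
    """
    order = np.argsort(np.array(train.patients))
    X = train.dense_columns(features)[order]
    y = train.labels[order]
    gs = TreeGridSearchCV(grid, folds=folds, seed=seed).fit(
        X, y, feature_names=list(features)
    )
    return GridResult(
        profile=grid.profile,
        results=gs.cv_results_,
        best=gs.best_params_,
        n_fits=gs.n_fits_,
    )


def _sort_key(report: PerformanceReport, n_features: int):
    f1 = report.f1 if not math.isnan(report.f1) else -1.0
    return (report.accuracy, f1, -n_features)


def select_final_model(
    candidates: Sequence[tuple[Sequence[str], str, dict]],
    train: PatientTermMatrix,
    val: PatientTermMatrix,
    test: PatientTermMatrix,
) -> tuple[PhenotypeDecisionTree, PerformanceReport, list[dict]]:
    """Refit candidates on the training part and pick the validation winner.

    Each candidate is (feature list, profile, best params). Candidates are
    ranked by validation accuracy, F1, then fewer features; the winner's
    performance is measured once on the test part.

    Returns (winning model, test report, per-candidate validation summary).
    """
    if not candidates:
        raise ConfigurationError("no candidates to select from")
    fitted = []
    summaries = []
    for features, profile, params in candidates:
        model = fit_tree(train, list(features), profile=profile, **params)
        pred = predict_matrix(model, val)
        report = performance(ConfusionMatrix.from_labels(val.labels, pred))
        fitted.append((model, report, len(features)))
        summaries.append(
            {
                "profile": profile,
                "params": params,
                "n_features": len(features),
                "val_accuracy": report.accuracy,
                "val_f1": report.f1,
            }
        )
    winner = max(range(len(fitted)), key=lambda i: _sort_key(fitted[i][1], fitted[i][2]))
    model = fitted[winner][0]
    test_pred = predict_matrix(model, test)
    test_report = performance(ConfusionMatrix.from_labels(test.labels, test_pred))
    for i, s in enumerate(summaries):
        s["selected"] = i == winner
    return model, test_report, summaries
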