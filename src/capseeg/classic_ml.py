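"""Comparison harness for the eight classical classifiers.

Estimator math is delegated to scikit-learn; this module owns the search
grids (built around the published winning hyperparameter values, each
winner plus a neighbouring value), the grid-search orchestration, and
tree-model feature-importance ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from sklearn.ensemble import (ExtraTreesClassifier, GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data import SegmentSet

ALGORITHMS = ("DTC", "MLP", "KNN", "SGDC", "ETC", "SVM", "RFC", "GB")

_ESTIMATORS = {
    "DTC": DecisionTreeClassifier,
    "MLP": MLPClassifier,
    "KNN": KNeighborsClassifier,
    "SGDC": SGDClassifier,
    "ETC": ExtraTreesClassifier,
    "SVM": SVC,
    "RFC": RandomForestClassifier,
    "GB": GradientBoostingClassifier,
}

# The grid-search winners reported for the two-class / multiclass tasks.
WINNERS = {
    "two_class": {
        "DTC": {"criterion": "entropy", "max_depth": None,
                "min_samples_leaf": 4, "min_samples_split": 10},
        "MLP": {"activation": "logistic", "hidden_layer_sizes": (100,),
                "learning_rate": "constant", "solver": "adam"},
        "KNN": {"algorithm": "auto", "leaf_size": 1, "n_neighbors": 1,
                "p": 2, "weights": "uniform"},
        "SGDC": {"alpha": 0.001, "loss": "hinge", "max_iter": 2000,
                 "penalty": "l2"},
        "ETC": {"min_samples_split": 4, "n_estimators": 150,
                "random_state": 20},
        "SVM": {"C": 10, "gamma": "scale", "kernel": "rbf"},
        "RFC": {"max_depth": None, "min_samples_split": 2,
                "n_estimators": 500, "random_state": 40},
        "GB": {"learning_rate": 0.1, "max_depth": 5, "n_estimators": 200,
               "random_state": 40},
    },
    "multi_class": {
        "DTC": {"criterion": "gini", "min_samples_leaf": 2,
                "min_samples_split": 10},
        "MLP": {"activation": "relu", "hidden_layer_sizes": (100, 50),
                "learning_rate": "constant", "solver": "adam"},
        "KNN": {"algorithm": "auto", "leaf_size": 1, "n_neighbors": 1,
                "p": 1, "weights": "uniform"},
        "SGDC": {"alpha": 0.01, "loss": "hinge", "max_iter": 1000,
                 "penalty": "l1"},
        "ETC": {"n_estimators": 300, "random_state": 20},
        "SVM": {"C": 10, "gamma": "auto", "kernel": "rbf"},
        "RFC": {"max_depth": None, "min_samples_split": 2,
                "n_estimators": 500, "random_state": 40},
        "GB": {"learning_rate": 0.1, "max_depth": 7, "n_estimators": 200,
               "random_state": 10},
    },
}

# winner-plus-neighbour search grids
_DEFAULT_GRIDS = {
    "DTC": {"criterion": ["gini", "entropy"], "max_depth": [None],
            "min_samples_leaf": [1, 2, 4], "min_samples_split": [2, 10]},
    "MLP": {"activation": ["logistic", "relu"],
            "hidden_layer_sizes": [(100,), (100, 50)],
            "learning_rate": ["constant", "adaptive"], "solver": ["adam"]},
    "KNN": {"algorithm": ["auto"], "leaf_size": [1, 30],
            "n_neighbors": [1, 3], "p": [1, 2],
            "weights": ["uniform", "distance"]},
    "SGDC": {"alpha": [0.001, 0.01], "loss": ["hinge"],
             "max_iter": [1000, 2000, 3000],
             "penalty": ["l1", "l2", "elasticnet"]},
    "ETC": {"min_samples_split": [2, 4], "n_estimators": [150, 300],
            "random_state": [20]},
    "SVM": {"C": [1, 10], "gamma": ["scale", "auto"], "kernel": ["rbf"]},
    "RFC": {"max_depth": [None], "min_samples_split": [2, 4],
            "n_estimators": [150, 500], "random_state": [40]},
    "GB": {"learning_rate": [0.1], "max_depth": [5, 7],
           "n_estimators": [200], "random_state": [10, 40]},
}


@dataclass
class GridSpec:
    """Search specification for one classical algorithm."""

    algorithm: str
    grid: dict = None
    cv_folds: int = 10

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unsupported algorithm {self.algorithm!r}; supported: "
                f"{', '.join(ALGORITHMS)}"
            )
        if self.grid is None:
            self.grid = {k: list(v) for k, v in
                         _DEFAULT_GRIDS[self.algorithm].items()}
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid must be non-empty")


def make_estimator(algorithm: str, **params):
    if algorithm not in _ESTIMATORS:
        raise ValueError(
            f"unsupported algorithm {algorithm!r}; supported: "
            f"{', '.join(ALGORITHMS)}"
        )
    return _ESTIMATORS[algorithm](**params)


def grid_search_fit(spec: GridSpec, train: SegmentSet, seed: int = 0):
    """Exhaustive grid search with stratified k-fold CV; refits the winner.

    Returns ``(fitted_estimator, best_params)``.
    """
    base_params = {}
    cls = _ESTIMATORS[spec.algorithm]
    if "random_state" in cls().get_params() and "random_state" not in spec.grid:
        base_params["random_state"] = seed
    est = cls(**base_params)
    gs = GridSearchCV(est, spec.grid, cv=spec.cv_folds, scoring="accuracy",
                      refit=True)
    gs.fit(train.signals, train.labels)
    return gs.best_estimator_, dict(gs.best_params_)


def feature_importance(fitted, top_n: int = 30):
    """Top `top_n` features of a fitted tree ensemble, by impurity importance.

    Returns a list of ``(feature_index, importance)`` pairs in descending
    importance; importances over all features sum to 1.
    """
    if not hasattr(fitted, "feature_importances_"):
        raise ValueError(
            f"{type(fitted).__name__} exposes no impurity-based feature "
            "importances; fit a tree ensemble (DTC/ETC/RFC/GB)"
        )
    imp = fitted.feature_importances_
    order = imp.argsort()[::-1][:top_n]
    return [(int(i), float(imp[i])) for i in order]
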