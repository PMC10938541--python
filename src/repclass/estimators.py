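"""Estimator registry: model families, selection estimators, search spaces.

Eight classifier families make up the model-search grid; four estimators
serve importance-based feature selection (select-from-model). Each family
carries a hyperparameter search space consumed by the Bayesian optimizer:
``("float", lo, hi)`` linear, ``("logfloat", lo, hi)`` log-scaled,
``("int", lo, hi)`` inclusive integers, ``("cat", [...])`` categories.
"""

from __future__ import annotations

from typing import Any

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from xgboost import XGBClassifier

MODEL_FAMILIES = ("gbm", "knn", "lda", "lgb", "logreg", "rf", "svc", "xgb")
SELECTORS = ("LDA", "XGB", "LGB", "LINREG")

SEARCH_SPACES: dict[str, dict[str, tuple]] = {
    "lda": {"shrinkage": ("float", 0.0, 0.99)},
    "logreg": {"C": ("logfloat", 1e-3, 1e3)},
    "gbm": {
        "n_estimators": ("int", 30, 300),
        "learning_rate": ("logfloat", 0.01, 0.5),
        "max_depth": ("int", 1, 5),
    },
    "xgb": {
        "n_estimators": ("int", 30, 300),
        "learning_rate": ("logfloat", 0.01, 0.5),
        "max_depth": ("int", 1, 6),
        "subsample": ("float", 0.5, 1.0),
    },
    "lgb": {
        "n_estimators": ("int", 30, 300),
        "learning_rate": ("logfloat", 0.01, 0.5),
        "num_leaves": ("int", 2, 31),
        "min_child_samples": ("int", 2, 20),
    },
    "rf": {
        "n_estimators": ("int", 50, 400),
        "max_depth": ("int", 2, 10),
        "max_features": ("float", 0.2, 1.0),
    },
    "knn": {"n_neighbors": ("int", 1, 25), "weights": ("cat", ["uniform", "distance"])},
    "svc": {"C": ("logfloat", 1e-3, 1e3)},
}


def make_estimator(family: str, params: dict[str, Any] | None = None, seed: int = 0):
    """Instantiate a classifier family with hyperparameters and a fixed seed.

    Scale-sensitive families (LDA with shrinkage, logistic regression, KNN,
    linear SVC) are wrapped in a standardization pipeline — clone frequencies
    span orders of magnitude, which would otherwise let high-abundance noise
    clones dominate distances and regularized covariances.
    """
    params = dict(params or {})
    if family == "lda":
        est = LinearDiscriminantAnalysis(solver="lsqr", **params)
    elif family == "logreg":
        est = LogisticRegression(max_iter=5000, random_state=seed, **params)
    elif family == "gbm":
        return GradientBoostingClassifier(random_state=seed, **params)
    elif family == "xgb":
        return XGBClassifier(
            random_state=seed, verbosity=0, n_jobs=1, eval_metric="logloss", **params
        )
    elif family == "lgb":
        return LGBMClassifier(random_state=seed, verbose=-1, n_jobs=1, **params)
    elif family == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    elif family == "knn":
        est = KNeighborsClassifier(**params)
    elif family == "svc":
        est = LinearSVC(random_state=seed, **params)
    else:
        raise ValueError(f"unknown model family {family!r}; one of {MODEL_FAMILIES}")
    return make_pipeline(StandardScaler(), est)


def decision_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous class-1 scores for AUC: probabilities when available,
    otherwise the decision function."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def selector_importances(selector: str, X: np.ndarray, y: np.ndarray, seed: int = 0) -> np.ndarray:
    """Per-feature importances for select-from-model.

    Linear selectors (LDA, linear regression) use absolute coefficients on
    standardized features; tree ensembles (XGB, LGB) use gain importance.
    """
    selector = selector.upper()
    if selector in ("LDA", "LINREG"):
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        if selector == "LDA":
            model = LinearDiscriminantAnalysis(solver="lsqr")
            model.fit(Xs, y)
            coef = model.coef_.ravel()
        else:
            model = LinearRegression()
            model.fit(Xs, y)
            coef = model.coef_.ravel()
        return np.abs(coef)
    # Tree selectors subsample features per tree (random-forest-style
    # decorrelation): without it, boosting funnels all gain into whichever
    # of several redundant informative features it encounters first.
    if selector == "XGB":
        model = XGBClassifier(
            random_state=seed, verbosity=0, n_jobs=1, eval_metric="logloss",
            importance_type="gain", colsample_bytree=0.5,
        )
        model.fit(X, y)
        return model.feature_importances_.astype(float)
    if selector == "LGB":
        # LightGBM's default leaf size (20) also forbids any split on
        # cohort-sized data; scale it to the sample count so gain exists
        model = LGBMClassifier(
            random_state=seed, verbose=-1, n_jobs=1, importance_type="gain",
            min_child_samples=max(2, len(y) // 12), colsample_bytree=0.5,
        )
        model.fit(X, y)
        return model.feature_importances_.astype(float)
    raise ValueError(f"unknown selector {selector!r}; one of {SELECTORS}")
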