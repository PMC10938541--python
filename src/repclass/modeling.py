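"""Model search: stratified splits, Bayesian hyperparameter tuning,
bootstrap evaluation, multi-split AUC and model selection.

The tuner is a Gaussian-process Bayesian optimizer: after ``bo_init`` random
configurations it fits a Matern-kernel GP to the observed validation AUCs
and proposes the configuration maximizing expected improvement, up to
``bo_iters`` total evaluations. Every evaluation fits on a fresh stratified
sub-train split (80% of the training set) and scores AUC on the held-out
20% validation split; the best configuration is then refit on the entire
training set.

Evaluation follows the study protocol: the tuned model is assessed on a
fixed test set under bootstrap resampling of the training set (n refits),
and model quality is summarized as the mean test AUC over multiple
independent train/test splits with a vertically averaged ROC curve.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split

from repclass.estimators import (
    MODEL_FAMILIES,
    SEARCH_SPACES,
    SELECTORS,
    decision_scores,
    make_estimator,
)
from repclass.repertoire_io import CohortMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "ModelReport",
    "split_cohort",
    "tune_and_fit",
    "bootstrap_evaluate",
    "multi_split_evaluation",
    "select_best_model",
]

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class SearchConfig:
    """Model-search settings: 8 families x 4 selection estimators, Bayesian
    optimization with 10 starting points for 40 iterations, bootstrap
    evaluation with n=5, 20 held-out test samples."""

    families: tuple[str, ...] = MODEL_FAMILIES
    selectors: tuple[str, ...] = SELECTORS
    bo_init: int = 10
    bo_iters: int = 40
    bootstrap_n: int = 5
    test_size: int = 20
    n_splits: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bo_init > self.bo_iters:
            raise ValueError("bo_init must not exceed bo_iters")
        if self.bootstrap_n < 1:
            raise ValueError("bootstrap_n must be >= 1")


@dataclass
class ModelReport:
    """Everything the search learned about one (selector, family) model."""

    family: str
    selector: str
    feature_set: list[str]
    hyperparameters: dict[str, Any]
    per_split_auc: list[float]
    mean_auc: float
    bootstrap_scores: list[float]
    bootstrap_mean: float
    confusion: dict[str, int]  # TP, FP, TN, FN on the full dataset
    roc_fpr: list[float]
    roc_mean_tpr: list[float]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @staticmethod
    def from_json(path: str | Path) -> "ModelReport":
        return ModelReport(**json.loads(Path(path).read_text()))


def split_cohort(
    matrix: CohortMatrix, test_size: int, seed: int = 0
) -> tuple[CohortMatrix, CohortMatrix]:
    """Stratified random split into disjoint, exhaustive train/test matrices."""
    ids = np.asarray(matrix.sample_ids)
    if not 0 < test_size < len(ids):
        raise ValueError(f"test_size={test_size} outside (0, {len(ids)})")
    groups = matrix.labels.to_numpy()
    train_ids, test_ids = train_test_split(
        ids, test_size=test_size, stratify=groups, random_state=seed
    )
    for part, name in ((train_ids, "train"), (test_ids, "test")):
        if len(np.unique(matrix.labels.loc[part])) < 2:
            raise ValueError(f"a class is absent from the {name} partition")
    return matrix.restrict_samples(list(train_ids)), matrix.restrict_samples(list(test_ids))


# ---------------------------------------------------------------------------
# Gaussian-process Bayesian optimization over the encoded unit cube


def _decode(z: np.ndarray, space: dict[str, tuple]) -> dict[str, Any]:
    params: dict[str, Any] = {}
    for zi, (name, spec) in zip(z, space.items()):
        kind = spec[0]
        if kind == "float":
            params[name] = spec[1] + zi * (spec[2] - spec[1])
        elif kind == "logfloat":
            params[name] = float(np.exp(np.log(spec[1]) + zi * (np.log(spec[2]) - np.log(spec[1]))))
        elif kind == "int":
            params[name] = int(round(spec[1] + zi * (spec[2] - spec[1])))
        elif kind == "cat":
            cats = spec[1]
            params[name] = cats[min(int(zi * len(cats)), len(cats) - 1)]
        else:
            raise ValueError(f"unknown space kind {kind!r}")
    return params


def bayesian_optimize(
    objective: Callable[[dict[str, Any]], float],
    space: dict[str, tuple],
    n_init: int,
    n_iter: int,
    seed: int = 0,
) -> tuple[dict[str, Any], list[tuple[dict[str, Any], float]]]:
    """Maximize ``objective`` over a search space with GP expected improvement.

    ``n_init`` random starting points, then GP-guided proposals up to
    ``n_iter`` total evaluations. Failed evaluations score -inf; if every
    evaluation fails an error is raised with the per-trial log.
    """
    if not space:
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    d = len(space)
    Z: list[np.ndarray] = []
    ys: list[float] = []
    trials: list[tuple[dict[str, Any], float]] = []
    for i in range(n_iter):
        if i < n_init or len([v for v in ys if np.isfinite(v)]) < 2:
            z = rng.random(d)
        else:
            ok = np.isfinite(ys)
            gp = GaussianProcessRegressor(
                kernel=Matern(
                    nu=2.5, length_scale=np.full(d, 0.3), length_scale_bounds=(1e-2, 1e2)
                ),
                alpha=1e-4,
                normalize_y=True,
                random_state=seed,
            )
            with warnings.catch_warnings():
                # length-scale hitting its bound is fine for an acquisition model
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(np.array(Z)[ok], np.array(ys)[ok])
            cand = rng.random((256, d))
            mu, sigma = gp.predict(cand, return_std=True)
            best = max(np.array(ys)[ok])
            xi = 0.01
            with np.errstate(divide="ignore", invalid="ignore"):
                imp = mu - best - xi
                zscore = np.where(sigma > 0, imp / sigma, 0.0)
                ei = imp * stats.norm.cdf(zscore) + sigma * stats.norm.pdf(zscore)
                ei[sigma == 0] = 0.0
            z = cand[int(np.argmax(ei))]
        params = _decode(z, space)
        try:
            score = float(objective(params))
        except Exception as exc:  # noqa: BLE001 — a failed trial is data
            logger.debug("trial %d failed: %s", i, exc)
            score = -np.inf
        Z.append(z)
        ys.append(score)
        trials.append((params, score))
    if not np.isfinite(ys).any():
        raise RuntimeError(f"all {n_iter} tuning evaluations failed: {trials}")
    best_idx = int(np.argmax(ys))
    return trials[best_idx][0], trials


@dataclass
class TunedModel:
    model: Any
    family: str
    params: dict[str, Any]
    val_auc: float
    trials: list = field(repr=False, default_factory=list)


def tune_and_fit(
    train: CohortMatrix,
    family: str,
    bo_init: int = 10,
    bo_iters: int = 40,
    seed: int = 0,
    search_space: dict[str, tuple] | None = None,
) -> TunedModel:
    """Bayesian-optimize a family's hyperparameters on the training matrix,
    then refit the best configuration on the entire training set.

    Each trial uses a fresh stratified 80/20 sub-train/validation split
    (trial-indexed seed) and scores validation AUC.
    """
    space = SEARCH_SPACES[family] if search_space is None else search_space
    X, y = train.X(), train.y()
    trial_counter = {"i": 0}

    def objective(params: dict[str, Any]) -> float:
        t = trial_counter["i"]
        trial_counter["i"] += 1
        Xs, Xv, ys_, yv = train_test_split(
            X, y, test_size=0.2, stratify=y, random_state=(seed * 1009 + t) % (2**31)
        )
        est = make_estimator(family, params, seed=seed)
        est.fit(Xs, ys_)
        return roc_auc_score(yv, decision_scores(est, Xv))

    best_params, trials = bayesian_optimize(objective, space, bo_init, bo_iters, seed=seed)
    model = make_estimator(family, best_params, seed=seed)
    model.fit(X, y)
    best_val = max(s for _, s in trials)
    return TunedModel(model=model, family=family, params=best_params, val_auc=best_val, trials=trials)


def bootstrap_evaluate(
    family: str,
    params: dict[str, Any],
    train: CohortMatrix,
    test: CohortMatrix,
    n: int = 5,
    seed: int = 0,
) -> tuple[list[float], float, float]:
    """Refit on n bootstrap resamples of the training set (each the size of
    the original training set) and score each on the fixed test set.

    A resample containing a single class is redrawn (up to 100 attempts).
    Returns (scores, mean, sd).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    X, y = train.X(), train.y()
    Xt, yt = test.X(), test.y()
    scores = []
    for _ in range(n):
        for attempt in range(100):
            idx = rng.integers(0, len(y), size=len(y))
            if len(np.unique(y[idx])) == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample in 100 attempts")
        if attempt > 0:
            logger.warning("redrew a single-class bootstrap resample (%d attempts)", attempt + 1)
        est = make_estimator(family, params, seed=seed)
        est.fit(X[idx], y[idx])
        scores.append(float(roc_auc_score(yt, decision_scores(est, Xt))))
    arr = np.array(scores)
    return scores, float(arr.mean()), float(arr.std())


def multi_split_evaluation(
    matrix: CohortMatrix,
    feature_set: Sequence[str],
    family: str,
    n_splits: int = 10,
    seed: int = 0,
    config: SearchConfig | None = None,
    selector: str = "",
) -> ModelReport:
    """Repeat split -> tune -> test over independent stratified splits.

    Reports per-split test AUCs, their mean, the vertically averaged ROC on
    a 101-point false-positive-rate grid, bootstrap scores on the last
    split, and a confusion matrix of the last tuned model over the entire
    dataset (train + test).
    """
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    cfg = config or SearchConfig()
    sub = matrix.restrict_clones(list(feature_set))
    split_seeds = np.random.SeedSequence(seed).generate_state(n_splits) % (2**31)
    aucs: list[float] = []
    tprs: list[np.ndarray] = []
    last: tuple[TunedModel, CohortMatrix, CohortMatrix] | None = None
    for s in range(n_splits):
        split_seed = int(split_seeds[s])
        train, test = split_cohort(sub, cfg.test_size, seed=split_seed)
        tuned = tune_and_fit(
            train, family, bo_init=cfg.bo_init, bo_iters=cfg.bo_iters, seed=split_seed
        )
        yt = test.y()
        score = decision_scores(tuned.model, test.X())
        aucs.append(float(roc_auc_score(yt, score)))
        fpr, tpr, _ = roc_curve(yt, score)
        tprs.append(np.interp(FPR_GRID, fpr, tpr))
        last = (tuned, train, test)
        logger.info("split %d/%d: test AUC %.3f", s + 1, n_splits, aucs[-1])
    assert last is not None
    tuned, train, test = last
    boot_scores, boot_mean, _ = bootstrap_evaluate(
        family, tuned.params, train, test, n=cfg.bootstrap_n, seed=seed
    )
    y_all = sub.y()
    pred = np.asarray(tuned.model.predict(sub.X())).astype(int)
    confusion = {
        "TP": int(np.sum((pred == 1) & (y_all == 1))),
        "FP": int(np.sum((pred == 1) & (y_all == 0))),
        "TN": int(np.sum((pred == 0) & (y_all == 0))),
        "FN": int(np.sum((pred == 0) & (y_all == 1))),
    }
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    return ModelReport(
        family=family,
        selector=selector,
        feature_set=list(feature_set),
        hyperparameters=tuned.params,
        per_split_auc=aucs,
        mean_auc=float(np.mean(aucs)),
        bootstrap_scores=boot_scores,
        bootstrap_mean=boot_mean,
        confusion=confusion,
        roc_fpr=FPR_GRID.tolist(),
        roc_mean_tpr=mean_tpr.tolist(),
        seed=seed,
    )


def select_best_model(reports: Sequence[ModelReport]) -> ModelReport:
    """The report with the highest mean AUC; ties prefer fewer features,
    then the lexicographically first family name."""
    if not reports:
        raise ValueError("no reports to select from")
    return min(reports, key=lambda r: (-r.mean_auc, len(r.feature_set), r.family))
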