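"""Two routes from the clone-by-sample matrix to a small discriminative set.

*Top-down*: start from the cohort's most widely shared ("common") clones,
reduce by select-from-model (importance filtering under a fitted estimator),
then by greedy backward sequential feature selection scored with
cross-validated AUC.

*Top clones*: start from the most prevalent CDR3s of three public-clone
databases ("omnipresent" clones), keep those present in the cohort, then
reduce by backward sequential selection.

All selection operates on whatever matrix it is given; pass a training-only
matrix to keep held-out samples unseen (the pipeline does).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score

from repclass.estimators import make_estimator, selector_importances
from repclass.repertoire_io import CohortMatrix, PublicDBTable

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSet",
    "rank_common_clones",
    "select_from_model",
    "backward_sfs",
    "top_db_clones",
    "intersect_with_cohort",
]


@dataclass
class FeatureSet:
    """An ordered discriminative clone set with its provenance."""

    clone_keys: list[str]  # importance/selection-ordered
    route: str  # "TOP_DOWN" | "TOP_CLONES"
    selector: str  # estimator used to rank/score
    ranking: list[str]  # importance-ordered keys (same members as clone_keys)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @staticmethod
    def from_json(path: str | Path) -> "FeatureSet":
        return FeatureSet(**json.loads(Path(path).read_text()))


def rank_common_clones(matrix: CohortMatrix, k: int) -> list[str]:
    """The k most widely shared clones.

    Ranked by the number of samples with nonzero frequency (descending),
    ties by summed frequency (descending), then lexicographically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(matrix.clone_keys):
        raise ValueError(f"k={k} exceeds the {len(matrix.clone_keys)} available clones")
    vals = matrix.values.to_numpy()
    sharing = (vals > 0).sum(axis=1)
    total = vals.sum(axis=1)
    keys = np.asarray(matrix.clone_keys)
    order = np.lexsort((keys, -total, -sharing))
    return list(keys[order][:k])


def select_from_model(
    matrix: CohortMatrix,
    y: np.ndarray,
    estimator: str,
    k: int,
    seed: int = 0,
    route: str = "TOP_DOWN",
) -> FeatureSet:
    """Keep the k features with the largest importance under a fitted estimator.

    Importance is the absolute coefficient on standardized features for the
    linear estimators and gain importance for the tree ensembles; ties break
    lexicographically for determinism.
    """
    keys = matrix.clone_keys
    if k < 1 or k > len(keys):
        raise ValueError(f"k={k} outside [1, {len(keys)}]")
    if len(np.unique(y)) < 2:
        raise ValueError("labels are degenerate (single class)")
    imps = selector_importances(estimator, matrix.X(), y, seed=seed)
    order = np.lexsort((np.asarray(keys), -imps))
    ranked = list(np.asarray(keys)[order][:k])
    return FeatureSet(clone_keys=ranked, route=route, selector=estimator, ranking=ranked)


def _cv_auc(
    estimator_name: str,
    matrix: CohortMatrix,
    keys: Sequence[str],
    y: np.ndarray,
    cv_splits: int,
    seed: int,
    n_repeats: int = 3,
) -> float:
    # repeated CV: a single k-fold AUC on cohort-sized data is too noisy to
    # rank candidate removals reliably
    est = make_estimator(estimator_name, seed=seed)
    cv = RepeatedStratifiedKFold(n_splits=cv_splits, n_repeats=n_repeats, random_state=seed)
    scores = cross_val_score(est, matrix.X(keys), y, scoring="roc_auc", cv=cv)
    return float(scores.mean())


def backward_sfs(
    matrix: CohortMatrix,
    y: np.ndarray,
    estimator: str,
    k: int,
    cv_splits: int = 5,
    seed: int = 0,
    route: str = "TOP_DOWN",
) -> FeatureSet:
    """Greedy backward elimination down to k features, scored by
    cross-validated AUC.

    At each step the feature whose removal gives the highest CV AUC is
    dropped. The CV score frequently saturates on small cohorts — several
    removals tie exactly — so ties are resolved by removing the feature with
    the weakest univariate association with the labels (|AUC − 1/2|),
    residual ties by the lexicographically last key. Survivors keep their
    input order.
    """
    features = list(matrix.clone_keys)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(features):
        raise ValueError(f"k={k} exceeds current feature count {len(features)}")
    # tie-break key: marginal relevance of each feature on this matrix
    dev = {
        f: abs(roc_auc_score(y, matrix.values.loc[f].to_numpy()) - 0.5)
        for f in features
    }
    while len(features) > k:
        scores = {}
        for f in features:
            trial = [g for g in features if g != f]
            s = _cv_auc(estimator, matrix, trial, y, cv_splits, seed)
            if not np.isfinite(s):
                raise ValueError(f"non-finite CV score removing {f!r}")
            scores[f] = s
        best = max(scores.values())
        tied = [f for f, s in scores.items() if s == best]
        min_dev = min(dev[f] for f in tied)
        drop = max(f for f in tied if dev[f] == min_dev)
        logger.debug("SFS: dropping %s (CV AUC without it %.4f)", drop, best)
        features.remove(drop)
    return FeatureSet(clone_keys=features, route=route, selector=estimator, ranking=list(features))


def top_db_clones(dbs: Sequence[PublicDBTable], n_per_db: int = 10) -> list[str]:
    """Union of each database's n most prevalent CDR3s, deduplicated with
    first-seen order preserved (db order, then prevalence rank)."""
    seen: list[str] = []
    for db in dbs:
        if db.records.empty:
            raise ValueError(f"database {db.source} is empty")
        for c in db.top_clones(n_per_db):
            if c not in seen:
                seen.append(c)
    return seen


def intersect_with_cohort(clones: Iterable[str], matrix: CohortMatrix) -> list[str]:
    """Clones with nonzero frequency in at least one cohort sample,
    order-preserved."""
    index = matrix.values.index
    present = []
    for c in clones:
        if c in index and (matrix.values.loc[c] > 0).any():
            present.append(c)
    if not present:
        logger.warning("no query clones present in the cohort")
    return present
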