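"""Clonotypic diversity profiling and group comparison.

Summary statistics per repertoire: unique clonotype count, Gini
concentration coefficient of clone abundances, Gini–Simpson index
(1 − Σp², the probability two random reads come from different clones),
inverse Simpson index (1/Σp², the effective number of dominant clones),
true diversity (the Hill number of order q, (Σp^q)^(1/(1−q)); the q→1
limit is exponential Shannon entropy), the frequency share of the ten most
abundant clones and of rare clones. Group differences are tested with a
two-sided Mann–Whitney U.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from repclass.repertoire_io import Repertoire

__all__ = [
    "DiversityProfile",
    "GroupComparison",
    "diversity_profile",
    "overlap_matrix",
    "compare_groups",
    "profiles_frame",
]

DIVERSITY_METRICS = (
    "unique_clonotypes",
    "gini",
    "gini_simpson",
    "inv_simpson",
    "true_diversity",
    "top_prop",
    "rare_prop",
)


@dataclass(frozen=True)
class DiversityProfile:
    sample_id: str
    unique_clonotypes: int
    gini: float
    gini_simpson: float
    inv_simpson: float
    true_diversity: float
    q: float
    top_prop: float
    rare_prop: float


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, int]
    method: str  # "exact" | "asymptotic"


def gini_coefficient(abundances: np.ndarray) -> float:
    """Gini concentration coefficient: 0 for perfectly even abundances,
    approaching 1 for a single dominant clone."""
    x = np.sort(np.asarray(abundances, dtype=float))
    n = len(x)
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * x) / (n * x.sum()))


def hill_number(p: np.ndarray, q: float) -> float:
    """True diversity of order q: effective number of equally common clones."""
    p = p[p > 0]
    if q == 1.0:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def diversity_profile(repertoire: Repertoire, q: float = 1.0, rare_max: int = 3) -> DiversityProfile:
    """Compute the full diversity profile of one repertoire.

    ``q`` is the Hill order for true diversity (default 1, exponential
    Shannon); ``rare_max`` the maximal count of a "rare" clone (meaningful
    after depth-matched downsampling).
    """
    if repertoire.n_clonotypes == 0:
        raise ValueError(f"{repertoire.sample_id}: empty repertoire")
    if q < 0:
        raise ValueError("Hill order q must be >= 0")
    counts = repertoire.counts.astype(float)
    p = counts / counts.sum()
    sum_p2 = float(np.sum(p**2))
    top = float(np.sort(p)[::-1][:10].sum())
    rare = float(p[counts <= rare_max].sum())
    return DiversityProfile(
        sample_id=repertoire.sample_id,
        unique_clonotypes=repertoire.n_clonotypes,
        gini=gini_coefficient(counts),
        gini_simpson=1.0 - sum_p2,
        inv_simpson=1.0 / sum_p2,
        true_diversity=hill_number(p, q),
        q=q,
        top_prop=top,
        rare_prop=rare,
    )


def profiles_frame(profiles: Iterable[DiversityProfile]) -> pd.DataFrame:
    """One row per sample; the CSV-export layout."""
    return pd.DataFrame([asdict(p) for p in profiles]).set_index("sample_id")


def overlap_matrix(repertoires: Sequence[Repertoire]) -> pd.DataFrame:
    """Pairwise shared-clone counts; the diagonal is each sample's unique
    clonotype count."""
    if len(repertoires) < 2:
        raise ValueError("need at least 2 repertoires")
    sets = [r.clone_set for r in repertoires]
    ids = [r.sample_id for r in repertoires]
    n = len(sets)
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        out[i, i] = len(sets[i])
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = len(sets[i] & sets[j])
    return pd.DataFrame(out, index=ids, columns=ids)


def compare_groups(
    profiles: Sequence[DiversityProfile],
    labels: Sequence[str],
    metric: str,
    positive: str = "OC",
) -> GroupComparison:
    """Two-sided Mann–Whitney U between the two groups on one metric.

    Exact p-value when the combined sample size is at most 20 and there are
    no ties; the tie-corrected normal approximation otherwise.
    """
    if metric not in DIVERSITY_METRICS:
        raise ValueError(f"unknown metric {metric!r}; one of {DIVERSITY_METRICS}")
    values = np.array([getattr(p, metric) for p in profiles], dtype=float)
    labels_arr = np.asarray(labels)
    a = values[labels_arr == positive]
    b = values[labels_arr != positive]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(values == values[0]):
        # degenerate: no variation at all, no evidence of a difference
        return GroupComparison(metric, len(a) * len(b) / 2.0, 1.0, (len(a), len(b)), "degenerate")
    has_ties = len(np.unique(values)) < len(values)
    method = "exact" if (len(values) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        metric=metric,
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        group_sizes=(len(a), len(b)),
        method=method,
    )
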