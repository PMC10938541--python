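"""Invariant T-cell annotation, public-DB lookups and the TIL occurrence null.

Certain T-cell subtypes carry canonical, germline-encoded alpha chains and
are therefore identifiable from the V-J gene combination alone: iNKT cells
use TRAV10 joined to TRAJ18, MAIT cells TRAV1-2 joined to TRAJ33. The rule
table is extensible.

The occurrence null asks whether a selected clone set appears in more tumor
samples of a TIL (tumor-infiltrating-lymphocyte) database than random clone
sets of the same size drawn from the cohort's clone universe; significance
is an empirical p-value with the plus-one rule, so p is never reported as 0.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SubtypeCall",
    "TILDatabase",
    "NullDistribution",
    "annotate_subtype",
    "normalize_gene",
    "db_entry_counts",
    "count_samples_with_any",
    "bootstrap_occurrence_null",
    "per_cancer_breakdown",
    "load_til_db",
    "write_til_db",
]

# (V, J) -> subtype; matched on normalized gene names.
DEFAULT_SUBTYPE_RULES: dict[tuple[str, str], str] = {
    ("TRAV10", "TRAJ18"): "iNKT",
    ("TRAV1-2", "TRAJ33"): "MAIT",
}

_GENE_RE = re.compile(r"^(TR[ABGD])?([VJ])([0-9][0-9/-]*)$", re.IGNORECASE)


@dataclass(frozen=True)
class SubtypeCall:
    cdr3_aa: str
    v_gene: str
    j_gene: str
    subtype: str  # "iNKT" | "MAIT" | "NONE"


def normalize_gene(name: str) -> str | None:
    """Canonicalize an IMGT gene name: strip allele suffix and whitespace.

    ``"TRAV10*01"`` -> ``"TRAV10"``; locus-less short forms (``"V10"``,
    ``"J18"``) are kept short and matched locus-insensitively downstream.
    Returns None for unparseable names.
    """
    if not isinstance(name, str):
        return None
    base = name.strip().split("*")[0].upper()
    m = _GENE_RE.match(base)
    if m is None:
        return None
    locus, seg, num = m.groups()
    return f"{locus or ''}{seg}{num}"


def _gene_matches(query: str, rule: str) -> bool:
    """True if normalized query names the rule gene; a locus-less query
    (e.g. ``V10``) matches the rule's locus-stripped form."""
    if query == rule:
        return True
    return not query.startswith("TR") and rule.endswith(query)


def annotate_subtype(
    v_gene: str,
    j_gene: str,
    cdr3_aa: str = "",
    rules: Mapping[tuple[str, str], str] = DEFAULT_SUBTYPE_RULES,
) -> SubtypeCall:
    """Call the invariant subtype for a V-J combination (``NONE`` otherwise).

    Gene names are normalized first (allele suffixes stripped, locus prefix
    optional); unparseable names yield ``NONE`` with a warning.
    """
    v = normalize_gene(v_gene)
    j = normalize_gene(j_gene)
    if v is None or j is None:
        logger.warning("unparseable gene name(s): %r / %r", v_gene, j_gene)
        return SubtypeCall(cdr3_aa, str(v_gene), str(j_gene), "NONE")
    for (rv, rj), subtype in rules.items():
        if _gene_matches(v, rv) and _gene_matches(j, rj):
            return SubtypeCall(cdr3_aa, v_gene, j_gene, subtype)
    return SubtypeCall(cdr3_aa, v_gene, j_gene, "NONE")


def db_entry_counts(clones: Iterable[str], db) -> dict[str, int]:
    """Prevalence of each query clone in a grouped public DB (0 if absent)."""
    prev = pd.Series(
        db.records["prevalence"].to_numpy(), index=db.records["cdr3_aa"].to_numpy()
    )
    return {c: int(prev.get(c, 0)) for c in clones}


@dataclass
class TILDatabase:
    """Tumor samples mapped to a cancer-type label and a CDR3 clone set."""

    samples: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for sid, (_, clones) in self.samples.items():
            if not clones:
                raise ValueError(f"TIL sample {sid} has an empty clone set")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def cancer_types(self) -> list[str]:
        return sorted({ctype for ctype, _ in self.samples.values()})

    def presence_matrix(self, clones: Sequence[str]) -> np.ndarray:
        """Boolean (len(clones), n_samples) membership matrix."""
        index = {c: i for i, c in enumerate(clones)}
        out = np.zeros((len(clones), len(self.samples)), dtype=bool)
        for j, (_, clone_set) in enumerate(self.samples.values()):
            for c in clone_set:
                i = index.get(c)
                if i is not None:
                    out[i, j] = True
        return out


@dataclass
class NullDistribution:
    """Bootstrap occurrence null for a k-clone query against a TIL database."""

    observed: int
    draws: np.ndarray  # B integer occurrence counts
    k: int
    p_value: float = field(init=False)

    def __post_init__(self) -> None:
        b = len(self.draws)
        # plus-one empirical p: ties count against the query, p is never 0
        self.p_value = (1 + int(np.sum(self.draws >= self.observed))) / (b + 1)

    @property
    def B(self) -> int:
        return len(self.draws)


def count_samples_with_any(query: Iterable[str], db: TILDatabase) -> int:
    """Number of tumor samples containing at least one query clone
    (each sample counted at most once)."""
    q = set(query)
    if not q:
        raise ValueError("empty query clone set")
    return sum(1 for _, clones in db.samples.values() if not q.isdisjoint(clones))


def bootstrap_occurrence_null(
    k: int,
    universe: Sequence[str],
    db: TILDatabase,
    observed: int,
    B: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Null distribution of the occurrence count for random k-clone sets.

    Each of the B draws takes k distinct clones uniformly from ``universe``
    (the cohort's full clone set; without replacement within a draw, with
    replacement across draws) and counts the tumor samples containing at
    least one of them. The empirical p-value follows the plus-one rule.
    """
    universe = sorted(set(universe))
    if k > len(universe):
        raise ValueError(f"k={k} exceeds universe size {len(universe)}")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    present = db.presence_matrix(universe)  # clones x tumors
    idx = np.empty((B, k), dtype=np.intp)
    for b in range(B):
        idx[b] = rng.choice(len(universe), size=k, replace=False)
    # union occurrence per draw, vectorized over tumors
    counts = np.any(present[idx], axis=1).sum(axis=1)
    return NullDistribution(observed=observed, draws=counts.astype(int), k=k)


def occurrence_null_calibration(
    k: int,
    universe: Sequence[str],
    db: TILDatabase,
    n_replicates: int,
    B: int = 999,
    seed: int = 0,
) -> np.ndarray:
    """Type-I-error study of the occurrence null: p-values for query sets that
    are themselves uniform draws from the universe.

    For each replicate, a k-clone "observed" set is drawn uniformly from the
    universe, scored against the TIL database, and compared with its own
    B-draw null; under this pure null the returned p-values should be
    approximately uniform (up to the discreteness of the occurrence count).
    """
    universe = sorted(set(universe))
    if k > len(universe):
        raise ValueError(f"k={k} exceeds universe size {len(universe)}")
    rng = np.random.default_rng(seed)
    present = db.presence_matrix(universe)
    n = len(universe)
    pvals = np.empty(n_replicates)
    for r in range(n_replicates):
        obs_idx = rng.choice(n, size=k, replace=False)
        observed = int(np.any(present[obs_idx], axis=0).sum())
        # distinct clones within each draw: redraw rows with a collision
        idx = rng.integers(0, n, size=(B, k))
        bad = (np.diff(np.sort(idx, axis=1), axis=1) == 0).any(axis=1)
        while bad.any():
            idx[bad] = rng.integers(0, n, size=(int(bad.sum()), k))
            bad = (np.diff(np.sort(idx, axis=1), axis=1) == 0).any(axis=1)
        counts = np.any(present[idx], axis=1).sum(axis=1)
        pvals[r] = (1 + int(np.sum(counts >= observed))) / (B + 1)
    return pvals


def per_cancer_breakdown(query: Iterable[str], db: TILDatabase) -> dict[str, float]:
    """Per cancer type, the fraction of its tumor samples containing at least
    one query clone."""
    q = set(query)
    if not q:
        raise ValueError("empty query clone set")
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for ctype, clones in db.samples.values():
        totals[ctype] = totals.get(ctype, 0) + 1
        if not q.isdisjoint(clones):
            hits[ctype] = hits.get(ctype, 0) + 1
    return {ctype: hits.get(ctype, 0) / n for ctype, n in sorted(totals.items())}


def write_til_db(db: TILDatabase, path: str | Path) -> None:
    """Serialize as a long table: tumor_sample_id, cancer_type, cdr3_aa."""
    rows = [
        (sid, ctype, cdr3)
        for sid, (ctype, clones) in db.samples.items()
        for cdr3 in sorted(clones)
    ]
    pd.DataFrame(rows, columns=["tumor_sample_id", "cancer_type", "cdr3_aa"]).to_csv(
        path, sep="\t", index=False
    )


def load_til_db(path: str | Path) -> TILDatabase:
    df = pd.read_csv(path, sep="\t", dtype=str)
    samples: dict[str, tuple[str, frozenset[str]]] = {}
    for (sid, ctype), grp in df.groupby(["tumor_sample_id", "cancer_type"], sort=False):
        samples[str(sid)] = (str(ctype), frozenset(grp["cdr3_aa"]))
    return TILDatabase(samples=samples)
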