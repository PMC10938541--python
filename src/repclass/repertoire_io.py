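"""Clonotype-table IO and the clone-by-sample frequency matrix.

A repertoire is one blood sample's collection of clonotypes, each keyed by
its CDR3 amino-acid sequence and carrying V/J gene annotations and a UMI
count. Two table dialects are supported: AIRR Rearrangement TSV
(``junction_aa``, ``v_call``, ``j_call``, ``duplicate_count``) and a
MiXCR-style clonotype export (``aaSeqCDR3``, ``allVHitsWithScore``,
``allJHitsWithScore``, ``cloneCount``).

Clone identity throughout the package is the CDR3 amino-acid string alone,
chain-agnostic; V and J genes are carried as annotations only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_CLONOTYPE_COLUMNS = ["cdr3_aa", "v_gene", "j_gene", "chain", "count", "frequency"]

_AIRR_REQUIRED = ["junction_aa", "v_call", "j_call", "duplicate_count"]
_MIXCR_REQUIRED = ["aaSeqCDR3", "allVHitsWithScore", "allJHitsWithScore", "cloneCount"]

Dialect = Literal["AIRR", "MIXCR"]


class RepertoireFormatError(ValueError):
    """A clonotype table is missing required columns or is malformed."""


class EmptyRepertoireError(ValueError):
    """No usable clonotype rows remain after filtering."""


class Clonotype(NamedTuple):
    """One CDR3-defined clone within a sample."""

    cdr3_aa: str
    v_gene: str
    j_gene: str
    chain: str  # "TRA" | "TRB"
    count: int
    frequency: float


@dataclass
class Repertoire:
    """One sample's clonotypes with abundances.

    The clonotype collection is held as a DataFrame with columns
    ``cdr3_aa, v_gene, j_gene, chain, count, frequency``; counts are UMIs
    and frequencies are counts normalised by the sample total.
    """

    sample_id: str
    group: str = "UNKNOWN"  # "OC" | "HD" | "UNKNOWN"
    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_CLONOTYPE_COLUMNS))

    @property
    def total_umis(self) -> int:
        return int(self.table["count"].sum())

    @property
    def n_clonotypes(self) -> int:
        return len(self.table)

    @property
    def clonotypes(self) -> list[Clonotype]:
        return [Clonotype(*row) for row in self.table[_CLONOTYPE_COLUMNS].itertuples(index=False)]

    @property
    def counts(self) -> np.ndarray:
        return self.table["count"].to_numpy()

    @property
    def frequencies(self) -> np.ndarray:
        return self.table["frequency"].to_numpy()

    @property
    def clone_set(self) -> frozenset[str]:
        return frozenset(self.table["cdr3_aa"])

    def frequency_series(self) -> pd.Series:
        """Per-clone frequency keyed by CDR3 (requires aggregated table)."""
        return pd.Series(
            self.table["frequency"].to_numpy(), index=self.table["cdr3_aa"].to_numpy()
        )

    def with_table(self, table: pd.DataFrame) -> "Repertoire":
        return Repertoire(sample_id=self.sample_id, group=self.group, table=table)


@dataclass
class PublicDBTable:
    """A public-clone database grouped by CDR3 sequence.

    ``records`` has one row per CDR3 with its summed prevalence and free-text
    metadata, ordered by prevalence (descending) then CDR3 lexicographically.
    """

    source: str  # "VDJDB_LIKE" | "MCPAS_LIKE" | "TCGA_TIL_LIKE"
    records: pd.DataFrame  # columns: cdr3_aa, prevalence, metadata

    def top_clones(self, n: int) -> list[str]:
        """The ``n`` highest-prevalence CDR3s (prevalence desc, lexicographic ties)."""
        return self.records["cdr3_aa"].head(n).tolist()

    def prevalence_of(self, cdr3: str) -> int:
        hit = self.records.loc[self.records["cdr3_aa"] == cdr3, "prevalence"]
        return int(hit.iloc[0]) if len(hit) else 0


@dataclass
class CohortMatrix:
    """Clone-by-sample frequency matrix with per-sample group labels.

    Rows are unique CDR3 amino-acid strings, columns are sample ids, and each
    cell holds the clone's within-sample frequency (0 when absent). When rows
    cover the full clone union of the cohort every column sums to 1.
    """

    values: pd.DataFrame  # index: clone keys; columns: sample ids
    labels: pd.Series  # index: sample ids; values: group strings

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.values.columns)

    @property
    def clone_keys(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def y(self, positive: str = "OC") -> np.ndarray:
        """Binary label vector, 1 for the positive (case) group."""
        return (self.labels.to_numpy() == positive).astype(int)

    def X(self, clone_keys: Sequence[str] | None = None) -> np.ndarray:
        """Samples-by-clones design matrix (transposed view of ``values``)."""
        vals = self.values if clone_keys is None else self.values.loc[list(clone_keys)]
        return vals.to_numpy().T

    def restrict_clones(self, keys: Sequence[str]) -> "CohortMatrix":
        return CohortMatrix(values=self.values.loc[list(keys)], labels=self.labels)

    def restrict_samples(self, sample_ids: Sequence[str]) -> "CohortMatrix":
        ids = list(sample_ids)
        return CohortMatrix(values=self.values[ids], labels=self.labels.loc[ids])

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "cdr3_aa"
        out.to_csv(path)

    @staticmethod
    def from_csv(path: str | Path, labels: pd.Series) -> "CohortMatrix":
        values = pd.read_csv(path, index_col=0)
        values.index.name = None
        return CohortMatrix(values=values, labels=labels.reindex(values.columns))


def _validate_cdr3(seq: object) -> bool:
    """True for a non-empty, fully productive amino-acid CDR3."""
    if not isinstance(seq, str) or not seq:
        return False
    return all(c in AMINO_ACIDS for c in seq)


_GENE_HIT_RE = re.compile(r"^([A-Za-z0-9/-]+)")


def _first_hit(hits: object) -> str:
    """First gene name from a MiXCR hits string like ``TRAV10*00(957),TRAV2*00(800)``."""
    if not isinstance(hits, str) or not hits:
        return ""
    first = hits.split(",")[0].split("*")[0].split("(")[0]
    m = _GENE_HIT_RE.match(first.strip())
    return m.group(1) if m else ""


def _chain_from_gene(gene: str) -> str:
    if gene.upper().startswith("TRA"):
        return "TRA"
    if gene.upper().startswith("TRB"):
        return "TRB"
    return "TRB"


def read_clonotypes(path: str | Path, dialect: Dialect, sample_id: str, group: str = "UNKNOWN") -> Repertoire:
    """Read a clonotype table into a :class:`Repertoire`.

    Rows with empty, stop-codon ('*') or frameshift ('_') CDR3s are dropped
    and the total recomputed; frequencies are count / total_umis.

    Raises
    ------
    RepertoireFormatError
        If a required column for the dialect is missing.
    EmptyRepertoireError
        If no usable rows remain.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    required = _AIRR_REQUIRED if dialect == "AIRR" else _MIXCR_REQUIRED
    for col in required:
        if col not in raw.columns:
            raise RepertoireFormatError(
                f"{path}: missing required {dialect} column {col!r}"
            )

    if dialect == "AIRR":
        cdr3 = raw["junction_aa"]
        v_gene = raw["v_call"].fillna("").map(lambda s: s.split("*")[0].split(",")[0].strip())
        j_gene = raw["j_call"].fillna("").map(lambda s: s.split("*")[0].split(",")[0].strip())
        count = pd.to_numeric(raw["duplicate_count"], errors="coerce")
        if "locus" in raw.columns:
            chain = raw["locus"].fillna("").where(raw["locus"].isin(["TRA", "TRB"]), other=v_gene.map(_chain_from_gene))
        else:
            chain = v_gene.map(_chain_from_gene)
    else:
        cdr3 = raw["aaSeqCDR3"]
        v_gene = raw["allVHitsWithScore"].map(_first_hit)
        j_gene = raw["allJHitsWithScore"].map(_first_hit)
        count = pd.to_numeric(raw["cloneCount"], errors="coerce")
        chain = v_gene.map(_chain_from_gene)

    table = pd.DataFrame(
        {
            "cdr3_aa": cdr3,
            "v_gene": v_gene,
            "j_gene": j_gene,
            "chain": chain,
            "count": count,
        }
    )
    ok = table["cdr3_aa"].map(_validate_cdr3) & table["count"].notna() & (table["count"] > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s: dropped %d nonproductive/malformed rows", sample_id, n_dropped)
    table = table.loc[ok].copy()
    if table.empty:
        raise EmptyRepertoireError(f"{path}: no usable clonotype rows")
    table["count"] = table["count"].astype(np.int64)
    table["frequency"] = table["count"] / table["count"].sum()
    return Repertoire(sample_id=sample_id, group=group, table=table.reset_index(drop=True))


def write_clonotypes(repertoire: Repertoire, path: str | Path, dialect: Dialect) -> None:
    """Write a repertoire as an AIRR or MiXCR-style TSV (inverse of reading)."""
    t = repertoire.table
    if dialect == "AIRR":
        out = pd.DataFrame(
            {
                "junction_aa": t["cdr3_aa"],
                "v_call": t["v_gene"],
                "j_call": t["j_gene"],
                "locus": t["chain"],
                "duplicate_count": t["count"],
            }
        )
    else:
        out = pd.DataFrame(
            {
                "cloneCount": t["count"],
                "cloneFraction": t["frequency"],
                "aaSeqCDR3": t["cdr3_aa"],
                "allVHitsWithScore": t["v_gene"].map(lambda g: f"{g}*00(100)" if g else ""),
                "allJHitsWithScore": t["j_gene"].map(lambda g: f"{g}*00(100)" if g else ""),
            }
        )
    out.to_csv(path, sep="\t", index=False)


def aggregate_by_cdr3(repertoire: Repertoire) -> Repertoire:
    """Merge clonotypes sharing a CDR3 amino-acid sequence.

    Counts are summed, frequency recomputed, and the V/J/chain annotations of
    the merged record come from the highest-count constituent. Total UMIs are
    preserved exactly.
    """
    t = repertoire.table
    if t["cdr3_aa"].is_unique:
        return repertoire
    # annotation donor: highest-count row per key (stable for equal counts)
    order = t.sort_values("count", ascending=False, kind="stable")
    donors = order.drop_duplicates("cdr3_aa").set_index("cdr3_aa")
    counts = t.groupby("cdr3_aa", sort=False)["count"].sum()
    merged = pd.DataFrame(
        {
            "cdr3_aa": counts.index,
            "v_gene": donors.loc[counts.index, "v_gene"].to_numpy(),
            "j_gene": donors.loc[counts.index, "j_gene"].to_numpy(),
            "chain": donors.loc[counts.index, "chain"].to_numpy(),
            "count": counts.to_numpy(),
        }
    )
    merged["frequency"] = merged["count"] / merged["count"].sum()
    return repertoire.with_table(merged.reset_index(drop=True))


def rank_clone_order(values: pd.DataFrame) -> pd.Index:
    """Deterministic clone ordering: sharing count desc, summed frequency desc,
    then lexicographic CDR3."""
    sharing = (values.to_numpy() > 0).sum(axis=1)
    total = values.to_numpy().sum(axis=1)
    keys = values.index.to_numpy()
    # np.lexsort: last key is primary; negate for descending numeric keys
    order = np.lexsort((keys, -total, -sharing))
    return pd.Index(keys[order])


def build_cohort_matrix(repertoires: Iterable[Repertoire]) -> CohortMatrix:
    """Assemble the clone-by-sample frequency matrix from aggregated repertoires.

    Rows are the union of CDR3s across samples (absent clone -> 0), columns
    follow input order, and rows are ordered by sharing count (descending),
    then summed frequency (descending), then lexicographically — a byte-stable
    layout across runs.
    """
    reps = list(repertoires)
    ids = [r.sample_id for r in reps]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate sample_id(s): {dupes}")
    cols = {r.sample_id: r.frequency_series() for r in reps}
    values = pd.DataFrame(cols).fillna(0.0)
    values = values[ids]  # preserve input column order
    values = values.loc[rank_clone_order(values)]
    labels = pd.Series({r.sample_id: r.group for r in reps}, name="group")
    return CohortMatrix(values=values, labels=labels)


def load_public_db(path: str | Path, source: str) -> PublicDBTable:
    """Load a public-clone database fixture (``cdr3_aa<TAB>prevalence<TAB>metadata``).

    Rows are grouped by CDR3 with prevalences summed; an empty prevalence
    field counts as 1. Malformed rows are skipped (logged); if every row is
    malformed an error is raised. Record order is prevalence descending,
    then lexicographic.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if "cdr3_aa" not in raw.columns or "prevalence" not in raw.columns:
        raise RepertoireFormatError(f"{path}: public DB needs cdr3_aa and prevalence columns")
    prevalence = pd.to_numeric(raw["prevalence"], errors="coerce")
    prevalence = prevalence.where(raw["prevalence"].notna() & (raw["prevalence"].str.len() > 0), other=1)
    ok = raw["cdr3_aa"].map(_validate_cdr3) & prevalence.notna() & (prevalence >= 0)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("%s: skipped %d malformed DB rows", path, n_bad)
    if not ok.any():
        raise RepertoireFormatError(f"{path}: all rows malformed")
    df = pd.DataFrame(
        {
            "cdr3_aa": raw.loc[ok, "cdr3_aa"],
            "prevalence": prevalence[ok].astype(np.int64),
            "metadata": raw["metadata"].fillna("") if "metadata" in raw.columns else "",
        }
    )
    grouped = (
        df.groupby("cdr3_aa", sort=False)
        .agg(prevalence=("prevalence", "sum"), metadata=("metadata", "first"))
        .reset_index()
    )
    grouped = grouped.sort_values(
        ["prevalence", "cdr3_aa"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return PublicDBTable(source=source, records=grouped)


def write_public_db(db: PublicDBTable, path: str | Path) -> None:
    db.records.to_csv(path, sep="\t", index=False)


def write_metadata(repertoires: Iterable[Repertoire], path: str | Path) -> None:
    """Two-column sample metadata CSV (sample_id, group)."""
    rows = [(r.sample_id, r.group) for r in repertoires]
    pd.DataFrame(rows, columns=["sample_id", "group"]).to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, dtype=str)
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"].to_numpy(), name="group")
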