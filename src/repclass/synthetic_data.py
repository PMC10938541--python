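"""Synthetic cohorts, public-clone databases and a TIL database.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline runs offline:

* a cohort of case (ovarian-cancer-like, ``OC``) and control (healthy-donor,
  ``HD``) repertoires whose background clones come from a *shared pool* with
  Zipf-distributed abundances — this is what creates realistic clone sharing
  ("common" and "public" clones) across samples;
* group-discriminative clones implanted with group-conditional presence
  probabilities and frequency scales;
* three public-clone database fixtures whose top-prevalence lists overlap by
  a configurable amount;
* a tumor-infiltrating-lymphocyte (TIL) database of tumor samples, each with
  a cancer-type label and a CDR3 set, optionally enriched for a clone set.

Every generator is a pure function of its spec: a single global seed with
fixed per-component substreams (pool=0, cohort sample *i* = (1, *i*),
public DBs=2, TIL DB=3), so each stage can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from repclass.repertoire_io import PublicDBTable, Repertoire
from repclass.clone_annotation import TILDatabase

__all__ = [
    "SyntheticSpec",
    "ImplantedClone",
    "generate_cohort",
    "generate_public_dbs",
    "generate_til_db",
    "default_implants",
]

# Canonical invariant-T CDR3 junctions used as demo implants: the first is a
# classic iNKT alpha-chain junction (TRAV10/TRAJ18), CAVRDSNYQLIW and
# CAVLDSNYQLIW are MAIT alpha junctions (TRAV1-2/TRAJ33), the rest are
# ordinary beta-chain junctions.
INKT_CDR3 = "CVVSDRGSTLGRLYF"
MAIT_CDR3S = ("CAVRDSNYQLIW", "CAVLDSNYQLIW")
BETA_CDR3S = ("CASSLKETQYF", "CASSLAYEQYF", "CASSLGETQYF")

_TRAV = [f"TRAV{i}" for i in (2, 3, 4, 5, 6, 8, 9, 12, 13, 17, 19, 21, 22, 24, 26, 29, 35, 38)]
_TRAJ = [f"TRAJ{i}" for i in (4, 6, 9, 12, 15, 20, 23, 28, 31, 34, 37, 40, 43, 45, 48, 49, 52, 54)]
_TRBV = [f"TRBV{g}" for g in ("2", "4-1", "5-1", "6-1", "7-2", "9", "11-2", "12-3", "15", "18", "19", "20-1", "25-1", "27", "28", "30")]
_TRBJ = [f"TRBJ{g}" for g in ("1-1", "1-2", "1-3", "1-4", "1-5", "1-6", "2-1", "2-2", "2-3", "2-5", "2-7")]


@dataclass(frozen=True)
class ImplantedClone:
    """A group-discriminative clone inserted into the synthetic cohort."""

    cdr3_aa: str
    v_gene: str = "TRBV5-1"
    j_gene: str = "TRBJ2-7"
    p_present_case: float = 1.0
    p_present_control: float = 0.0
    freq_scale_case: float = 1e-3
    freq_scale_control: float = 1e-3

    def __post_init__(self) -> None:
        for p in (self.p_present_case, self.p_present_control):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"presence probability {p} outside [0, 1]")
        for f in (self.freq_scale_case, self.freq_scale_control):
            if not 0.0 < f < 1.0:
                raise ValueError(f"frequency scale {f} outside (0, 1)")


def default_implants(route: str = "TOP_DOWN") -> tuple[ImplantedClone, ...]:
    """Demo implant sets: three clones (one iNKT-like) for the top-down route,
    four (two MAIT-like, one iNKT-like) for the top-clones route.

    Effect sizes are deliberately partial (no single clone separates the
    groups on its own), so a selection cascade has to retain the whole set to
    classify well. The clones are present in both groups — widely enough to
    rank among the cohort's shared clones — but expand roughly tenfold in
    cases, so the discriminative signal sits in the frequency, not bare
    presence.
    """
    if route == "TOP_DOWN":
        return (
            ImplantedClone(INKT_CDR3, "TRAV10", "TRAJ18", 0.8, 0.5, 2e-3, 1.5e-4),
            ImplantedClone(BETA_CDR3S[0], p_present_case=0.8, p_present_control=0.5,
                           freq_scale_case=2e-3, freq_scale_control=1.5e-4),
            ImplantedClone(BETA_CDR3S[1], p_present_case=0.8, p_present_control=0.5,
                           freq_scale_case=2e-3, freq_scale_control=1.5e-4),
        )
    return (
        ImplantedClone(MAIT_CDR3S[0], "TRAV1-2", "TRAJ33", 0.95, 0.05),
        ImplantedClone(INKT_CDR3, "TRAV10", "TRAJ18", 0.95, 0.05),
        ImplantedClone(MAIT_CDR3S[1], "TRAV1-2", "TRAJ33", 0.95, 0.05),
        ImplantedClone(BETA_CDR3S[2], p_present_case=0.95, p_present_control=0.05),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Cohort-generation parameters.

    Defaults mirror the study shape: 34 case / 51 control repertoires with
    10^4–10^6 UMIs each (log-uniform), a shared background pool of 5x10^4
    clones with Zipf rank-frequency exponent 1.4, and canonical CDR3 lengths.
    ``n_undersized`` controls how many control samples are generated at
    ``undersized_umis`` depth (emulating repertoires small enough to be
    excluded upstream).
    """

    n_case: int = 34
    n_control: int = 51
    umis_per_sample: tuple[int, int] = (10_000, 1_000_000)
    clone_size_exponent: float = 1.4
    background_pool_size: int = 50_000
    cdr3_length_range: tuple[int, int] = (8, 20)
    implanted_clones: tuple[ImplantedClone, ...] = ()
    seed: int = 0
    n_undersized: int = 0
    undersized_umis: int = 400
    sample_jitter_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_case and n_control must be >= 1")
        if self.clone_size_exponent <= 1.0:
            raise ValueError("clone_size_exponent must be > 1")
        if self.umis_per_sample[0] > self.umis_per_sample[1] or self.umis_per_sample[0] < 1:
            raise ValueError("umis_per_sample range is empty")
        if self.cdr3_length_range[0] > self.cdr3_length_range[1] or self.cdr3_length_range[0] < 5:
            raise ValueError("cdr3_length_range is empty or below minimal CDR3 length")
        if self.n_undersized > self.n_control:
            raise ValueError("cannot undersize more samples than there are controls")
        for scales in (
            [c.freq_scale_case for c in self.implanted_clones],
            [c.freq_scale_control for c in self.implanted_clones],
        ):
            if sum(scales) > 1.0:
                raise ValueError("implanted frequency scales sum above 1")


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_NO_TERM = np.array(list("ACDEGHIKLMNPQRSTVY"))  # interior positions


def _random_cdr3s(rng: np.random.Generator, n: int, length_range: tuple[int, int],
                  forbidden: frozenset[str] = frozenset()) -> list[str]:
    """Unique CDR3-like strings: 'C' + random interior + 'F' or 'W'."""
    out: list[str] = []
    seen = set(forbidden)
    lo, hi = length_range
    while len(out) < n:
        batch = max(n - len(out), 64)
        lengths = rng.integers(lo, hi + 1, size=batch)
        for L in lengths:
            mid = "".join(rng.choice(_AA, size=L - 2))
            seq = "C" + mid + ("F" if rng.random() < 0.5 else "W")
            if seq not in seen:
                seen.add(seq)
                out.append(seq)
            if len(out) == n:
                break
    return out


@lru_cache(maxsize=8)
def _background_pool(spec: SyntheticSpec) -> pd.DataFrame:
    """The shared clone pool: CDR3 keys, V/J/chain annotations, Zipf weights.

    Substream (seed, 0). Implanted CDR3s are excluded from the pool so their
    group-conditional structure is never diluted by background occurrences.
    """
    rng = np.random.default_rng([spec.seed, 0])
    forbidden = frozenset(c.cdr3_aa for c in spec.implanted_clones)
    cdr3s = _random_cdr3s(rng, spec.background_pool_size, spec.cdr3_length_range, forbidden)
    n = spec.background_pool_size
    chain = np.where(rng.random(n) < 0.5, "TRA", "TRB")
    v = np.where(chain == "TRA", rng.choice(_TRAV, n), rng.choice(_TRBV, n))
    j = np.where(chain == "TRA", rng.choice(_TRAJ, n), rng.choice(_TRBJ, n))
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** (-spec.clone_size_exponent)
    return pd.DataFrame(
        {"cdr3_aa": cdr3s, "v_gene": v, "j_gene": j, "chain": chain, "weight": w / w.sum()}
    )


def _sample_repertoire(spec: SyntheticSpec, pool: pd.DataFrame, sample_id: str,
                       group: str, index: int, n_umis: int) -> Repertoire:
    rng = np.random.default_rng([spec.seed, 1, index])
    # implanted clones first, so the background budget is what remains
    imp_rows = []
    implanted_total = 0
    for clone in spec.implanted_clones:
        p = clone.p_present_case if group == "OC" else clone.p_present_control
        scale = clone.freq_scale_case if group == "OC" else clone.freq_scale_control
        if rng.random() < p:
            f = min(scale * rng.lognormal(0.0, 0.25), 10 * scale)
            count = max(1, rng.binomial(n_umis, f))
            implanted_total += count
            imp_rows.append((clone.cdr3_aa, clone.v_gene, clone.j_gene,
                             "TRA" if clone.v_gene.startswith("TRA") else "TRB", count))
    if implanted_total >= n_umis:
        raise ValueError(f"{sample_id}: implanted clones exhaust the UMI budget")
    # per-sample lognormal jitter individualises the shared Zipf ranking
    jitter = rng.lognormal(0.0, spec.sample_jitter_sigma, len(pool))
    p_bg = pool["weight"].to_numpy() * jitter
    p_bg /= p_bg.sum()
    counts = rng.multinomial(n_umis - implanted_total, p_bg)
    nz = counts > 0
    table = pd.DataFrame(
        {
            "cdr3_aa": pool.loc[nz, "cdr3_aa"].to_numpy(),
            "v_gene": pool.loc[nz, "v_gene"].to_numpy(),
            "j_gene": pool.loc[nz, "j_gene"].to_numpy(),
            "chain": pool.loc[nz, "chain"].to_numpy(),
            "count": counts[nz],
        }
    )
    if imp_rows:
        imp = pd.DataFrame(imp_rows, columns=["cdr3_aa", "v_gene", "j_gene", "chain", "count"])
        table = pd.concat([imp, table], ignore_index=True)
    table["count"] = table["count"].astype(np.int64)
    table["frequency"] = table["count"] / table["count"].sum()
    return Repertoire(sample_id=sample_id, group=group, table=table)


def generate_cohort(spec: SyntheticSpec) -> list[Repertoire]:
    """Generate the full case/control cohort, reproducibly from the spec seed.

    Background clones are drawn per sample from the shared Zipf pool
    (multinomial at the sample's UMI depth, after lognormal per-sample
    weight jitter); implanted clones are inserted per their group-conditional
    presence probabilities and frequency scales. The last ``n_undersized``
    control samples are generated at ``undersized_umis`` depth.
    """
    pool = _background_pool(spec)
    size_rng = np.random.default_rng([spec.seed, 4])
    lo, hi = spec.umis_per_sample
    reps: list[Repertoire] = []
    n_total = spec.n_case + spec.n_control
    depths = np.exp(size_rng.uniform(np.log(lo), np.log(hi), n_total)).astype(int)
    for i in range(spec.n_case):
        reps.append(_sample_repertoire(spec, pool, f"OC{i + 1:02d}", "OC", i, int(depths[i])))
    for k in range(spec.n_control):
        i = spec.n_case + k
        n_umis = int(depths[i])
        if k >= spec.n_control - spec.n_undersized:
            n_umis = spec.undersized_umis
        reps.append(_sample_repertoire(spec, pool, f"HD{k + 1:02d}", "HD", i, n_umis))
    return reps


_DB_SOURCES = ("VDJDB_LIKE", "MCPAS_LIKE", "TCGA_TIL_LIKE")
_PAIRS = ((0, 1), (1, 2), (0, 2))


def generate_public_dbs(
    spec: SyntheticSpec,
    overlap: int,
    n_cohort_absent: int = 9,
    n_background_records: int = 200,
) -> tuple[PublicDBTable, PublicDBTable, PublicDBTable]:
    """Three public-DB fixtures whose top-10 prevalence lists share ``overlap``
    sequences.

    Each shared sequence appears in exactly two of the three lists, so the
    union of the top-10 lists has 30 − overlap members; ``overlap=10`` is the
    degenerate identical-lists case (union 10). Implanted clones are placed
    among the top entries (so the top-clones route can recover them);
    ``n_cohort_absent`` of the non-implanted top entries are novel sequences
    absent from the cohort, the rest are drawn from the head of the shared
    background pool and are therefore present in essentially every sample.
    """
    if not 0 <= overlap <= 10:
        raise ValueError("overlap must be in [0, 10]")
    pool = _background_pool(spec)
    rng = np.random.default_rng([spec.seed, 2])
    implanted = [c.cdr3_aa for c in spec.implanted_clones]

    if overlap == 10:
        distinct_n = 10
        capacity = 10
    else:
        distinct_n = 30 - overlap
        capacity = 30 - 2 * overlap  # unique (non-shared) slots across the three lists
    if len(implanted) + n_cohort_absent > capacity:
        raise ValueError("implanted clones plus absent entries exceed the top-list capacity")

    novel = _random_cdr3s(rng, n_cohort_absent + 3 * n_background_records,
                          spec.cdr3_length_range,
                          frozenset(pool["cdr3_aa"]) | frozenset(implanted))
    absent_top = novel[:n_cohort_absent]
    pool_head = pool["cdr3_aa"].head(distinct_n).tolist()

    if overlap == 10:
        # identical lists: implanted first, then pool clones, then absentees
        top = (implanted + [c for c in pool_head if c not in implanted])[: 10 - n_cohort_absent]
        top += absent_top[: 10 - len(top)]
        lists = [list(top), list(top), list(top)]
    else:
        n_unique = 30 - 2 * overlap
        uniques = (implanted + absent_top + pool_head)[:n_unique]
        shared_pool = [c for c in pool_head if c not in uniques]
        shared = shared_pool[:overlap]
        lists = [[], [], []]
        for idx, seq in enumerate(shared):
            for db_i in _PAIRS[idx % 3]:
                lists[db_i].append(seq)
        turn = 0
        for seq in uniques:
            while len(lists[turn % 3]) >= 10:
                turn += 1
            lists[turn % 3].append(seq)
            turn += 1

    dbs = []
    bg_iter = iter(novel[n_cohort_absent:])
    bg_pool_candidates = pool["cdr3_aa"].iloc[distinct_n + overlap:].to_numpy()
    for db_i, source in enumerate(_DB_SOURCES):
        top = lists[db_i]
        top_prev = np.sort(rng.integers(100, 300, size=len(top)))[::-1]
        n_from_pool = n_background_records // 2
        bg_keys = list(rng.choice(bg_pool_candidates, size=n_from_pool, replace=False))
        bg_keys += [next(bg_iter) for _ in range(n_background_records - n_from_pool)]
        bg_keys = [k for k in bg_keys if k not in top]
        bg_prev = rng.integers(1, 50, size=len(bg_keys))
        records = pd.DataFrame(
            {
                "cdr3_aa": top + bg_keys,
                "prevalence": np.concatenate([top_prev, bg_prev]).astype(np.int64),
                "metadata": [f"{source.lower()} synthetic entry"] * (len(top) + len(bg_keys)),
            }
        )
        records = records.sort_values(
            ["prevalence", "cdr3_aa"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
        dbs.append(PublicDBTable(source=source, records=records))
    return tuple(dbs)


DEFAULT_CANCER_TYPES = ("OV", "BRCA", "LUAD", "COAD", "SKCM", "PRAD", "KIRC", "HNSC")


def generate_til_db(
    spec: SyntheticSpec,
    n_tumors: int,
    clones_per_tumor: tuple[int, int] = (20, 200),
    enriched: frozenset[str] | set[str] = frozenset(),
    p_enriched: float = 0.0,
    cancer_types: tuple[str, ...] = DEFAULT_CANCER_TYPES,
) -> TILDatabase:
    """A synthetic TIL database: tumor samples with cancer-type labels and
    CDR3 sets drawn (Zipf-weighted, without replacement) from the background
    pool; each clone in ``enriched`` is independently added to each tumor
    with probability ``p_enriched``."""
    if not 0.0 <= p_enriched <= 1.0:
        raise ValueError("p_enriched must be in [0, 1]")
    pool = _background_pool(spec)
    rng = np.random.default_rng([spec.seed, 3])
    keys = pool["cdr3_aa"].to_numpy()
    weights = pool["weight"].to_numpy()
    enriched = sorted(enriched)
    samples: dict[str, tuple[str, frozenset[str]]] = {}
    for t in range(n_tumors):
        ctype = cancer_types[int(rng.integers(0, len(cancer_types)))]
        n_clones = int(rng.integers(clones_per_tumor[0], clones_per_tumor[1] + 1))
        clones = set(rng.choice(keys, size=n_clones, replace=False, p=weights))
        for c in enriched:
            if rng.random() < p_enriched:
                clones.add(c)
        samples[f"TUMOR{t + 1:04d}"] = (ctype, frozenset(clones))
    return TILDatabase(samples=samples)
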