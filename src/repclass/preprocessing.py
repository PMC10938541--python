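"""Repertoire exclusion and depth-matched downsampling.

Diversity and frequency comparisons across repertoires are only fair at a
common sequencing depth, so the cohort is downsampled to the depth of its
smallest retained repertoire. Downsampling draws reads without replacement
from the read-level multiset (each clone repeated ``count`` times) — a
multivariate-hypergeometric sample of the observed reads, not a simulation
from a fitted abundance model. Repertoires too small to downsample to are
excluded first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from repclass.repertoire_io import Repertoire

logger = logging.getLogger(__name__)

__all__ = ["DownsampleResult", "exclusion_filter", "downsample", "downsample_cohort"]


@dataclass
class DownsampleResult:
    repertoires: list[Repertoire]
    target: int  # common UMI depth (the minimum retained depth)
    excluded: list[str]  # sample_ids removed by the exclusion filter


def default_min_umis(repertoires: list[Repertoire]) -> int:
    """Default exclusion threshold: a tenth of the 5th-percentile cohort depth.

    Flags only repertoires an order of magnitude below the cohort's lower
    tail, so ordinary depth variation (which spans decades in real cohorts)
    is never excluded; override via ``min_umis`` for explicit control.
    """
    depths = np.array([r.total_umis for r in repertoires])
    return max(1, int(np.percentile(depths, 5) / 10))


def exclusion_filter(
    repertoires: list[Repertoire], min_umis: int | None = None
) -> tuple[list[Repertoire], list[Repertoire]]:
    """Split a cohort into (kept, excluded) by total UMI count.

    ``min_umis=None`` uses :func:`default_min_umis`. Excluded samples are
    logged with their sizes; excluding everything is an error.
    """
    if min_umis is None:
        min_umis = default_min_umis(repertoires)
    if min_umis < 1:
        raise ValueError("min_umis must be >= 1")
    kept = [r for r in repertoires if r.total_umis >= min_umis]
    excluded = [r for r in repertoires if r.total_umis < min_umis]
    for r in excluded:
        logger.warning(
            "excluding %s: %d UMIs below threshold %d", r.sample_id, r.total_umis, min_umis
        )
    if not kept:
        raise ValueError(f"all {len(repertoires)} repertoires fall below min_umis={min_umis}")
    return kept, excluded


def downsample(repertoire: Repertoire, target: int, seed: int = 0) -> Repertoire:
    """Downsample one repertoire to exactly ``target`` UMIs.

    Per-clone sampled counts follow the multivariate hypergeometric
    distribution (reads drawn uniformly without replacement); clones sampled
    to zero are dropped and frequencies recomputed. ``target == total_umis``
    returns the repertoire unchanged.
    """
    total = repertoire.total_umis
    if target > total:
        raise ValueError(
            f"{repertoire.sample_id}: target {target} exceeds total UMIs {total}"
        )
    if target == total:
        return repertoire
    rng = np.random.default_rng(seed)
    counts = repertoire.table["count"].to_numpy()
    sampled = rng.multivariate_hypergeometric(counts, target)
    keep = sampled > 0
    table = repertoire.table.loc[keep].copy()
    table["count"] = sampled[keep]
    table["frequency"] = table["count"] / target
    return repertoire.with_table(table.reset_index(drop=True))


def downsample_cohort(
    repertoires: list[Repertoire],
    seed: int = 0,
    min_umis: int | None = None,
) -> DownsampleResult:
    """Exclude undersized repertoires, then downsample the rest to the
    minimum retained depth, each sample on its own seed substream."""
    if len(repertoires) < 2:
        raise ValueError("need at least 2 repertoires")
    kept, excluded = exclusion_filter(repertoires, min_umis=min_umis)
    target = min(r.total_umis for r in kept)
    seeds = np.random.SeedSequence(seed).spawn(len(kept))
    out = [
        downsample(r, target, seed=sub)  # type: ignore[arg-type]
        for r, sub in zip(kept, seeds)
    ]
    logger.info("downsampled %d repertoires to %d UMIs", len(out), target)
    return DownsampleResult(
        repertoires=out, target=target, excluded=[r.sample_id for r in excluded]
    )
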