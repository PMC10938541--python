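"""End-to-end orchestration of the two classification routes.

Stages communicate through serialized artifacts in the output directory
(clonotype TSVs, feature-set JSON, model-report JSON) so any stage can be
re-run or audited in isolation; every run writes a provenance record with
the resolved configuration, seeds, library versions and stage timings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from repclass import repertoire_io as rio
from repclass.clone_annotation import annotate_subtype
from repclass.feature_selection import (
    backward_sfs,
    intersect_with_cohort,
    rank_common_clones,
    select_from_model,
    top_db_clones,
)
from repclass.modeling import ModelReport, SearchConfig, multi_split_evaluation, split_cohort
from repclass.preprocessing import downsample_cohort
from repclass.repertoire_io import CohortMatrix, Repertoire, build_cohort_matrix
from repclass.synthetic_data import SyntheticSpec, generate_cohort, generate_public_dbs

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_topdown", "run_topclones", "load_cohort_dir"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of ``synthetic`` (a :class:`SyntheticSpec`) or ``input_dir``
    (a directory of clonotype TSVs plus ``metadata.csv``) provides the
    cohort. The top-down route reduces the ``n_candidates`` most shared
    clones to ``sfm_k`` by select-from-model and then to ``final_k`` by
    backward sequential selection; the top-clones route starts from the
    ``n_per_db`` most prevalent clones of three public databases and reduces
    the cohort-present subset to ``intermediate_k`` then ``topclones_k``.
    """

    synthetic: SyntheticSpec | None = None
    input_dir: str | None = None
    dialect: str = "MIXCR"
    route: str = "TOP_DOWN"  # TOP_DOWN | TOP_CLONES | BOTH
    search: SearchConfig = field(default_factory=SearchConfig)
    out_dir: str = "repclass_out"
    seed: int = 0
    min_umis: int | None = None
    selection_on_full: bool = False  # candidate pool / selection on full cohort instead of train
    # top-down route
    n_candidates: int = 600
    sfm_k: int = 10
    sfm_selector: str = "LGB"
    sfs_estimator: str = "gbm"
    final_k: int = 3
    topdown_family: str = "gbm"
    # top-clones route
    n_per_db: int = 10
    db_overlap: int = 5
    db_paths: tuple[str, str, str] | None = None
    intermediate_k: int = 8
    topclones_k: int = 4
    topclones_family: str = "lda"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_dir is None):
            raise ValueError("exactly one of synthetic spec or input_dir must be set")


def load_cohort_dir(input_dir: str | Path, dialect: str = "MIXCR") -> list[Repertoire]:
    """Read every ``<sample>.tsv`` in a directory, labelled by metadata.csv."""
    input_dir = Path(input_dir)
    meta = rio.read_metadata(input_dir / "metadata.csv")
    reps = []
    for sid, group in meta.items():
        reps.append(rio.read_clonotypes(input_dir / f"{sid}.tsv", dialect, str(sid), group=str(group)))
    return reps


class _Provenance:
    def __init__(self, config: RunConfig, out: Path):
        self.record: dict = {
            "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
            "versions": _versions(),
            "stages": {},
        }
        self.out = out

    def stage(self, name: str):
        prov = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, *exc):
                prov.record["stages"][name] = round(time.perf_counter() - self.t0, 3)
                logger.info("stage %s: %.2fs", name, prov.record["stages"][name])
                return False

        return _Timer()

    def write(self) -> None:
        (self.out / "provenance.json").write_text(json.dumps(self.record, indent=2))


def _versions() -> dict[str, str]:
    import lightgbm
    import sklearn
    import xgboost

    import repclass

    return {
        "repclass": repclass.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "xgboost": xgboost.__version__,
        "lightgbm": lightgbm.__version__,
    }


def _prepare_matrix(config: RunConfig, prov: _Provenance) -> CohortMatrix:
    with prov.stage("cohort"):
        if config.synthetic is not None:
            reps = generate_cohort(config.synthetic)
        else:
            reps = load_cohort_dir(config.input_dir, config.dialect)
        reps = [rio.aggregate_by_cdr3(r) for r in reps]
    with prov.stage("downsample"):
        ds = downsample_cohort(reps, seed=config.seed, min_umis=config.min_umis)
        prov.record["excluded_samples"] = ds.excluded
        prov.record["downsample_target"] = ds.target
    with prov.stage("matrix"):
        matrix = build_cohort_matrix(ds.repertoires)
    prov.record["n_samples"] = matrix.n_samples
    prov.record["n_clones"] = len(matrix.clone_keys)
    # V/J annotations for later subtype calls: highest-count occurrence wins
    _remember_vj(ds.repertoires, prov)
    return matrix


def _remember_vj(reps: Sequence[Repertoire], prov: _Provenance) -> None:
    frames = [r.table[["cdr3_aa", "v_gene", "j_gene", "count"]] for r in reps]
    allc = pd.concat(frames, ignore_index=True)
    best = allc.sort_values("count", ascending=False, kind="stable").drop_duplicates("cdr3_aa")
    prov.vj = best.set_index("cdr3_aa")[["v_gene", "j_gene"]]  # type: ignore[attr-defined]


def _annotate(keys: Sequence[str], prov: _Provenance, out: Path, name: str) -> pd.DataFrame:
    vj = getattr(prov, "vj", pd.DataFrame(columns=["v_gene", "j_gene"]))
    rows = []
    for c in keys:
        v = vj.loc[c, "v_gene"] if c in vj.index else ""
        j = vj.loc[c, "j_gene"] if c in vj.index else ""
        call = annotate_subtype(v, j, cdr3_aa=c)
        rows.append((c, v, j, call.subtype))
    df = pd.DataFrame(rows, columns=["cdr3_aa", "v_gene", "j_gene", "subtype"])
    df.to_csv(out / name, index=False)
    return df


def run_topdown(config: RunConfig) -> ModelReport:
    """Shared-clone route: rank common clones, select-from-model, backward
    sequential selection, then multi-split evaluation of the final model."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _Provenance(config, out)
    matrix = _prepare_matrix(config, prov)
    cfg = config.search
    sel_matrix = matrix
    if not config.selection_on_full:
        sel_matrix, _ = split_cohort(matrix, cfg.test_size, seed=config.seed)
    with prov.stage("rank_common"):
        candidates = rank_common_clones(sel_matrix, config.n_candidates)
        sel_matrix.restrict_clones(candidates).to_csv(out / "matrix_candidates.csv")
    with prov.stage("sfm"):
        fs_mid = select_from_model(
            sel_matrix.restrict_clones(candidates),
            sel_matrix.y(),
            config.sfm_selector,
            config.sfm_k,
            seed=config.seed,
        )
        fs_mid.to_json(out / "features_sfm.json")
    with prov.stage("sfs"):
        fs = backward_sfs(
            sel_matrix.restrict_clones(fs_mid.clone_keys),
            sel_matrix.y(),
            config.sfs_estimator,
            config.final_k,
            seed=config.seed,
        )
        fs.to_json(out / "features_final_topdown.json")
    with prov.stage("evaluation"):
        report = multi_split_evaluation(
            matrix,
            fs.clone_keys,
            config.topdown_family,
            n_splits=cfg.n_splits,
            seed=config.seed,
            config=cfg,
            selector=config.sfm_selector,
        )
        report.to_json(out / "report_topdown.json")
    _annotate(fs.clone_keys, prov, out, "annotations_topdown.csv")
    prov.write()
    logger.info("top-down mean AUC over %d splits: %.3f", cfg.n_splits, report.mean_auc)
    return report


def run_topclones(config: RunConfig) -> ModelReport:
    """Public-database route: most prevalent database clones, cohort
    intersection, two backward-selection reductions, multi-split evaluation."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _Provenance(config, out)
    matrix = _prepare_matrix(config, prov)
    cfg = config.search
    with prov.stage("databases"):
        if config.db_paths is not None:
            sources = ("VDJDB_LIKE", "MCPAS_LIKE", "TCGA_TIL_LIKE")
            dbs = tuple(rio.load_public_db(p, s) for p, s in zip(config.db_paths, sources))
        elif config.synthetic is not None:
            dbs = generate_public_dbs(config.synthetic, overlap=config.db_overlap)
        else:
            raise ValueError("top-clones route needs db_paths when reading a real cohort")
        candidates = top_db_clones(dbs, config.n_per_db)
        prov.record["db_candidates"] = candidates
    with prov.stage("intersection"):
        present = intersect_with_cohort(candidates, matrix)
        prov.record["cohort_present"] = present
        if not present:
            raise ValueError("no database clone is present in the cohort")
    sel_matrix = matrix
    if not config.selection_on_full:
        sel_matrix, _ = split_cohort(matrix, cfg.test_size, seed=config.seed)
    with prov.stage("sfs"):
        fs = None
        keys = present
        for k in (config.intermediate_k, config.topclones_k):
            if k < len(keys):
                fs = backward_sfs(
                    sel_matrix.restrict_clones(keys),
                    sel_matrix.y(),
                    config.topclones_family,
                    k,
                    seed=config.seed,
                    route="TOP_CLONES",
                )
                keys = fs.clone_keys
        if fs is None:  # already at or below the final size
            from repclass.feature_selection import FeatureSet

            fs = FeatureSet(keys, "TOP_CLONES", config.topclones_family, list(keys))
        fs.to_json(out / "features_final_topclones.json")
    with prov.stage("evaluation"):
        report = multi_split_evaluation(
            matrix,
            fs.clone_keys,
            config.topclones_family,
            n_splits=cfg.n_splits,
            seed=config.seed,
            config=cfg,
            selector=config.topclones_family,
        )
        report.to_json(out / "report_topclones.json")
    _annotate(fs.clone_keys, prov, out, "annotations_topclones.csv")
    prov.write()
    logger.info("top-clones mean AUC over %d splits: %.3f", cfg.n_splits, report.mean_auc)
    return report
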