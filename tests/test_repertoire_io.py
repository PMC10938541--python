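"""Clonotype-table parsing, aggregation and matrix assembly."""

import numpy as np
import pandas as pd
import pytest

from repclass.repertoire_io import (
    CohortMatrix,
    EmptyRepertoireError,
    Repertoire,
    RepertoireFormatError,
    aggregate_by_cdr3,
    build_cohort_matrix,
    load_public_db,
    read_clonotypes,
    write_clonotypes,
)


def _airr_file(tmp_path, rows, name="s.tsv"):
    path = tmp_path / name
    pd.DataFrame(rows, columns=["junction_aa", "v_call", "j_call", "duplicate_count"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def _rep(entries, sample_id="s1", group="UNKNOWN"):
    t = pd.DataFrame(entries, columns=["cdr3_aa", "v_gene", "j_gene", "chain", "count"])
    t["frequency"] = t["count"] / t["count"].sum()
    return Repertoire(sample_id=sample_id, group=group, table=t)


class TestReadClonotypes:
    def test_airr_frequencies(self, tmp_path):
        path = _airr_file(
            tmp_path,
            [
                ("CASSLKETQYF", "TRBV5-1*01", "TRBJ2-7*01", 5),
                ("CAVRDSNYQLIW", "TRAV1-2*01", "TRAJ33*01", 3),
                ("CASSLAYEQYF", "TRBV6-1*01", "TRBJ2-7*01", 2),
            ],
        )
        rep = read_clonotypes(path, "AIRR", "s1")
        assert rep.total_umis == 10
        assert sorted(rep.frequencies.tolist()) == [0.2, 0.3, 0.5]
        assert rep.table.loc[0, "v_gene"] == "TRBV5-1"  # allele stripped

    def test_nonproductive_rows_dropped_and_total_recomputed(self, tmp_path):
        path = _airr_file(
            tmp_path,
            [
                ("CASS*YF", "TRBV5-1", "TRBJ2-7", 100),
                ("CASS_LF", "TRBV5-1", "TRBJ2-7", 50),
                ("CASSLKETQYF", "TRBV5-1", "TRBJ2-7", 4),
            ],
        )
        rep = read_clonotypes(path, "AIRR", "s1")
        assert rep.total_umis == 4
        assert rep.frequencies.tolist() == [1.0]

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"junction_aa": ["CASSF"], "v_call": ["TRBV2"]}).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(RepertoireFormatError, match="j_call"):
            read_clonotypes(path, "AIRR", "s1")

    def test_all_rows_unusable_raises(self, tmp_path):
        path = _airr_file(tmp_path, [("CASS*F", "TRBV2", "TRBJ1-1", 3)])
        with pytest.raises(EmptyRepertoireError):
            read_clonotypes(path, "AIRR", "s1")

    @pytest.mark.parametrize("dialect", ["AIRR", "MIXCR"])
    def test_write_read_round_trip(self, tmp_path, tiny_cohort, dialect):
        """Round trip preserves (cdr3, V, J, count) in both dialects."""
        rep = tiny_cohort[0]
        path = tmp_path / f"rt_{dialect}.tsv"
        write_clonotypes(rep, path, dialect)
        back = read_clonotypes(path, dialect, rep.sample_id)
        cols = ["cdr3_aa", "v_gene", "j_gene", "count"]
        a = rep.table[cols].sort_values("cdr3_aa").reset_index(drop=True)
        b = back.table[cols].sort_values("cdr3_aa").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestAggregate:
    def test_duplicates_merged_and_annotation_from_majority(self):
        rep = _rep(
            [
                ("CASSLKETQYF", "TRBV5-1", "TRBJ2-7", "TRB", 4),
                ("CASSLKETQYF", "TRBV9", "TRBJ1-1", "TRB", 6),
                ("CAVRDSNYQLIW", "TRAV1-2", "TRAJ33", "TRA", 5),
            ]
        )
        agg = aggregate_by_cdr3(rep)
        assert agg.n_clonotypes == 2
        row = agg.table.set_index("cdr3_aa").loc["CASSLKETQYF"]
        assert row["count"] == 10
        assert row["v_gene"] == "TRBV9"  # from the higher-count constituent

    def test_already_unique_is_identity(self):
        rep = _rep([("CASSLKETQYF", "TRBV5-1", "TRBJ2-7", "TRB", 4)])
        assert aggregate_by_cdr3(rep) is rep

    def test_conservation_of_total_umis(self, tiny_cohort):
        """Aggregation never changes the UMI total nor invents records."""
        rng = np.random.default_rng(5)
        rep = tiny_cohort[0]
        # plant duplicates by splitting random rows
        t = rep.table.copy()
        dup = t.sample(20, random_state=1).copy()
        t.loc[dup.index, "count"] -= 0  # keep originals
        planted = pd.concat([t, dup], ignore_index=True)
        planted["frequency"] = planted["count"] / planted["count"].sum()
        messy = Repertoire("x", "HD", planted)
        agg = aggregate_by_cdr3(messy)
        assert agg.total_umis == messy.total_umis
        assert agg.n_clonotypes <= messy.n_clonotypes
        assert agg.table["cdr3_aa"].is_unique
        assert abs(agg.frequencies.sum() - 1) < 1e-9
        del rng


class TestCohortMatrix:
    def test_disjoint_union(self):
        a = _rep([("CAAAF", "TRAV2", "TRAJ4", "TRA", 3)], "A")
        b = _rep([("CBBBF", "TRBV2", "TRBJ1-1", "TRB", 5)], "B")
        m = build_cohort_matrix([a, b])
        assert m.values.shape == (2, 2)
        assert m.values.loc["CAAAF", "A"] == 1.0
        assert m.values.loc["CAAAF", "B"] == 0.0
        assert m.values.loc["CBBBF", "B"] == 1.0

    def test_columns_sum_to_one(self, tiny_matrix):
        assert np.allclose(tiny_matrix.values.sum(axis=0), 1.0, atol=1e-9)

    def test_duplicate_sample_ids_rejected(self):
        a = _rep([("CAAAF", "TRAV2", "TRAJ4", "TRA", 3)], "A")
        with pytest.raises(ValueError, match="duplicate"):
            build_cohort_matrix([a, a])

    def test_matrix_completeness_brute_force(self, tiny_cohort):
        """Every cell equals the clone's frequency in that sample, or 0."""
        reps = tiny_cohort[:5]
        m = build_cohort_matrix(reps)
        for rep in reps:
            freqs = dict(zip(rep.table["cdr3_aa"], rep.table["frequency"]))
            col = m.values[rep.sample_id]
            for clone in list(m.values.index[:50]):
                assert col.loc[clone] == pytest.approx(freqs.get(clone, 0.0))

    def test_row_order_is_sharing_then_frequency(self):
        reps = [
            _rep(
                [
                    ("CSHAREDF", "TRAV2", "TRAJ4", "TRA", 5),
                    (f"CPRIV{i}F", "TRAV2", "TRAJ4", "TRA", 5),
                ],
                f"S{i}",
            )
            for i in range(3)
        ]
        m = build_cohort_matrix(reps)
        assert m.values.index[0] == "CSHAREDF"

    def test_csv_round_trip(self, tiny_matrix, tmp_path):
        path = tmp_path / "m.csv"
        tiny_matrix.to_csv(path)
        back = CohortMatrix.from_csv(path, tiny_matrix.labels)
        pd.testing.assert_frame_equal(back.values, tiny_matrix.values)


class TestPublicDB:
    def _db_file(self, tmp_path, rows):
        path = tmp_path / "db.tsv"
        pd.DataFrame(rows, columns=["cdr3_aa", "prevalence", "metadata"]).to_csv(
            path, sep="\t", index=False
        )
        return path

    def test_group_and_sum(self, tmp_path):
        path = self._db_file(tmp_path, [("CAVF", 2, "a"), ("CAVF", 3, "b")])
        db = load_public_db(path, "VDJDB_LIKE")
        assert len(db.records) == 1
        assert db.prevalence_of("CAVF") == 5

    def test_empty_prevalence_counts_as_one(self, tmp_path):
        path = self._db_file(tmp_path, [("CAVF", None, "a")])
        db = load_public_db(path, "MCPAS_LIKE")
        assert db.prevalence_of("CAVF") == 1

    def test_malformed_rows_skipped_all_malformed_raises(self, tmp_path):
        path = self._db_file(tmp_path, [("CAV*F", 2, "x"), ("CAVWF", 2, "y")])
        db = load_public_db(path, "VDJDB_LIKE")
        assert len(db.records) == 1
        bad = self._db_file(tmp_path, [("CAV*F", 2, "x")])
        with pytest.raises(RepertoireFormatError):
            load_public_db(bad, "VDJDB_LIKE")

    def test_dedup_count_oracle(self, tmp_path):
        """100 records with 10 duplicated keys group to 90."""
        rng = np.random.default_rng(0)
        keys = [f"CA{''.join(rng.choice(list('DEFGHIKL'), 6))}F" for _ in range(90)]
        keys = list(dict.fromkeys(keys))
        assert len(keys) == 90
        rows = [(k, 1, "") for k in keys] + [(k, 1, "") for k in keys[:10]]
        db = load_public_db(self._db_file(tmp_path, rows), "TCGA_TIL_LIKE")
        assert len(db.records) == len(set(keys))
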