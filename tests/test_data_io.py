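import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from microtrace import (
    AbundanceTable,
    CountTable,
    SampleRecord,
    assemble_series,
    filter_low_abundance,
    read_count_table,
    read_metadata,
    to_relative_abundance,
    write_count_table,
    write_metadata,
)


def records_for(table, days_per_series=None):
    """One individual per sample unless days_per_series groups them."""
    recs = []
    if days_per_series is None:
        for i, sid in enumerate(table.sample_ids):
            recs.append(
                SampleRecord(sid, "sp1", f"ind{i}", "zoo1", f"ser{i}", 1)
            )
    return recs


class TestCountTableIO:
    def test_round_trip_identity(self, tiny_counts, tmp_path):
        p = tmp_path / "counts.tsv"
        write_count_table(tiny_counts, p)
        back = read_count_table(p)
        assert back.sample_ids == tiny_counts.sample_ids
        assert back.family_ids == tiny_counts.family_ids
        assert np.array_equal(back.counts, tiny_counts.counts)

    def test_taxa_as_rows_orientation(self, tiny_counts, tmp_path):
        p = tmp_path / "t.tsv"
        df = tiny_counts.to_frame().T
        df.index.name = "family_id"
        df.to_csv(p, sep="\t")
        back = read_count_table(p, taxa_as_rows=True)
        assert back.sample_ids == tiny_counts.sample_ids
        assert np.array_equal(back.counts, tiny_counts.counts)

    @pytest.mark.parametrize(
        "cell,match",
        [("-4", "negative"), ("3.5", "non-integer"), ("oops", "non-numeric")],
    )
    def test_bad_cells_report_position(self, tmp_path, cell, match):
        p = tmp_path / "bad.tsv"
        p.write_text(f"sample_id\tfA\tfB\ns1\t1\t{cell}\ns2\t2\t3\n")
        with pytest.raises(ValueError, match=match) as err:
            read_count_table(p)
        assert "s1" in str(err.value) and "fB" in str(err.value)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("sample_id\tfA\tfB\ns1\t1\t2\ns1\t3\t4\n")
        with pytest.raises(ValueError, match="duplicate sample id.*s1"):
            read_count_table(p)


class TestMetadataIO:
    def test_round_trip(self, tmp_path):
        recs = [
            SampleRecord("a", "sp1", "i1", "z1", "ser1", 1),
            SampleRecord("b", "sp1", "i1", "z1", "ser1", 2),
            SampleRecord("c", "sp2", "i2", "z2", "ser2", 1),
            SampleRecord("d", "sp2", "i2", "z2", "ser2", 4),
        ]
        p = tmp_path / "meta.tsv"
        write_metadata(recs, p)
        assert read_metadata(p) == recs

    def test_duplicate_series_day_rejected(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text(
            "sample_id\tspecies\tindividual\tsite\tseries\tday\n"
            "a\tsp1\ti1\tz1\tserA\t3\n"
            "b\tsp1\ti1\tz1\tserA\t3\n"
        )
        with pytest.raises(ValueError, match="serA"):
            read_metadata(p)

    def test_non_integer_day_rejected(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text(
            "sample_id\tspecies\tindividual\tsite\tseries\tday\n"
            "a\tsp1\ti1\tz1\tserA\t3.5\n"
        )
        with pytest.raises(ValueError, match="integer"):
            read_metadata(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text("sample_id\tspecies\tindividual\tsite\tday\na\tsp1\ti1\tz1\t1\n")
        with pytest.raises(ValueError, match="series"):
            read_metadata(p)


class TestFilterLowAbundance:
    def test_threshold_arithmetic(self, tiny_counts):
        # family totals are {12, 9, 10, 30}; the <10-read rule keeps 12, 10, 30
        out = filter_low_abundance(tiny_counts, 10)
        assert out.family_ids == ("fA", "fC", "fD")
        assert out.sample_ids == tiny_counts.sample_ids

    def test_zero_threshold_is_identity(self, tiny_counts):
        out = filter_low_abundance(tiny_counts, 0)
        assert out.family_ids == tiny_counts.family_ids
        assert np.array_equal(out.counts, tiny_counts.counts)

    def test_all_removed_is_error(self):
        t = CountTable(("s1",), ("fA", "fB"), np.array([[3, 4]]))
        with pytest.raises(ValueError, match="threshold"):
            filter_low_abundance(t, 10)

    def test_idempotent(self, tiny_counts):
        once = filter_low_abundance(tiny_counts, 10)
        twice = filter_low_abundance(once, 10)
        assert twice.family_ids == once.family_ids
        assert np.array_equal(twice.counts, once.counts)


class TestRelativeAbundance:
    def test_closed_forms(self):
        t = CountTable(("s1", "s2"), ("a", "b", "c"), np.array([[5, 5, 0], [10, 0, 0]]))
        ab = to_relative_abundance(t)
        assert np.allclose(ab.proportions, [[0.5, 0.5, 0.0], [1.0, 0.0, 0.0]])

    def test_zero_row_errors_with_sample_name(self):
        t = CountTable(("ok", "empty"), ("a", "b"), np.array([[1, 1], [0, 0]]))
        with pytest.raises(ValueError, match="empty"):
            to_relative_abundance(t)

    @settings(max_examples=50, derandomize=True)
    @given(
        arrays(
            np.int64,
            st.tuples(st.integers(1, 6), st.integers(1, 8)),
            elements=st.integers(0, 1000),
        )
    )
    def test_rows_sum_to_one(self, counts):
        if (counts.sum(axis=1) == 0).any():
            counts = counts + 1
        t = CountTable(
            tuple(f"s{i}" for i in range(counts.shape[0])),
            tuple(f"f{j}" for j in range(counts.shape[1])),
            counts,
        )
        ab = to_relative_abundance(t)
        assert np.allclose(ab.proportions.sum(axis=1), 1.0, atol=1e-9)


class TestAssembleSeries:
    def _table(self, sample_ids, n_fam=3):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, size=(len(sample_ids), n_fam))
        return to_relative_abundance(
            CountTable(tuple(sample_ids), tuple(f"f{j}" for j in range(n_fam)), counts)
        )

    def test_eight_day_series(self):
        ids = [f"x_d{d}" for d in range(1, 9)]
        recs = [SampleRecord(s, "sp1", "i1", "z1", "serX", d) for d, s in enumerate(ids, 1)]
        series = assemble_series(self._table(ids), recs)
        assert len(series) == 1 and len(series[0]) == 8
        assert series[0].day_indices == tuple(range(1, 9))

    def test_missing_days_are_absent(self):
        days = [1, 2, 4, 5]
        ids = [f"x_d{d}" for d in days]
        recs = [SampleRecord(s, "sp1", "i1", "z1", "serX", d) for d, s in zip(days, ids)]
        series = assemble_series(self._table(ids), recs)
        assert series[0].day_indices == (1, 2, 4, 5)
        assert len(series[0]) == 4

    def test_two_individuals(self):
        ids = [f"{i}_d{d}" for i in ("a", "b") for d in (1, 2, 3)]
        recs = [
            SampleRecord(f"{i}_d{d}", "sp1", i, "z1", f"ser_{i}", d)
            for i in ("a", "b")
            for d in (1, 2, 3)
        ]
        series = assemble_series(self._table(ids), recs)
        assert [s.series_id for s in series] == ["ser_a", "ser_b"]
        assert all(len(s) == 3 for s in series)

    def test_partitions_samples(self, default_abundances):
        ab, records, _ = default_abundances
        series = assemble_series(ab, records)
        seen = [
            f"{s.series_id}_d{d}" for s in series for d in s.day_indices
        ]
        assert sorted(seen) == sorted(ab.sample_ids)

    def test_sample_without_metadata_errors(self):
        ab = self._table(["a", "b"])
        recs = [SampleRecord("a", "sp1", "i1", "z1", "ser1", 1)]
        with pytest.raises(ValueError, match="'b'"):
            assemble_series(ab, recs)
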