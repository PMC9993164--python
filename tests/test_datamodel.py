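import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from symdelta.datamodel import (
    MISSING,
    DataFormatError,
    Dataset,
    DiscreteVariable,
    EmptyDatasetError,
    load_matrix,
    prune_by_missingness,
    to_bitplanes,
    write_matrix,
)

from conftest import random_dataset


class TestLoadMatrix:
    def test_small_tsv_read_back(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("A\tB\n0\t1\n1\t0\n0\t0\n")
        ds = load_matrix(path)
        assert ds.n_variables == 2 and ds.n_samples == 3
        assert [v.n_bins for v in ds.variables] == [2, 2]
        np.testing.assert_array_equal(ds["A"].codes, [0, 1, 0])

    def test_sentinel_counts_as_missing(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("A\tB\n0\t-1\n-1\t1\n-1\t2\n")
        ds = load_matrix(path)
        assert ds["A"].n_missing == 2
        assert ds["B"].n_missing == 1
        assert ds["B"].n_bins == 3

    def test_genotype_matrix_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        matrix = rng.choice([0, 1, 2, MISSING], size=(5556, 10),
                            p=[0.6, 0.1, 0.25, 0.05])
        ds = Dataset.from_matrix(matrix, [f"SNP{j}" for j in range(10)])
        path = tmp_path / "geno.tsv"
        write_matrix(ds, path)
        back = load_matrix(path)
        assert back.names == ds.names
        for a, b in zip(ds.variables, back.variables):
            np.testing.assert_array_equal(a.codes, b.codes)

    def test_csv_delimiter_and_transpose(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("id,s1,s2,s3\nA,0,1,0\nB,1,1,0\n")
        ds = load_matrix(path, orientation="variables-as-rows")
        assert ds.names == ["A", "B"]
        assert ds.n_samples == 3
        assert ds.sample_ids == ["s1", "s2", "s3"]

    def test_non_integer_cell_names_location(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("A\tB\n0\t1\n0.5\t0\n")
        with pytest.raises(DataFormatError, match="A"):
            load_matrix(path)

    def test_duplicate_names_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("A\tA\n0\t1\n")
        with pytest.raises(DataFormatError, match="duplicate"):
            load_matrix(path)


class TestDiscreteVariable:
    def test_out_of_range_code_rejected(self):
        with pytest.raises(DataFormatError):
            DiscreteVariable("x", 0, np.array([0, 3]), n_bins=2)

    def test_bins_inferred_from_max_code(self):
        v = DiscreteVariable.from_codes("x", 0, [0, 2, MISSING])
        assert v.n_bins == 3 and v.n_missing == 1


class TestBitPlanes:
    def test_by_definition_example(self):
        v = DiscreteVariable.from_codes("x", 0, [0, 1, 0, MISSING], n_bins=2)
        bp = to_bitplanes(v)
        word = lambda bits: sum(1 << i for i in bits)
        assert bp.planes[0][0] == word([0, 2])
        assert bp.planes[1][0] == word([1])
        assert bp.valid[0] == word([0, 1, 2])

    def test_all_missing_variable(self):
        v = DiscreteVariable.from_codes("x", 0, [MISSING] * 5, n_bins=2)
        bp = to_bitplanes(v)
        assert not bp.planes.any() and not bp.valid.any()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           m=st.integers(1, 300),
           b=st.integers(1, 4),
           missing_rate=st.floats(0, 0.5))
    def test_encode_decode_round_trip(self, seed, m, b, missing_rate):
        """Round trip holds for any M, including non-word-aligned lengths."""
        rng = np.random.default_rng(seed)
        codes = rng.integers(0, b, size=m)
        codes[rng.random(m) < missing_rate] = MISSING
        v = DiscreteVariable.from_codes("x", 0, codes, n_bins=b)
        bp = to_bitplanes(v)
        np.testing.assert_array_equal(bp.decode(), codes)
        # invariants: disjoint planes OR-ing to the validity mask
        acc = np.zeros_like(bp.valid)
        for i in range(b):
            for j in range(i + 1, b):
                assert not (bp.planes[i] & bp.planes[j]).any()
            acc |= bp.planes[i]
        np.testing.assert_array_equal(acc, bp.valid)
        assert int(np.bitwise_count(bp.valid).sum()) == m - v.n_missing


class TestPrune:
    def _dataset_with_missing(self, counts, m=1100):
        cols = []
        for k, c in enumerate(counts):
            col = np.zeros(m, dtype=np.int64)
            col[:c] = MISSING
            cols.append(col)
        return Dataset.from_matrix(np.column_stack(cols),
                                   [f"v{k}" for k in range(len(counts))])

    def test_boundary_is_inclusive(self):
        ds = self._dataset_with_missing([0, 1000, 1001])
        pruned = prune_by_missingness(ds, 1000)
        assert pruned.names == ["v0", "v1"]

    def test_threshold_at_sample_count_is_identity(self):
        ds = self._dataset_with_missing([0, 500, 1100])
        assert prune_by_missingness(ds, 1100).names == ds.names

    def test_idempotent_and_reindexed(self):
        ds = self._dataset_with_missing([0, 1001, 5])
        once = prune_by_missingness(ds, 1000)
        twice = prune_by_missingness(once, 1000)
        assert once.names == twice.names == ["v0", "v2"]
        assert [v.index for v in once.variables] == [0, 1]

    def test_protected_variable_survives(self):
        ds = self._dataset_with_missing([1001, 0])
        pruned = prune_by_missingness(ds, 1000, protected=["v0"])
        assert "v0" in pruned.names

    def test_fractional_threshold(self):
        ds = self._dataset_with_missing([0, 110, 111], m=1100)
        assert prune_by_missingness(ds, 0.1).names == ["v0", "v1"]

    def test_empty_result_raises(self):
        ds = self._dataset_with_missing([500, 600])
        with pytest.raises(EmptyDatasetError):
            prune_by_missingness(ds, 10)

    def test_retained_count_matches_direct_count(self):
        """Size bookkeeping on a 1000-variable simulation."""
        rng = np.random.default_rng(7)
        m, n = 60, 1000
        matrix = rng.integers(0, 2, size=(m, n))
        matrix[rng.random(matrix.shape) < 0.3] = MISSING
        ds = Dataset.from_matrix(matrix, [f"v{j}" for j in range(n)])
        threshold = 18
        expected = sum(
            1 for j in range(n)
            if int((matrix[:, j] == MISSING).sum()) <= threshold
        )
        assert prune_by_missingness(ds, threshold).n_variables == expected


class TestDataset:
    def test_unequal_lengths_rejected(self):
        a = DiscreteVariable.from_codes("a", 0, [0, 1])
        b = DiscreteVariable.from_codes("b", 1, [0, 1, 0])
        with pytest.raises(DataFormatError):
            Dataset([a, b])

    def test_lookup_by_name(self):
        ds = random_dataset(0, n_variables=4)
        assert ds.index_of("v2") == 2
        with pytest.raises(KeyError):
            ds.index_of("nope")
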