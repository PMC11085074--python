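import numpy as np
import pytest

from pairgrn.matrix import (
    ExpressionMatrix,
    ExpressionMatrixError,
    align_gene_universe,
    log_transform,
    normalize_per_million,
    read_dense_matrix,
    read_sparse_triplet,
)


def _write(path, text):
    path.write_text(text)
    return path


class TestReadDense:
    def test_basic_parse(self, tmp_path):
        p = _write(tmp_path / "m.tsv",
                   "gene_id\ts1\ts2\ng1\t1\t2\ng2\t3\t4\ng3\t5\t6\n")
        m = read_dense_matrix(p)
        assert m.values.shape == (3, 2)
        assert m.gene_ids == ["g1", "g2", "g3"]
        assert m.transform_state == "raw"

    def test_genes_in_columns_is_transposed(self, tmp_path):
        p = _write(tmp_path / "m.tsv",
                   "sample\tg1\tg2\ns1\t1\t2\ns2\t3\t4\n")
        m = read_dense_matrix(p, orientation="genes_in_columns")
        assert m.gene_ids == ["g1", "g2"]
        assert m.sample_ids == ["s1", "s2"]
        np.testing.assert_array_equal(m.values, [[1, 3], [2, 4]])

    def test_duplicate_gene_id_named(self, tmp_path):
        p = _write(tmp_path / "m.tsv", "g\ts1\ng1\t1\ng1\t2\n")
        with pytest.raises(ExpressionMatrixError, match="g1"):
            read_dense_matrix(p)

    def test_non_numeric_cell_located(self, tmp_path):
        p = _write(tmp_path / "m.tsv", "g\ts1\ts2\ng1\t1\toops\n")
        with pytest.raises(ExpressionMatrixError, match="g1.*s2|s2.*g1"):
            read_dense_matrix(p)

    def test_csv_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        m = ExpressionMatrix(
            ["g1", "g2"], ["s1", "s2", "s3"],
            rng.random((2, 3)) * 1000, "bulk",
        )
        out = tmp_path / "rt.tsv"
        m.to_tsv(out)
        back = read_dense_matrix(out)
        np.testing.assert_array_equal(back.values, m.values)
        assert back.gene_ids == m.gene_ids
        assert back.sample_ids == m.sample_ids


class TestReadSparseTriplet:
    def _triplet(self, tmp_path, body, n_genes=2, n_cells=2, n_entries=None):
        if n_entries is None:
            n_entries = len(body.strip().splitlines()) if body.strip() else 0
        mtx = _write(
            tmp_path / "m.mtx",
            "%%MatrixMarket matrix coordinate real general\n"
            f"{n_genes} {n_cells} {n_entries}\n{body}",
        )
        genes = _write(tmp_path / "g.tsv",
                       "\n".join(f"g{i}" for i in range(n_genes)) + "\n")
        cells = _write(tmp_path / "c.tsv",
                       "\n".join(f"c{i}" for i in range(n_cells)) + "\n")
        return mtx, genes, cells

    def test_sparse_fill(self, tmp_path):
        m = read_sparse_triplet(*self._triplet(tmp_path, "1 1 5\n"))
        np.testing.assert_array_equal(m.values, [[5, 0], [0, 0]])
        assert m.modality == "single_cell"

    def test_out_of_bounds_index_rejected(self, tmp_path):
        files = self._triplet(tmp_path, "3 1 5\n")
        with pytest.raises(ExpressionMatrixError):
            read_sparse_triplet(*files)

    def test_empty_body_gives_zero_matrix(self, tmp_path):
        m = read_sparse_triplet(*self._triplet(tmp_path, "", n_entries=0))
        np.testing.assert_array_equal(m.values, np.zeros((2, 2)))

    def test_sidecar_length_mismatch_rejected(self, tmp_path):
        mtx, genes, cells = self._triplet(tmp_path, "1 1 5\n")
        genes.write_text("g0\n")  # one id for a 2-row matrix
        with pytest.raises(ExpressionMatrixError, match="sidecar"):
            read_sparse_triplet(mtx, genes, cells)


class TestNormalizePerMillion:
    def test_proportional_scaling(self):
        m = ExpressionMatrix(["a", "b", "c"], ["s"], [[10], [30], [60]], "bulk")
        out = normalize_per_million(m)
        np.testing.assert_allclose(out.values[:, 0], [1e5, 3e5, 6e5])

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(1)
        m = ExpressionMatrix(
            [f"g{i}" for i in range(5)], ["s1", "s2"],
            rng.integers(1, 100, (5, 2)).astype(float), "bulk",
        )
        out = normalize_per_million(m)
        np.testing.assert_allclose(out.values.sum(axis=0), [1e6, 1e6])

    def test_tpm_with_lengths_hand_example(self):
        m = ExpressionMatrix(["a", "b"], ["s"], [[2], [2]], "bulk")
        out = normalize_per_million(m, gene_lengths={"a": 1, "b": 2})
        np.testing.assert_allclose(
            out.values[:, 0], [666666.67, 333333.33], atol=0.01
        )

    def test_not_idempotent_silently(self):
        m = ExpressionMatrix(["a"], ["s"], [[5]], "bulk")
        out = normalize_per_million(m)
        with pytest.raises(ExpressionMatrixError, match="raw"):
            normalize_per_million(out)

    def test_non_positive_length_rejected(self):
        m = ExpressionMatrix(["a"], ["s"], [[5]], "bulk")
        with pytest.raises(ExpressionMatrixError, match="length"):
            normalize_per_million(m, gene_lengths={"a": 0})

    def test_all_zero_column_left_at_zero(self):
        m = ExpressionMatrix(["a", "b"], ["s1", "s2"], [[1, 0], [1, 0]], "bulk")
        out = normalize_per_million(m)
        np.testing.assert_array_equal(out.values[:, 1], [0, 0])
        np.testing.assert_allclose(out.values[:, 0].sum(), 1e6)


class TestLogTransform:
    @pytest.mark.parametrize(
        "value,base,pseudo,expected",
        [(0, 10, 1, 0.0), (99, 10, 1, 2.0), (7, 2, 1, 3.0)],
    )
    def test_hand_values(self, value, base, pseudo, expected):
        m = ExpressionMatrix(["g"], ["s"], [[value]], "bulk")
        out = log_transform(m, base=base, pseudocount=pseudo)
        assert out.values[0, 0] == pytest.approx(expected)
        assert out.transform_state == "log"

    def test_zero_pseudocount_with_zeros_rejected(self):
        m = ExpressionMatrix(["g"], ["s"], [[0]], "bulk")
        with pytest.raises(ExpressionMatrixError, match="inf"):
            log_transform(m, pseudocount=0)

    def test_double_log_rejected(self):
        m = ExpressionMatrix(["g"], ["s"], [[1]], "bulk")
        with pytest.raises(ExpressionMatrixError):
            log_transform(log_transform(m))


class TestAlignGeneUniverse:
    def _mat(self, genes, values, modality="bulk"):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(
            genes, [f"s{i}" for i in range(values.shape[1])], values, modality
        )

    def test_intersection_and_order(self):
        bulk = self._mat(["a", "b", "c"], [[1, 2], [3, 4], [5, 6]])
        sc = self._mat(["b", "c", "d"], [[1, 1], [2, 2], [3, 3]], "single_cell")
        b, s, shared = align_gene_universe(bulk, sc)
        assert shared == ["b", "c"]
        assert b.gene_ids == s.gene_ids == shared

    def test_all_zero_gene_dropped(self):
        bulk = self._mat(["a", "b"], [[1, 2], [3, 4]])
        sc = self._mat(["a", "b"], [[0, 0], [1, 2]], "single_cell")
        _, _, shared = align_gene_universe(bulk, sc)
        assert shared == ["b"]

    def test_identity(self):
        bulk = self._mat(["a", "b"], [[1, 2], [3, 4]])
        sc = self._mat(["a", "b"], [[1, 1], [2, 2]], "single_cell")
        b, s, shared = align_gene_universe(bulk, sc)
        assert shared == ["a", "b"]
        np.testing.assert_array_equal(b.values, bulk.values)

    def test_empty_intersection_rejected(self):
        bulk = self._mat(["a"], [[1]])
        sc = self._mat(["b"], [[1]], "single_cell")
        with pytest.raises(ExpressionMatrixError):
            align_gene_universe(bulk, sc)


class TestInvariants:
    def test_negative_values_rejected(self):
        with pytest.raises(ExpressionMatrixError):
            ExpressionMatrix(["g"], ["s"], [[-1.0]], "bulk")

    def test_nan_rejected(self):
        with pytest.raises(ExpressionMatrixError):
            ExpressionMatrix(["g"], ["s"], [[np.nan]], "bulk")

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ExpressionMatrixError):
            ExpressionMatrix(["g1", "g2"], ["s"], [[1.0]], "bulk")
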