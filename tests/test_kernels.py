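import numpy as np
import pytest

from glyqgram import (
    GeneratorConfig,
    GlycanError,
    assert_valid_kernel,
    build_index,
    combine_kernels,
    cosine_normalize,
    count_matrix,
    glycan_kernel,
    multi_q_kernel,
    psd_correct,
    qgram_kernel,
    random_glycan,
    weighted_kernel,
)
from glyqgram.kernels import KernelMatrix
from glyqgram.qgrams import CountMatrix
from glyqgram.similarity import SimilarityMatrix


def _sim(values, q=2, method="LK"):
    values = np.asarray(values, dtype=float)
    keys = [f"k{i}" for i in range(values.shape[0])]
    return SimilarityMatrix(q, keys, values, method)


def _counts(values, q=2):
    values = np.asarray(values, dtype=np.int64)
    keys = [f"k{i}" for i in range(values.shape[0])]
    ids = [f"g{i}" for i in range(values.shape[1])]
    return CountMatrix(q, keys, ids, values)


class TestPSDCorrect:
    def test_identity_unchanged(self):
        W = psd_correct(_sim(np.eye(3)))
        assert np.allclose(W.values, np.eye(3), atol=1e-8)
        assert W.report.min_eig_after >= 0

    def test_indefinite_matrix_clipped(self):
        # eigenvalues 3 and -1; clipping yields the nearest PSD matrix
        W = psd_correct(_sim([[1, 2], [2, 1]]))
        assert W.report.min_eig_before == pytest.approx(-1.0)
        assert W.report.min_eig_after >= 0
        assert np.allclose(W.values, [[1.5, 1.5], [1.5, 1.5]], atol=1e-6)

    def test_psd_input_is_noop(self):
        S = _sim([[1.0, 0.5], [0.5, 1.0]])
        W = psd_correct(S)
        assert np.linalg.norm(W.values - S.values) < 1e-8

    def test_shift_method_preserves_offdiagonal(self):
        W = psd_correct(_sim([[1, 2], [2, 1]]), method="shift")
        assert W.values[0, 1] == pytest.approx(2.0)
        assert W.report.min_eig_after >= 0

    def test_nonfinite_rejected(self):
        with pytest.raises(GlycanError):
            psd_correct(_sim([[1, np.nan], [np.nan, 1]]))


class TestQGramKernel:
    def test_disjoint_columns_orthogonal(self):
        K = qgram_kernel(_counts([[2, 0], [0, 3]]))
        assert K.values[0, 1] == 0.0

    def test_shared_key_inner_product(self):
        K = qgram_kernel(_counts([[2, 3]]))
        assert K.values[0, 1] == 6.0

    def test_equals_weighted_with_identity(self):
        X = _counts([[1, 2, 0], [0, 1, 3], [2, 0, 1]])
        K = qgram_kernel(X)
        KW = weighted_kernel(X, np.eye(3))
        assert np.allclose(K.values, KW.values)


class TestWeightedKernel:
    def test_offdiagonal_weight(self):
        X = _counts([[1, 0], [0, 1]])
        W = np.array([[1.0, 0.9], [0.9, 1.0]])
        K = weighted_kernel(X, W)
        assert K.values[0, 1] == pytest.approx(0.9)

    def test_single_column_quadratic_form(self):
        X = _counts([[1], [2]])
        W = psd_correct(_sim([[1.0, 0.5], [0.5, 1.0]]))
        K = weighted_kernel(X, W)
        assert K.values.shape == (1, 1) and K.values[0, 0] >= 0

    def test_dimension_mismatch(self):
        with pytest.raises(GlycanError):
            weighted_kernel(_counts([[1, 0], [0, 1]]), np.eye(3))


class TestCombine:
    def test_single_kernel_identity(self):
        K = qgram_kernel(_counts([[1, 2]]))
        C = combine_kernels({2: K})
        assert np.allclose(C.values, K.values)

    def test_sum_and_selection(self):
        A = KernelMatrix(np.eye(2), ["g0", "g1"])
        B = KernelMatrix(np.full((2, 2), 2.0), ["g0", "g1"])
        assert np.allclose(
            combine_kernels({2: A, 3: B}).values, A.values + B.values
        )
        picked = combine_kernels({2: A, 3: B}, {2: 0.0, 3: 1.0})
        assert np.allclose(picked.values, B.values)

    def test_mismatched_orders_rejected(self):
        A = KernelMatrix(np.eye(2), ["g0", "g1"])
        B = KernelMatrix(np.eye(2), ["g1", "g0"])
        with pytest.raises(GlycanError):
            combine_kernels({2: A, 3: B})

    def test_q_gram_additivity_on_random_data(self):
        """K_Q equals the sum of per-q kernels to machine precision."""
        cfg = GeneratorConfig(min_nodes=4, max_nodes=12, seed=0)
        rng = np.random.default_rng(5)
        glycans = [random_glycan(cfg, rng, id=f"G{i:02d}") for i in range(15)]
        qs = [2, 3, 4]
        per_q = {q: glycan_kernel(glycans, q)[0] for q in qs}
        KQ = multi_q_kernel(glycans, qs)
        total = sum(per_q[q].values for q in qs)
        assert np.allclose(KQ.values, total, rtol=0, atol=1e-12)
        assert_valid_kernel(KQ)


class TestCosineNormalize:
    def test_unit_diagonal_and_scale_invariance(self):
        K = KernelMatrix(np.array([[4.0, 2.0], [2.0, 9.0]]), ["a", "b"])
        N1 = cosine_normalize(K)
        N2 = cosine_normalize(KernelMatrix(7 * K.values, ["a", "b"]))
        assert np.allclose(np.diag(N1.values), 1.0)
        assert np.allclose(N1.values, N2.values)

    def test_rank_one_collapses_to_ones(self):
        K = KernelMatrix(np.array([[4.0, 2.0], [2.0, 1.0]]), ["a", "b"])
        assert np.allclose(cosine_normalize(K).values, 1.0)

    def test_zero_diagonal_names_glycan(self):
        K = KernelMatrix(np.array([[1.0, 0.0], [0.0, 0.0]]), ["a", "bad"])
        with pytest.raises(GlycanError, match="bad"):
            cosine_normalize(K)


class TestPipelines:
    @pytest.mark.parametrize("method", ["qgram", "lk", "km", "lkm"])
    def test_all_methods_emit_valid_kernels(self, method):
        cfg = GeneratorConfig(min_nodes=3, max_nodes=8, seed=0)
        rng = np.random.default_rng(11)
        glycans = [random_glycan(cfg, rng, id=f"G{i:02d}") for i in range(10)]
        K, W = glycan_kernel(glycans, 2, method)
        assert_valid_kernel(K)
        if method == "qgram":
            assert W is None
        else:
            assert W.report.min_eig_after >= -1e-8

    def test_lk_with_identity_tables_reduces_to_plain(self):
        """Forcing the inter-q-gram similarity to identity reproduces the
        plain q-gram kernel."""
        from glyqgram.similarity import (
            BondSimilarityTable,
            LinkageTables,
            MonoSimilarityTable,
            lk_matrix,
        )

        cfg = GeneratorConfig(min_nodes=3, max_nodes=8, seed=0)
        rng = np.random.default_rng(13)
        glycans = [random_glycan(cfg, rng, id=f"G{i:02d}") for i in range(8)]
        index = build_index(glycans, 2)
        X = count_matrix(glycans, index)
        tables = LinkageTables(
            MonoSimilarityTable.identity(), BondSimilarityTable({}, [])
        )
        S = lk_matrix(index, tables)
        assert np.allclose(S.values, np.eye(index.d_q))
        K_plain = qgram_kernel(X)
        K_lk = weighted_kernel(X, psd_correct(S))
        assert np.allclose(K_plain.values, K_lk.values, atol=1e-6)
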