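import numpy as np
import pytest

from glyqgram import (
    AlignParams,
    GeneratorConfig,
    Glycan,
    GlycanError,
    build_index,
    enumerate_qgrams,
    kcam_align,
    kcam_score,
    km_matrix,
    lkm_matrix,
    random_glycan,
)
from glyqgram.kcam import qgram_as_glycan, _Aligner
from glyqgram.similarity import (
    BondSimilarityTable,
    LinkageTables,
    MonoSimilarityTable,
)

from oracles import brute_align


def _g(monos, edges, id="G"):
    return Glycan(id, monos, edges)


class TestRawAlignment:
    def test_identical_single_nodes(self):
        a = _g({1: "Gal"}, {})
        b = _g({1: "Gal"}, {})
        assert kcam_align(a, b).raw_score == 1.0

    def test_different_single_nodes(self):
        a = _g({1: "Gal"}, {})
        b = _g({1: "Man"}, {})
        assert kcam_align(a, b).raw_score == 0.0

    def test_bond_mismatch_blocks_child_match(self):
        """Exact scoring requires equal parent bonds, so only the roots of
        Gal-(b1-4)-GlcNAc vs Gal-(b1-3)-GlcNAc can match."""
        a = _g({1: "Gal", 2: "GlcNAc"}, {2: (1, "b1-4")})
        b = _g({1: "Gal", 2: "GlcNAc"}, {2: (1, "b1-3")})
        assert kcam_align(a, b).raw_score == 1.0

    def test_empty_glycan_rejected(self, chain3):
        with pytest.raises(GlycanError):
            Glycan("E", {}, {})

    def test_aligned_pairs_on_identity(self, chain3):
        result = kcam_align(chain3, chain3)
        assert sorted(result.pairs) == [(1, 1), (2, 2), (3, 3)]

    def test_monotone_in_node_score(self):
        """Raising a mono similarity entry cannot lower the raw score."""
        a = _g({1: "Gal", 2: "GlcNAc"}, {2: (1, "b1-4")})
        b = _g({1: "Glc", 2: "GlcNAc"}, {2: (1, "b1-4")})
        low = LinkageTables(MonoSimilarityTable.identity(), BondSimilarityTable.default())
        high = LinkageTables(
            MonoSimilarityTable({("Gal", "Glc"): 0.7}, ["Gal", "Glc"]),
            BondSimilarityTable.default(),
        )
        r_low = kcam_align(a, b, AlignParams(node_score="linkage", tables=low))
        r_high = kcam_align(a, b, AlignParams(node_score="linkage", tables=high))
        assert r_high.raw_score > r_low.raw_score

    def test_local_mode_finds_embedded_match(self):
        """A shared subchain hidden under mismatched roots scores fully in
        local mode."""
        a = _g({1: "Cer", 2: "Gal", 3: "GlcNAc"}, {2: (1, "b1-1"), 3: (2, "b1-3")})
        b = _g({1: "Asn", 2: "Gal", 3: "GlcNAc"}, {2: (1, "b1-1"), 3: (2, "b1-3")})
        local = kcam_align(a, b, AlignParams(mode="local"))
        assert local.raw_score >= 2.0


class TestOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_mapping_oracle(self, seed):
        """DP alignment equals brute force over all structure-preserving
        mappings on small random trees."""
        cfg = GeneratorConfig(min_nodes=2, max_nodes=6, max_depth=4, seed=seed)
        rng = np.random.default_rng(900 + seed)
        s = random_glycan(cfg, rng, id="S")
        t = random_glycan(cfg, rng, id="T")
        params = AlignParams()
        aligner = _Aligner(s, t, params)
        expected = brute_align(s, t, aligner.node_score)
        assert kcam_align(s, t, params).raw_score == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_linkage_scoring_matches_oracle(self, seed):
        cfg = GeneratorConfig(min_nodes=2, max_nodes=5, max_depth=3, seed=seed)
        rng = np.random.default_rng(1900 + seed)
        s = random_glycan(cfg, rng, id="S")
        t = random_glycan(cfg, rng, id="T")
        params = AlignParams(node_score="linkage")
        aligner = _Aligner(s, t, params)
        expected = brute_align(s, t, aligner.node_score)
        assert kcam_align(s, t, params).raw_score == pytest.approx(expected)


class TestNormalizedScore:
    def test_self_is_hundred(self, chain3, branched3):
        assert kcam_score(chain3, chain3) == 100.0
        assert kcam_score(branched3, branched3) == 100.0

    def test_label_disjoint_is_zero(self):
        a = _g({1: "Gal", 2: "Glc"}, {2: (1, "b1-4")})
        b = _g({1: "Man", 2: "Xyl"}, {2: (1, "a1-3")})
        assert kcam_score(a, b) == 0.0

    def test_symmetric_and_bounded_random_pairs(self):
        cfg = GeneratorConfig(min_nodes=3, max_nodes=10, seed=0)
        rng = np.random.default_rng(31)
        for _ in range(50):
            s = random_glycan(cfg, rng, id="S")
            t = random_glycan(cfg, rng, id="T")
            st = kcam_score(s, t)
            assert 0.0 <= st <= 100.0
            assert st == pytest.approx(kcam_score(t, s))


class TestQGramMatrices:
    def test_qgram_as_glycan_roundtrip(self, branched3):
        (qg,) = enumerate_qgrams(branched3, 3)
        tree = qgram_as_glycan(qg)
        assert tree.is_isomorphic(branched3)

    def test_km_matrix_diagonal_and_symmetry(self, chain3, branched3):
        S = km_matrix(build_index([chain3, branched3], 2))
        assert (np.diag(S.values) == 1.0).all()
        assert np.allclose(S.values, S.values.T)

    def test_km_matrix_label_disjoint_entry(self):
        a = _g({1: "Gal", 2: "Glc"}, {2: (1, "b1-4")}, id="A")
        b = _g({1: "Man", 2: "Xyl"}, {2: (1, "a1-3")}, id="B")
        S = km_matrix(build_index([a, b], 2))
        assert S.values[0, 1] == 0.0

    def test_lkm_credits_partial_bond_similarity(self):
        """b1-4 vs b1-3 2-grams: zero under exact KM, positive under LKM."""
        a = _g({1: "Gal", 2: "GlcNAc"}, {2: (1, "b1-4")}, id="A")
        b = _g({1: "Gal", 2: "GlcNAc"}, {2: (1, "b1-3")}, id="B")
        index = build_index([a, b], 2)
        km = km_matrix(index)
        lkm = lkm_matrix(index)
        assert lkm.values[0, 1] > km.values[0, 1]
        assert (lkm.values <= 1.0 + 1e-12).all()

    def test_lkm_dominates_km_when_node_scores_dominate(self):
        """On 2-grams sharing monos and layer and differing only by bonds
        with positive table similarity, linkage node scores dominate the
        exact indicator, so every LKM entry is at least the KM entry."""
        glycans = [
            _g({1: "Gal", 2: "GlcNAc"}, {2: (1, bond)}, id=bond)
            for bond in ("b1-4", "b1-3", "b1-2")
        ]
        index = build_index(glycans, 2)
        km = km_matrix(index)
        lkm = lkm_matrix(index)
        assert (lkm.values >= km.values - 1e-9).all()
        assert (lkm.values > km.values).sum() >= 6  # all off-diagonals gain

    def test_lkm_requires_linkage_scoring(self, chain3):
        with pytest.raises(GlycanError):
            lkm_matrix(build_index([chain3], 2), AlignParams(node_score="exact"))
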