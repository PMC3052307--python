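"""Block encoders: composition, BLOSUM62, PSSM pooling, ASA, SS, assembly."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from ubilys.features import (
    EncoderConfig,
    assemble,
    build_feature_matrix,
    encode_aac,
    encode_aapc,
    encode_asa,
    encode_blosum,
    encode_pssm400,
    encode_ss,
    feature_names,
)
from ubilys.seqio import AA_INDEX, AA_ORDER, ProteinRecord, ResidueProfiles, extract_fragment


class TestAAC:
    def test_single_residue_type(self):
        vec = encode_aac("AAAA")
        assert vec[AA_INDEX["A"]] == 1.0 and vec.sum() == 1.0

    def test_uniform_quartet(self):
        vec = encode_aac("ARND")
        assert all(vec[AA_INDEX[c]] == 0.25 for c in "ARND")

    def test_markers_and_unknown_excluded(self):
        np.testing.assert_array_equal(encode_aac("--AX-"), encode_aac("A"))

    def test_all_marker_rejected(self):
        with pytest.raises(ValueError):
            encode_aac("---")

    def test_matches_count_oracle(self, rng):
        seq = "".join(rng.choice(list(AA_ORDER), size=500))
        vec = encode_aac(seq)
        assert vec.sum() == pytest.approx(1.0, abs=1e-12)
        counts = {a: seq.count(a) for a in AA_ORDER}
        for a in AA_ORDER:
            assert vec[AA_INDEX[a]] == pytest.approx(counts[a] / 500)

    def test_compositionality(self, rng):
        """AAC of a concatenation is the length-weighted mean of the parts."""
        s1 = "".join(rng.choice(list(AA_ORDER), size=120))
        s2 = "".join(rng.choice(list(AA_ORDER), size=80))
        combined = encode_aac(s1 + s2)
        weighted = (120 * encode_aac(s1) + 80 * encode_aac(s2)) / 200
        np.testing.assert_allclose(combined, weighted, atol=1e-14)


class TestAAPC:
    def test_homopolymer(self):
        vec = encode_aapc("AAA")
        assert vec[AA_INDEX["A"] * 20 + AA_INDEX["A"]] == pytest.approx(2 / 3)
        assert vec.sum() == pytest.approx(2 / 3)

    def test_single_pair(self):
        vec = encode_aapc("AR")
        assert vec[AA_INDEX["A"] * 20 + AA_INDEX["R"]] == pytest.approx(1 / 2)

    def test_marker_spanning_pairs_skipped(self):
        np.testing.assert_array_equal(encode_aapc("AR-ND")[:400], encode_aapc("AR-ND"))
        vec = encode_aapc("AR-ND")
        # only AR and ND pairs; denominator is 4 effective residues
        assert vec.sum() == pytest.approx(2 / 4)

    def test_sum_identity(self, rng):
        seq = "".join(rng.choice(list(AA_ORDER), size=500))
        assert encode_aapc(seq).sum() == pytest.approx(499 / 500, abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            encode_aapc("A-")


class TestBlosum:
    def test_marker_position_is_flag_only(self):
        frag = extract_fragment(ProteinRecord("p", "KA"), 1, n=1)  # "-KA"
        vec = encode_blosum(frag).reshape(3, 21)
        assert vec[0, 20] == 1.0 and vec[0, :20].sum() == 0.0
        assert vec[1, 20] == 0.0 and vec[2, 20] == 0.0

    def test_dimension(self):
        frag = extract_fragment(ProteinRecord("p", "MKK"), 2, n=1)
        assert encode_blosum(frag).shape == (63,)

    def test_rows_match_published_matrix(self):
        """Each residue row recomputed from the published integer BLOSUM62."""
        blosum = substitution_matrices.load("BLOSUM62")
        ints = np.array([[blosum[a, b] for b in AA_ORDER] for a in AA_ORDER])
        lo, hi = ints.min(), ints.max()
        frag = extract_fragment(ProteinRecord("p", "AAMKWDE"), 4, n=2)
        vec = encode_blosum(frag).reshape(5, 21)
        for i, ch in enumerate(frag.residues):
            assert vec[i, 20] == 0.0
            expected = (ints[AA_INDEX[ch]] - lo) / (hi - lo)
            np.testing.assert_allclose(vec[i, :20], expected, atol=1e-14)
            assert vec[i, :20].max() == vec[i, AA_INDEX[ch]]  # diagonal is row max
            assert 0.0 <= vec[i, :20].min() and vec[i, :20].max() <= 1.0


class TestPssm400:
    def test_all_zero_pssm_gives_half(self):
        out = encode_pssm400(np.zeros((41, 20)), "A" * 41, 21, 41)
        np.testing.assert_array_equal(out, np.full(400, 0.5))

    def test_absent_type_row_is_half(self):
        out = encode_pssm400(np.ones((9, 20)), "AAAAKAAAA", 5, 9).reshape(20, 20)
        np.testing.assert_array_equal(out[AA_INDEX["W"]], np.full(20, 0.5))
        assert not np.allclose(out[AA_INDEX["A"]], 0.5)

    def test_matches_two_loop_oracle(self, rng):
        """Independent accumulation: loop positions, add row to its type, /m, squash."""
        for _ in range(10):
            L = 60
            seq = "".join(rng.choice(list(AA_ORDER), size=L))
            pssm = rng.integers(-10, 11, size=(L, 20)).astype(float)
            center = int(rng.integers(1, L + 1))
            m = 41
            expected = np.zeros((20, 20))
            for pos in range(center - 20, center + 21):
                if 1 <= pos <= L:
                    expected[AA_INDEX[seq[pos - 1]]] += pssm[pos - 1]
            expected = 1.0 / (1.0 + np.exp(-expected / m))
            out = encode_pssm400(pssm, seq, center, m)
            np.testing.assert_allclose(out, expected.ravel(), atol=1e-12)
            assert (out > 0).all() and (out < 1).all()

    def test_invariant_to_permuting_same_type_rows(self, rng):
        seq = "ARAAR" + "K" + "ARARA"
        pssm = rng.integers(-8, 9, size=(11, 20)).astype(float)
        out1 = encode_pssm400(pssm, seq, 6, 11)
        # swap the PSSM rows of two A positions
        swapped = pssm.copy()
        swapped[[0, 2]] = swapped[[2, 0]]
        out2 = encode_pssm400(swapped, seq, 6, 11)
        np.testing.assert_array_equal(out1, out2)

    def test_center_out_of_range(self):
        with pytest.raises(ValueError):
            encode_pssm400(np.zeros((5, 20)), "AAAAA", 6, 5)


class TestAsaSs:
    def test_asa_scaling(self):
        np.testing.assert_array_equal(
            encode_asa(np.full(10, 50.0), 5, 1), [0.5, 0.5, 0.5]
        )

    def test_asa_padding(self):
        out = encode_asa(np.full(10, 50.0), 1, 2)
        np.testing.assert_array_equal(out, [0.0, 0.0, 0.5, 0.5, 0.5])

    def test_asa_recompute(self, rng):
        asa = rng.uniform(0, 100, size=30)
        out = encode_asa(asa, 15, 5)
        assert ((0 <= out) & (out <= 1)).all()
        np.testing.assert_allclose(out, asa[9:20] / 100.0)

    def test_ss_one_hot(self):
        np.testing.assert_array_equal(
            encode_ss("HEC", 2, 1), [1, 0, 0, 0, 1, 0, 0, 0, 1]
        )

    def test_ss_out_of_range_is_zero(self):
        out = encode_ss("HEC", 1, 1).reshape(3, 3)
        np.testing.assert_array_equal(out[0], [0, 0, 0])

    def test_ss_triples_sum_to_one_in_range(self, rng):
        ss = "".join(rng.choice(list("HEC"), size=50))
        out = encode_ss(ss, 25, 10).reshape(21, 3)
        np.testing.assert_array_equal(out.sum(axis=1), np.ones(21))


class TestAssemble:
    protein = ProteinRecord("p", "MKWDEAK" * 10)

    def _profiles(self, rng):
        L = self.protein.length
        return ResidueProfiles(
            pssm=rng.integers(-5, 6, size=(L, 20)).astype(float),
            asa=rng.uniform(0, 100, size=L),
            ss="".join(rng.choice(list("HEC"), size=L)),
        )

    def test_aac_pssm_dimension(self, rng):
        frag = extract_fragment(self.protein, 2, 20, "positive")
        fv = assemble(frag, self._profiles(rng), EncoderConfig(n=20, blocks=("AAC", "PSSM400")), self.protein)
        assert len(fv.values) == 420
        assert [b[0] for b in fv.blocks] == ["AAC", "PSSM400"]

    def test_composition_pair_dimension(self, rng):
        frag = extract_fragment(self.protein, 2, 20, "positive")
        fv = assemble(frag, None, EncoderConfig(n=20, blocks=("AAC", "AAPC")), self.protein)
        assert len(fv.values) == 420

    def test_full_dimension_at_n20(self, rng):
        frag = extract_fragment(self.protein, 30, 20, "positive")
        config = EncoderConfig(n=20, blocks=("AAC", "AAPC", "BLOSUM", "PSSM400", "ASA", "SS"))
        fv = assemble(frag, self._profiles(rng), config, self.protein)
        assert len(fv.values) == 20 + 400 + 861 + 400 + 41 + 123 == 1845
        assert len(feature_names(config)) == 1845

    def test_missing_profile_rejected(self):
        frag = extract_fragment(self.protein, 2, 5, "positive")
        with pytest.raises(ValueError, match="ASA"):
            assemble(frag, ResidueProfiles(), EncoderConfig(n=5, blocks=("ASA",)), self.protein)

    def test_deterministic(self, rng):
        frag = extract_fragment(self.protein, 30, 10, "positive")
        profiles = self._profiles(rng)
        config = EncoderConfig(n=10, blocks=("AAC", "BLOSUM", "PSSM400"))
        a = assemble(frag, profiles, config, self.protein)
        b = assemble(frag, profiles, config, self.protein)
        np.testing.assert_array_equal(a.values, b.values)

    def test_build_matrix_columns_match_names(self, small_dataset):
        config = EncoderConfig(n=5, blocks=("AAC", "ASA", "SS"))
        X, labels, names, prov = build_feature_matrix(
            small_dataset.proteins, small_dataset.sites, small_dataset.profiles, config
        )
        assert X.shape == (len(small_dataset.sites), len(names))
        assert set(labels) == {"positive", "negative"}
        assert prov[0].count(":") == 1
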