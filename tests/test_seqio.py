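"""Sequence, annotation and profile I/O round-trips and validation."""

import numpy as np
import pytest

from ubilys import seqio
from ubilys.seqio import (
    FormatError,
    ProteinRecord,
    SiteAnnotation,
    enumerate_negative_sites,
    extract_fragment,
    read_asa_profile,
    read_fasta,
    read_pssm_profile,
    read_site_annotations,
    read_ss_profile,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestFasta:
    def test_single_record(self, tmp_path):
        p = _write(tmp_path, "a.fasta", ">p1\nMKKA\n")
        recs = read_fasta(p)
        assert len(recs) == 1
        assert recs[0].id == "p1" and recs[0].sequence == "MKKA"
        assert recs[0].length == 4

    def test_order_preserved_and_uppercased(self, tmp_path):
        p = _write(tmp_path, "a.fasta", ">p1\nmk ka\n>p2\nAR\nND\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["p1", "p2"]
        assert recs[0].sequence == "MKKA"
        assert recs[1].sequence == "ARND"

    def test_empty_file_errors(self, tmp_path):
        p = _write(tmp_path, "a.fasta", "")
        with pytest.raises(FormatError):
            read_fasta(p)

    @pytest.mark.parametrize("bad", list("BJOUZ*1"))
    def test_illegal_residue_named_with_offset(self, tmp_path, bad):
        p = _write(tmp_path, "a.fasta", f">p1\nMK{bad}A\n")
        with pytest.raises(FormatError, match="p1"):
            read_fasta(p)

    def test_roundtrip(self, tmp_path, rng):
        seqs = [
            ProteinRecord(f"p{i}", "".join(rng.choice(list(seqio.AA_ORDER), size=80)))
            for i in range(5)
        ]
        path = tmp_path / "rt.fasta"
        seqio.write_fasta(seqs, path)
        assert read_fasta(path) == seqs


class TestSiteAnnotations:
    proteins = [ProteinRecord("p1", "MKKA")]

    def test_valid_row_accepted(self, tmp_path):
        p = _write(tmp_path, "s.tsv", "p1\t2\tpositive\n")
        sites = read_site_annotations(p, self.proteins)
        assert sites == [SiteAnnotation("p1", 2, "positive")]

    @pytest.mark.parametrize(
        "row,msg",
        [
            ("p1\t1\tpositive", "expected K"),  # M at position 1
            ("p1\t9\tpositive", "outside"),
            ("pX\t2\tpositive", "unknown protein"),
        ],
    )
    def test_invalid_rows_rejected(self, tmp_path, row, msg):
        p = _write(tmp_path, "s.tsv", row + "\n")
        with pytest.raises(FormatError, match=msg):
            read_site_annotations(p, self.proteins)

    def test_random_rows_roundtrip(self, tmp_path, rng):
        proteins = []
        rows = []
        for i in range(20):
            seq = "".join(rng.choice(list(seqio.AA_ORDER), size=100))
            prot = ProteinRecord(f"p{i}", seq)
            proteins.append(prot)
            for pos in (j + 1 for j, ch in enumerate(seq) if ch == "K"):
                rows.append(SiteAnnotation(prot.id, pos, "positive" if rng.random() < 0.5 else "negative"))
        assert len(rows) >= 50
        path = tmp_path / "rt.tsv"
        seqio.write_site_annotations(rows, path)
        assert read_site_annotations(path, proteins) == rows


class TestNegativeEnumeration:
    def test_remaining_lysines(self):
        prot = ProteinRecord("p1", "MKKA")
        negs = enumerate_negative_sites(prot, [SiteAnnotation("p1", 2, "positive")])
        assert negs == [SiteAnnotation("p1", 3, "negative")]

    def test_no_lysine_protein(self):
        assert enumerate_negative_sites(ProteinRecord("p1", "MAAR"), []) == []

    def test_partition_covers_all_lysines(self, rng):
        seq = "".join(rng.choice(list(seqio.AA_ORDER), size=200))
        prot = ProteinRecord("p1", seq)
        k_positions = [i + 1 for i, ch in enumerate(seq) if ch == "K"]
        chosen = [SiteAnnotation("p1", p, "positive") for p in k_positions[::2]]
        negs = enumerate_negative_sites(prot, chosen)
        assert len(chosen) + len(negs) == seq.count("K")
        assert {s.position for s in chosen}.isdisjoint({s.position for s in negs})


class TestFragments:
    def test_small_window(self):
        frag = extract_fragment(ProteinRecord("p1", "MKKA"), 2, n=1)
        assert frag.residues == "MKK"

    def test_terminal_padding(self):
        frag = extract_fragment(ProteinRecord("p1", "MKKA"), 2, n=3)
        assert frag.residues == "--MKKA-"

    def test_non_lysine_center_rejected(self):
        with pytest.raises(ValueError, match="centred on K"):
            extract_fragment(ProteinRecord("p1", "MKKA"), 1, n=1)

    def test_all_lysines_yield_41mers(self, rng):
        seq = "".join(rng.choice(list(seqio.AA_ORDER), size=100))
        prot = ProteinRecord("p1", seq)
        for pos in (i + 1 for i, ch in enumerate(seq) if ch == "K"):
            frag = extract_fragment(prot, pos, n=20)
            assert len(frag.residues) == 41
            assert frag.residues[20] == "K"
            core = frag.residues.strip("-")
            assert "-" not in core  # markers only at the flanks


PSIBLAST_TEXT = """
Last position-specific scoring matrix computed, weight observed
           A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
    1 M   -1 -2 -3 -4  5  0 -1 -2 -3  1  2 -1  6 -2 -3 -1 -1 -2 -1  1   0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0
    2 K   -1  2  0 -1 -3  1  1 -2 -1 -3 -2  5 -1 -3 -1  0 -1 -3 -2 -2   0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0

                      K         Lambda
Standard Ungapped    0.13       0.31
"""


class TestPssmProfiles:
    def test_tsv_roundtrip_identity(self, tmp_path, rng):
        mat = rng.integers(-10, 11, size=(30, 20)).astype(float)
        path = tmp_path / "m.pssm.tsv"
        seqio.write_pssm_profile(mat, path)
        np.testing.assert_array_equal(read_pssm_profile(path, "tsv"), mat)

    def test_length_mismatch_rejected(self, tmp_path, rng):
        mat = rng.integers(-5, 6, size=(3, 20)).astype(float)
        path = tmp_path / "m.pssm.tsv"
        seqio.write_pssm_profile(mat, path)
        with pytest.raises(FormatError, match="length"):
            read_pssm_profile(path, "tsv", protein=ProteinRecord("p1", "MKKA"))

    def test_psiblast_ascii_dialect(self, tmp_path):
        path = _write(tmp_path, "p.pssm", PSIBLAST_TEXT)
        mat = read_pssm_profile(path, "psiblast_ascii")
        assert mat.shape == (2, 20)
        # row 1 is the M row: A column −1, M column +6
        assert mat[0, 0] == -1 and mat[0, seqio.AA_INDEX["M"]] == 6
        assert mat[1, seqio.AA_INDEX["K"]] == 5

    def test_malformed_line_rejected(self, tmp_path):
        path = _write(tmp_path, "m.pssm.tsv", "1 2 3\n")
        with pytest.raises(FormatError):
            read_pssm_profile(path, "tsv")


class TestAsaSsProfiles:
    def test_asa_values(self, tmp_path):
        path = _write(tmp_path, "a.asa", "55.2 12.0 90.0\n")
        np.testing.assert_allclose(read_asa_profile(path), [55.2, 12.0, 90.0])

    def test_asa_out_of_range(self, tmp_path):
        path = _write(tmp_path, "a.asa", "55.2 120.0\n")
        with pytest.raises(FormatError, match="outside"):
            read_asa_profile(path)

    def test_asa_roundtrip(self, tmp_path, rng):
        asa = rng.uniform(0, 100, size=50)
        path = tmp_path / "a.asa"
        seqio.write_asa_profile(asa, path)
        np.testing.assert_array_equal(read_asa_profile(path), asa)

    def test_ss_plain_and_ss2(self, tmp_path):
        plain = _write(tmp_path, "a.ss", "HEC\n")
        assert read_ss_profile(plain) == "HEC"
        ss2 = _write(tmp_path, "a.ss2", "1 M H 0.9 0.0 0.1\n2 K C 0.1 0.0 0.9\n")
        assert read_ss_profile(ss2) == "HC"

    def test_illegal_symbol(self, tmp_path):
        path = _write(tmp_path, "a.ss", "HEG\n")
        with pytest.raises(FormatError, match="illegal"):
            read_ss_profile(path)

    def test_length_mismatch(self, tmp_path):
        path = _write(tmp_path, "a.ss", "HE\n")
        with pytest.raises(FormatError):
            read_ss_profile(path, protein=ProteinRecord("p1", "MKKA"))
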