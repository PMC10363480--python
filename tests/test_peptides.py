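"""Peptide model, FASTA round trips, element extraction, construct grammar."""

import pytest
from hypothesis import given, settings, strategies as st

from peptarget import (
    BasicSubstitution,
    BasicVariant,
    CElement,
    NElement,
    Peptide,
    PeptideError,
    PeptideSet,
    Role,
    assemble_construct,
    extract_c_element,
    extract_n_element,
    format_construct_code,
    load_peptides,
    parse_construct_code,
    spec_for_cell,
    substitute_basic,
    write_peptides,
)
from peptarget.peptides import COLUMN_CORES, ROW_SIGNATURES
from peptarget.scales import ALPHABET

peptide_seq = st.text(alphabet=ALPHABET, min_size=1, max_size=60)


class TestPeptideModel:
    def test_rejects_non_alphabet_residue_with_position(self):
        with pytest.raises(PeptideError, match="position 3"):
            Peptide("p1", "ACB")  # B is not an amino-acid code

    def test_rejects_out_of_range_cleavage(self):
        with pytest.raises(PeptideError, match="cleavage_index"):
            Peptide("p1", "ACDEF", cleavage_index=6)

    def test_duplicate_ids_rejected(self):
        pset = PeptideSet("s", [Peptide("a", "ACD")])
        with pytest.raises(PeptideError, match="duplicate"):
            pset.add(Peptide("a", "ACD"))


class TestFastaIO:
    def test_single_record_parse(self, tmp_path):
        fasta = tmp_path / "one.fasta"
        fasta.write_text(">p1 role=HA_RAMP\nGIGKFLK\n")
        pset = load_peptides(fasta)
        assert len(pset) == 1
        assert pset["p1"].sequence == "GIGKFLK"
        assert pset["p1"].role is Role.HA_RAMP

    def test_study_fixture_has_17_records(self, library):
        assert len(library) == 17
        roles = [p.role for p in library]
        assert roles.count(Role.HA_RAMP) == 13
        assert roles.count(Role.CTP) == 1
        assert roles.count(Role.MTP) == 1
        assert roles.count(Role.RANDOM) == 2
        assert library["RCA1-cTP"].cleavage_index is not None
        assert library["CAG2-mTP"].cleavage_index is not None

    def test_non_alphabet_character_names_record_and_position(self, tmp_path):
        fasta = tmp_path / "bad.fasta"
        fasta.write_text(">bad\nACB1Z\n")
        with pytest.raises(PeptideError, match="bad.*position 3"):
            load_peptides(fasta)

    def test_write_load_round_trip(self, library, tmp_path):
        out = tmp_path / "roundtrip.fasta"
        write_peptides(library, out)
        back = load_peptides(out)
        assert back.ids == library.ids
        for p, q in zip(library, back):
            assert (p.sequence, p.role, p.cleavage_index, p.family) == (
                q.sequence, q.role, q.cleavage_index, q.family)


class TestBasicSubstitution:
    @pytest.mark.parametrize("seq,direction,expected", [
        ("GIGKFLK", BasicSubstitution.K_TO_R, "GIGRFLR"),
        ("AAAA", BasicSubstitution.K_TO_R, "AAAA"),
        ("RRKR", BasicSubstitution.R_TO_K, "KKKK"),
    ])
    def test_examples(self, seq, direction, expected):
        assert substitute_basic(Peptide("p", seq), direction).sequence == expected

    @settings(derandomize=True, max_examples=100)
    @given(seq=peptide_seq)
    def test_substitution_removes_source_and_preserves_length(self, seq):
        p = Peptide("p", seq)
        out = substitute_basic(p, BasicSubstitution.K_TO_R)
        assert out.sequence.count("K") == 0
        assert len(out) == len(p)
        # K->R then R->K sends every original K and R to K (not an involution)
        back = substitute_basic(out, BasicSubstitution.R_TO_K)
        assert back.sequence.count("R") == 0
        assert back.sequence == seq.replace("R", "K")

    @settings(derandomize=True, max_examples=50)
    @given(seq=peptide_seq)
    def test_idempotent_per_direction(self, seq):
        p = Peptide("p", seq)
        once = substitute_basic(p, BasicSubstitution.K_TO_R)
        twice = substitute_basic(once, BasicSubstitution.K_TO_R)
        assert once.sequence == twice.sequence


class TestElementExtraction:
    def test_n_element_is_prefix(self):
        p = Peptide("p", "ACDEFGHIKLMNPQRSTV")
        elem = extract_n_element(p, 15)
        assert elem.sequence == p.sequence[:15]

    def test_n_element_rejects_bad_n(self):
        p = Peptide("p", "ACDEFGHIKLMNPQRSTV")
        with pytest.raises(PeptideError):
            extract_n_element(p, 0)
        with pytest.raises(PeptideError):
            extract_n_element(Peptide("q", "ACD"), 15)

    def test_c_element_index_arithmetic(self):
        seq = "".join("ACDEFGHIKL"[i % 10] for i in range(70))
        p = Peptide("p", seq, cleavage_index=36)
        elem = extract_c_element(p)
        assert len(elem) == 33
        assert elem.sequence == seq[26:59]  # residues 27..59, 1-based
        assert elem.cleavage_index == 10

    def test_c_element_peptidase_recognition_region(self):
        seq = "A" * 50
        p = Peptide("p", seq, cleavage_index=30)
        elem = extract_c_element(p, upstream=10, downstream=0)
        assert len(elem) == 10

    def test_c_element_requires_enough_upstream(self):
        p = Peptide("p", "A" * 50, cleavage_index=5)
        with pytest.raises(PeptideError, match="upstream"):
            extract_c_element(p, upstream=10)

    def test_c_element_requires_cleavage_index(self):
        with pytest.raises(PeptideError, match="cleavage_index"):
            extract_c_element(Peptide("p", "A" * 50))


class TestConstructCode:
    @pytest.mark.parametrize("code,core,variant,n_elem,c_elem", [
        ("^cB2I_R^m", "B2I", BasicVariant.R, NElement.CTP_N, CElement.MTP_C),
        ("MH_R^c", "MH", BasicVariant.R, NElement.NONE, CElement.CTP_C),
        ("B2I_K", "B2I", BasicVariant.K, NElement.NONE, CElement.NONE),
        ("^c-^c", "-", BasicVariant.NATIVE, NElement.CTP_N, CElement.CTP_C),
    ])
    def test_parse_examples(self, code, core, variant, n_elem, c_elem):
        spec = parse_construct_code(code)
        assert (spec.core_id, spec.basic_variant, spec.n_element,
                spec.c_element) == (core, variant, n_elem, c_elem)

    def test_malformed_code_rejected(self):
        with pytest.raises(PeptideError, match="B2I\\^q"):
            parse_construct_code("B2I^q")

    def test_round_trip_on_all_grid_cells(self):
        for row in ROW_SIGNATURES:
            for col in "abcdefghijklm":
                spec = spec_for_cell(row, col)
                code = format_construct_code(spec)
                back = parse_construct_code(code)
                assert back == spec
                assert back.row == row and back.column == col


class TestAssembly:
    def test_native_construct_is_core_identity(self, library):
        spec = spec_for_cell("A", "a")  # B2I_K: all basics already K
        built = assemble_construct(spec, library)
        assert built.sequence == library["B2I"].sequence.replace("R", "K")

    def test_core_substitution_and_c_element(self, library):
        built = assemble_construct(parse_construct_code("MII_R^m"), library)
        mtp_c = extract_c_element(library["CAG2-mTP"]).sequence
        core = library["MII"].sequence.replace("K", "R")
        assert built.sequence == core + mtp_c
        assert built.cleavage_index == len(built) - 23

    def test_no_core_concatenation_length(self, library):
        built = assemble_construct(parse_construct_code("^c-^c"), library)
        assert len(built) == 15 + 33

    def test_full_tp_reconstruction(self, library):
        """cTP-N + CH + cTP-C stitches the original preprotein region back."""
        ctp = library["RCA1-cTP"]
        built = assemble_construct(parse_construct_code("^cCH_R^c"), library)
        assert built.sequence == ctp.sequence[: ctp.cleavage_index + 23]
        mtp = library["CAG2-mTP"]
        built_m = assemble_construct(parse_construct_code("MH_R^m"), library)
        assert built_m.sequence == mtp.sequence[: mtp.cleavage_index + 23]

    def test_polyalanine_matches_helix_length(self, library):
        aa = assemble_construct(parse_construct_code("^cAA^c"), library)
        ch = assemble_construct(parse_construct_code("^cCH_R^c"), library)
        assert len(aa) == len(ch)
        core = aa.sequence[15:-33]
        assert set(core) == {"A"}

    def test_length_is_sum_of_elements(self, library):
        for code in ("^cB2I_R^m", "B15_K^c", "^cSIM_R", "EHF_R"):
            spec = parse_construct_code(code)
            built = assemble_construct(spec, library)
            expected = len(library[spec.core_id])
            if spec.n_element is not NElement.NONE:
                expected += 15
            if spec.c_element is not CElement.NONE:
                expected += 33
            assert len(built) == expected
            assert set(built.sequence) <= set(ALPHABET)
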