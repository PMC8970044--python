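"""Mass engine: peptide/glycan masses, fragment ions, classification."""

import csv

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoprm.chem import (
    CARBAMIDOMETHYL,
    MONOSACCHARIDE_MASSES,
    PROTON,
    WATER,
    GlycanComposition,
    Glycopeptide,
    b_y_ladders,
    classify_glycoform,
    constants_table_path,
    glycan_mass,
    oxonium_ions,
    peptide_mass,
    y_ion_series,
)

compositions = st.builds(
    GlycanComposition,
    hexnac=st.integers(0, 8),
    hex=st.integers(0, 10),
    fuc=st.integers(0, 4),
    neuac=st.integers(0, 4),
)


class TestPeptideMass:
    @pytest.mark.parametrize(
        "seq,mods,expected",
        [
            ("G", None, 75.03203),  # glycine + water
            ("ELHHLQEQNVSNAFLDK", None, 2020.9966),
            ("C", {"C": CARBAMIDOMETHYL}, 178.04122),  # residue + water + CAM
        ],
    )
    def test_known_masses(self, seq, mods, expected):
        assert peptide_mass(seq, mods) == pytest.approx(expected, abs=5e-4)

    def test_unknown_residue_names_character_and_position(self):
        with pytest.raises(ValueError, match=r"'Z' at position 3"):
            peptide_mass("PEZTIDE")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            peptide_mass("")

    def test_variable_mods_add_deltas(self):
        base = peptide_mass("PEPTIDEM")
        oxidized = peptide_mass("PEPTIDEM", variable_mods=[(8, 15.994915)])
        assert oxidized - base == pytest.approx(15.994915, abs=1e-9)

    def test_variable_mod_position_out_of_range(self):
        with pytest.raises(ValueError, match="position 9"):
            peptide_mass("PEPTIDE", variable_mods=[(9, 1.0)])


class TestGlycanComposition:
    def test_monosaccharide_table_values(self):
        assert MONOSACCHARIDE_MASSES["HexNAc"] == pytest.approx(203.0794, abs=1e-4)
        assert MONOSACCHARIDE_MASSES["Hex"] == pytest.approx(162.0528, abs=1e-4)
        assert MONOSACCHARIDE_MASSES["Fuc"] == pytest.approx(146.0579, abs=1e-4)
        assert MONOSACCHARIDE_MASSES["NeuAc"] == pytest.approx(291.0954, abs=1e-4)
        assert set(MONOSACCHARIDE_MASSES) == {"HexNAc", "Hex", "Fuc", "NeuAc"}

    @pytest.mark.parametrize(
        "comp,expected",
        [
            (GlycanComposition(), 0.0),
            (GlycanComposition(1, 1, 1, 0), 511.1901),
            (GlycanComposition(5, 6, 2, 3), 3153.1159),
        ],
    )
    def test_masses(self, comp, expected):
        assert glycan_mass(comp) == pytest.approx(expected, abs=5e-4)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            GlycanComposition(hexnac=-1)

    def test_parse_canonical_string(self):
        c = GlycanComposition.parse("HexNAc(5)Hex(6)Fuc(2)NeuAc(3)")
        assert (c.hexnac, c.hex, c.fuc, c.neuac) == (5, 6, 2, 3)

    def test_parse_accepts_caption_synonyms(self):
        # HexNac casing and Gal/Glc/Man as Hex isomers
        c = GlycanComposition.parse("HexNac(1)Gal(1)Fuc(1)")
        assert c == GlycanComposition(1, 1, 1, 0)

    def test_parse_rejects_unknown_monosaccharide(self):
        with pytest.raises(ValueError, match="Xyl"):
            GlycanComposition.parse("Xyl(2)")

    def test_parse_rejects_garbage(self):
        with pytest.raises(ValueError):
            GlycanComposition.parse("HexNAc(2)junk")

    @settings(deadline=None, max_examples=200)
    @given(compositions)
    def test_string_round_trip(self, comp):
        assert GlycanComposition.parse(str(comp)) == comp

    @settings(deadline=None, max_examples=200)
    @given(compositions, compositions)
    def test_mass_linearity(self, a, b):
        assert glycan_mass(a) + glycan_mass(b) == pytest.approx(
            glycan_mass(a + b), abs=1e-9
        )


class TestOxoniumIons:
    ALL_EIGHT = [138.05, 168.05, 204.09, 274.09, 292.10, 366.14, 512.20, 657.23]

    def test_full_composition_reproduces_published_table(self):
        ions = oxonium_ions(GlycanComposition(1, 1, 1, 1))
        assert sorted(round(i.mz, 2) for i in ions) == sorted(self.ALL_EIGHT)

    def test_absent_monosaccharides_suppress_their_ions(self):
        ions = {round(i.mz, 2) for i in oxonium_ions(GlycanComposition(2, 3, 0, 0))}
        assert not ions & {512.20, 292.10, 274.09, 657.23}
        assert {138.05, 168.05, 204.09, 366.14} <= ions

    def test_hexnac_only(self):
        ions = {round(i.mz, 2) for i in oxonium_ions(GlycanComposition(1, 0, 0, 0))}
        assert ions == {138.05, 168.05, 204.09}

    def test_all_singly_charged(self):
        assert all(i.charge == 1 for i in oxonium_ions(GlycanComposition(2, 2, 1, 1)))

    def test_mz_consistency_invariant(self):
        for ion in oxonium_ions(GlycanComposition(2, 2, 1, 1)):
            assert ion.mz == pytest.approx(
                (ion.neutral_mass + ion.charge * PROTON) / ion.charge, abs=1e-6
            )


class TestYIonSeries:
    def test_headline_core_fucose_diagnostics(self, headline_gp):
        mz = {(i.label, i.charge): i.mz for i in y_ion_series(headline_gp, 2)}
        assert round(mz[("pep+2HexNAc+Fuc", 2)], 2) == 1287.61
        # theoretical 1186.07; the annotated spectral peak 1186.08 is
        # matched within observed-peak rounding of ±0.01
        assert mz[("pep+HexNAc+Fuc", 2)] == pytest.approx(1186.08, abs=0.01)

    def test_no_fucose_no_fuc_ions(self):
        gp = Glycopeptide("PEPTIDEK", 1, GlycanComposition(4, 5, 0, 2))
        labels = {i.label for i in y_ion_series(gp)}
        assert not any("Fuc" in lab for lab in labels)
        assert {"pep", "pep+HexNAc", "pep+2HexNAc"} == labels

    def test_hexnac_free_composition_gives_only_y0(self):
        gp = Glycopeptide("PEPTIDEK", 1, GlycanComposition(0, 0, 0, 0))
        assert {i.label for i in y_ion_series(gp)} == {"pep"}

    def test_charge_reduction_relation(self, headline_gp):
        ions = y_ion_series(headline_gp, 2)
        by_label = {}
        for i in ions:
            by_label.setdefault(i.label, {})[i.charge] = i.mz
        for charges in by_label.values():
            assert charges[2] == pytest.approx((charges[1] + PROTON) / 2, abs=1e-9)


class TestBYLadders:
    def test_b_y_masses_match_independent_oracle(self):
        # oracle: pyteomics fast_mass on each prefix/suffix
        from pyteomics import mass as pt

        seq = "PEPTIDE"
        ions = {(i.label, i.charge): i.mz for i in b_y_ladders(sequence=seq)}
        for i in range(1, len(seq)):
            b_expect = pt.fast_mass(seq[:i], ion_type="b", charge=1)
            y_expect = pt.fast_mass(seq[i:], ion_type="y", charge=1)
            assert ions[(f"b{i}", 1)] == pytest.approx(b_expect, abs=1e-3)
            assert ions[(f"y{len(seq) - i}", 1)] == pytest.approx(y_expect, abs=1e-3)


class TestClassifyGlycoform:
    @pytest.mark.parametrize(
        "comp,antennarity,fuc,sia",
        [
            ("HexNAc(5)Hex(6)Fuc(2)NeuAc(3)", "tri", 2, 3),
            ("HexNAc(4)Hex(5)NeuAc(2)", "bi", 0, 2),
            ("HexNAc(6)Hex(7)Fuc(1)NeuAc(4)", "tetra", 1, 4),
            ("HexNAc(3)Hex(4)", "other", 0, 0),
        ],
    )
    def test_antennarity_rule(self, comp, antennarity, fuc, sia):
        cls = classify_glycoform(GlycanComposition.parse(comp))
        assert cls.antennarity == antennarity
        assert cls.fucose_count == fuc
        assert cls.sialyl_count == sia
        assert not cls.below_complex_type

    def test_high_mannose_like_flagged_not_failed(self):
        cls = classify_glycoform(GlycanComposition.parse("HexNAc(2)Hex(5)"))
        assert cls.antennarity == "other"
        assert cls.below_complex_type


def test_constants_csv_ships_flagged_literals():
    with open(constants_table_path()) as fh:
        rows = list(csv.DictReader(fh))
    by_name = {r["name"]: r for r in rows}
    assert float(by_name["HexNAc"]["value_da"]) == pytest.approx(203.079373)
    assert by_name["HexNAc_frag_168"]["source"] == "published_literal"
    assert "168.066" in by_name["HexNAc_frag_168"]["note"]
    assert float(by_name["water"]["value_da"]) == WATER
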