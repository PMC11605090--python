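import pytest

from eadlipid.lipids import (
    AnnotationLevel,
    IN_DEPTH_SUBCLASSES,
    LipidParseError,
    LipidStructure,
    parse_lipid_name,
)


def test_pc_precursor_and_formula():
    s = parse_lipid_name("PC 16:0/18:1(9)")
    assert s.neutral_formula().hill() == "C42H82NO8P"
    assert s.precursor_mz("[M+H]+") == pytest.approx(760.5851, abs=2e-4)


def test_dlpc_and_papc_are_isobaric():
    dlpc = parse_lipid_name("PC 18:2(9,12)/18:2(9,12)")
    papc = parse_lipid_name("PC 16:0/20:4(5,8,11,14)")
    assert dlpc.precursor_mz("[M+H]+") == pytest.approx(782.5694, abs=2e-4)
    assert dlpc.precursor_mz("[M+H]+") == pytest.approx(
        papc.precursor_mz("[M+H]+"), abs=1e-9
    )


def test_species_level_formula_matches_resolved():
    resolved = parse_lipid_name("PC 16:0/18:1(9)")
    species = parse_lipid_name("PC 34:1")
    assert species.is_species_level
    assert species.neutral_formula().hill() == resolved.neutral_formula().hill()


def test_sphingomyelin_formula():
    sm = parse_lipid_name("SM 18:1(4);(1OH,3OH)/16:0")
    assert sm.neutral_formula().hill() == "C39H79N2O6P"
    assert parse_lipid_name("SM 34:1;O2").neutral_formula().hill() == "C39H79N2O6P"


def test_ceramide_species_formula_counts_amide_oxygens():
    assert parse_lipid_name("Cer 34:1;O2").neutral_formula().hill() == "C34H67NO3"


def test_levels():
    assert parse_lipid_name("PC 34:1").level is AnnotationLevel.SPECIES
    assert parse_lipid_name("PC 16:0_18:1").level is AnnotationLevel.MOLECULAR_SPECIES
    assert parse_lipid_name("PC 16:0/18:1").level is AnnotationLevel.SN_RESOLVED
    assert parse_lipid_name("PC 16:0_18:1(9)").level is AnnotationLevel.DB_RESOLVED
    assert parse_lipid_name("PC 16:0/18:1(9)").level is AnnotationLevel.SN_DB_RESOLVED


def test_ether_display_name():
    s = parse_lipid_name("PC O-16:0/18:1(9)")
    assert s.subclass_display() == "PC O-"
    assert s.is_ether


def test_lyso_parsing():
    s = parse_lipid_name("LPC 18:1(9)/0:0")
    assert s.chains[1] is None and s.sn_assigned
    s2 = parse_lipid_name("LPC 0:0/18:1(9)")
    assert s2.chains[0] is None


def test_adduct_shift_sodium():
    s = parse_lipid_name("PC 16:0/18:1(9)")
    assert s.precursor_mz("[M+Na]+") - s.precursor_mz("[M+H]+") == pytest.approx(
        21.98194, abs=1e-4
    )


def test_format_roundtrip():
    for name in (
        "PC 16:0/18:1(9)",
        "PE 16:0_20:4",
        "SM 18:1(4);(1OH,3OH)/16:0",
        "TG 16:0/18:1(9)/20:4(5,8,11,14)",
        "LPC 0:0/18:1",
        "CAR 18:1(9)",
        "PC O-16:0/18:1(9)",
        "PC 34:1",
    ):
        assert parse_lipid_name(name).format() == name


def test_mixed_separators_rejected():
    with pytest.raises(LipidParseError):
        parse_lipid_name("TG 16:0/18:1_20:4")


def test_unknown_subclass_rejected():
    with pytest.raises(LipidParseError):
        parse_lipid_name("XX 16:0/18:1")


def test_in_depth_subclass_count():
    assert len(IN_DEPTH_SUBCLASSES) == 27


def test_bmp_pg_isomeric():
    pg = parse_lipid_name("PG 18:1(9)/18:1(9)")
    bmp = parse_lipid_name("BMP 18:1(9)/18:1(9)")
    assert pg.neutral_formula().hill() == bmp.neutral_formula().hill()
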