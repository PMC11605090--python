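import pytest

from eadlipid.chains import AcylChain
from eadlipid.fragmentation import (
    AbundanceClass,
    FragmentationError,
    Series,
    build_insilico_spectrum,
    classify_abundance,
    crf_fragment_mz,
    crf_ions,
    diagnostic_plan,
)
from eadlipid.elements import H_ATOM_MASS
from eadlipid.lipids import parse_lipid_name

DLPC = parse_lipid_name("PC 18:2(9,12)/18:2(9,12)")
PAPC = parse_lipid_name("PC 16:0/20:4(5,8,11,14)")
POPC9 = parse_lipid_name("PC 16:0/18:1(9)")


def test_crf_series_spacing():
    r = crf_fragment_mz(DLPC, "[M+H]+", 0, 10, "radical")
    assert crf_fragment_mz(DLPC, "[M+H]+", 0, 10, "H-loss") == pytest.approx(
        r - H_ATOM_MASS
    )
    assert crf_fragment_mz(DLPC, "[M+H]+", 0, 10, "H-gain") == pytest.approx(
        r + H_ATOM_MASS
    )


def test_crf_printed_values():
    assert crf_fragment_mz(DLPC, "[M+H]+", 0, 14, "radical") == pytest.approx(
        725.499, abs=5e-4
    )
    assert crf_fragment_mz(DLPC, "[M+H]+", 0, 7, "H-loss") == pytest.approx(
        630.413, abs=5e-4
    )
    assert crf_fragment_mz(PAPC, "[M+H]+", 1, 6, "H-gain") == pytest.approx(
        592.397, abs=5e-4
    )


def test_crf_double_bond_counting_spans_cleavage():
    # at k=9 the delta-9 bond spans the cleavage and belongs to the loss
    v9 = crf_fragment_mz(POPC9, "[M+H]+", 1, 9, "H-loss")
    assert v9 == pytest.approx(634.4442, abs=5e-5)
    # crossing the bond (k=9 -> 10) shifts by a bare carbon: the lost part
    # drops one C but regains the two H the double bond had removed
    v10 = crf_fragment_mz(POPC9, "[M+H]+", 1, 10, "H-loss")
    assert v10 - v9 == pytest.approx(12.0, abs=1e-6)
    # away from the bond consecutive cleavages differ by CH2
    v11 = crf_fragment_mz(POPC9, "[M+H]+", 1, 11, "H-loss")
    assert v11 - v10 == pytest.approx(12.0 + 2 * H_ATOM_MASS, abs=1e-6)


def test_crf_requires_resolved_chain():
    with pytest.raises(FragmentationError):
        crf_fragment_mz(parse_lipid_name("PC 16:0/18:1"), "[M+H]+", 1, 9,
                        "radical")


def test_crf_position_bounds():
    with pytest.raises(FragmentationError):
        crf_fragment_mz(POPC9, "[M+H]+", 1, 18, "radical")


def test_classify_mufa():
    labels = classify_abundance(AcylChain.parse("18:1(9)"))
    assert labels[(9, Series.H_LOSS)] is AbundanceClass.CC_LOW
    assert labels[(9, Series.RADICAL)] is AbundanceClass.CC_LOW
    assert labels[(7, Series.H_LOSS)] is AbundanceClass.CC_HIGH_HLOSS
    assert labels[(11, Series.RADICAL)] is AbundanceClass.CC_HIGH_RADICAL
    assert labels[(5, Series.H_LOSS)] is AbundanceClass.PLAIN
    # no PUFA behaviour below 3 double bonds
    assert all(v is not AbundanceClass.CC_PUFA_HIGH for v in labels.values())


def test_classify_pufa_hgain():
    labels = classify_abundance(AcylChain.parse("20:4(5,8,11,14)"))
    for k in (6, 9, 12):
        assert labels[(k, Series.H_GAIN)] is AbundanceClass.CC_PUFA_HIGH
    assert labels[(15, Series.H_GAIN)] is AbundanceClass.PLAIN


def test_expected_cc_high_sets_match_printed_lists():
    ins = build_insilico_spectrum(DLPC, "[M+H]+")
    highs = sorted({round(p.mz, 3) for p in ins.expected_cc_high()})
    assert highs == [630.413, 670.444, 685.468, 725.499]
    ins2 = build_insilico_spectrum(PAPC, "[M+H]+")
    highs2 = {round(p.mz, 3) for p in ins2.expected_cc_high()}
    for v in (550.350, 590.382, 605.405, 645.436, 685.468, 725.499,
              592.397, 632.429):
        assert v in highs2


def test_crf_ion_count_and_cutoff():
    ions = crf_ions(POPC9, "[M+H]+", low_mass_cutoff=150.0)
    # 3 series x (n-1) cleavages per chain, all above the cutoff here
    assert len(ions) == 3 * (15 + 17)
    ions_hi = crf_ions(POPC9, "[M+H]+", low_mass_cutoff=600.0)
    assert all(i.mz >= 600.0 for i in ions_hi)
    assert len(ions_hi) < len(ions)


def test_diagnostics_pc_head_and_sn():
    plan = diagnostic_plan(POPC9, "[M+H]+")
    mzs = [round(i.mz, 3) for i in plan.ions]
    assert 184.073 in mzs
    assert plan.class_groups and plan.class_groups[0] == [
        pytest.approx(184.0733, abs=5e-4)
    ]
    # sn1 16:0 + CH2 neutral loss
    assert any(abs(m - 491.337) < 5e-4 for m in mzs)
    assert len(plan.chain_groups) == 2


def test_sn1_ion_printed_values():
    dlpc_plan = diagnostic_plan(DLPC, "[M+H]+")
    assert any(abs(g[0] - 489.321) < 5e-4 for g in dlpc_plan.position_groups)
    papc_plan = diagnostic_plan(PAPC, "[M+H]+")
    assert any(abs(g[0] - 513.321) < 5e-4 for g in papc_plan.position_groups)


def test_pe_sn_needs_sodium():
    pe = parse_lipid_name("PE 16:0/18:1(9)")
    assert not diagnostic_plan(pe, "[M+H]+").position_applicable
    assert diagnostic_plan(pe, "[M+Na]+").position_applicable


def test_dgtx_markers_and_ratio():
    dgts = diagnostic_plan(parse_lipid_name("DGTS 16:0/18:1(9)"), "[M+Na]+")
    assert dgts.ratio_rule == (
        pytest.approx(236.149, abs=5e-4), pytest.approx(204.123, abs=5e-4)
    )
    dgta = diagnostic_plan(parse_lipid_name("DGTA 16:0/18:1(9)"), "[M+Na]+")
    assert dgta.ratio_rule[0] == pytest.approx(204.123, abs=5e-4)
    # lyso forms require presence only: the single-chain ketene loss
    # coincides with the 236 marker and confounds the ratio
    ldgta = diagnostic_plan(parse_lipid_name("LDGTA 18:1(9)/0:0"), "[M+H]+")
    assert ldgta.ratio_rule is None


def test_car_class_marker():
    plan = diagnostic_plan(parse_lipid_name("CAR 18:1(9)"), "[M+H]+")
    assert plan.class_groups[0][0] == pytest.approx(85.028, abs=5e-4)


def test_sm_oh_markers_are_position_groups():
    plan = diagnostic_plan(
        parse_lipid_name("SM 18:1(4);(1OH,3OH)/16:0"), "[M+H]+"
    )
    assert len(plan.position_groups) == 1  # C3 hydroxyl; C1 is uninformative


def test_build_requires_fully_resolved():
    with pytest.raises(FragmentationError):
        build_insilico_spectrum(parse_lipid_name("PC 16:0/18:1"), "[M+H]+")


def test_insilico_peaks_sorted_and_positive():
    ins = build_insilico_spectrum(PAPC, "[M+H]+")
    mzs = [p.mz for p in ins.peaks]
    assert mzs == sorted(mzs)
    assert all(p.model_intensity > 0 for p in ins.peaks)


def test_merged_arrays_merge_exact_collisions():
    ins = build_insilico_spectrum(PAPC, "[M+H]+")
    mz, inten = ins.merged_arrays()
    assert all(b - a > 1e-4 for a, b in zip(mz, mz[1:]))
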