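import numpy as np
import pytest

from eadlipid.annotate import (
    annotate_spectrum,
    cc_presence_check,
    matched_peaks_percentage,
    reverse_dot_product,
    score_candidate,
)
from eadlipid.fragmentation import build_insilico_spectrum
from eadlipid.lipids import AnnotationLevel, parse_lipid_name
from eadlipid.spectra import CentroidSpectrum, NoiseModel

PAPC = parse_lipid_name("PC 16:0/20:4(5,8,11,14)")
POPC9 = parse_lipid_name("PC 16:0/18:1(9)")


def delete_peaks(spectrum, mzs, tol=0.01):
    keep = np.ones(len(spectrum), bool)
    for mz in mzs:
        keep &= np.abs(spectrum.mz - mz) > tol
    return CentroidSpectrum(spectrum.mz[keep], spectrum.intensity[keep],
                            precursor_mz=spectrum.precursor_mz)


def test_self_score_is_six(noise_free):
    spec = noise_free(PAPC)
    sc = score_candidate(PAPC, "[M+H]+", spec)
    assert sc.score.total == pytest.approx(6.0, abs=1e-9)
    assert sc.score.high_confidence


def test_rdp_and_mpp_self_identity(noise_free):
    spec = noise_free(POPC9)
    ins = build_insilico_spectrum(POPC9, "[M+H]+")
    assert reverse_dot_product(ins, spec) == pytest.approx(1.0, abs=1e-12)
    assert matched_peaks_percentage(ins, spec) == 1.0


def test_rdp_invariant_under_scaling(noise_free):
    spec = noise_free(POPC9)
    ins = build_insilico_spectrum(POPC9, "[M+H]+")
    assert reverse_dot_product(ins, spec.scaled_to(123.0)) == pytest.approx(
        1.0, abs=1e-12
    )


def test_presence_check_eliminates_on_deleted_high(noise_free):
    spec = noise_free(POPC9)
    ins = build_insilico_spectrum(POPC9, "[M+H]+")
    highs = [p.mz for p in ins.expected_cc_high()]
    assert len(highs) == 2   # MUFA: no one-missing allowance
    for mz in highs:
        broken = delete_peaks(spec, [mz])
        check = cc_presence_check(ins, broken)
        assert not check.passed


def test_presence_allowance_for_long_pufa(noise_free):
    truth = parse_lipid_name("PC 16:0/22:6(4,7,10,13,16,19)")
    spec = noise_free(truth)
    ins = build_insilico_spectrum(truth, "[M+H]+")
    highs = [p.mz for p in ins.expected_cc_high()]
    assert len(highs) > 5
    one_missing = delete_peaks(spec, [highs[0]])
    assert cc_presence_check(ins, one_missing).passed
    two_missing = delete_peaks(spec, highs[:2])
    assert not cc_presence_check(ins, two_missing).passed


def test_wrong_position_scores_lower(noise_free):
    spec = noise_free(POPC9)
    right = score_candidate(POPC9, "[M+H]+", spec)
    wrong = score_candidate(parse_lipid_name("PC 16:0/18:1(11)"), "[M+H]+", spec)
    assert right.score.total > wrong.score.total
    assert wrong.score.rdp < 1.0


def test_class_failure_means_unannotated(noise_free):
    spec = noise_free(POPC9)
    ins = build_insilico_spectrum(POPC9, "[M+H]+")
    no_head = delete_peaks(spec, [g[0] for g in ins.plan.class_groups])
    res = annotate_spectrum(no_head, parse_lipid_name("PC 16:0_18:1"),
                            "[M+H]+")
    assert res.status == "unannotated" and res.annotation is None


def test_chain_failure_demotes_to_species(noise_free):
    spec = noise_free(POPC9)
    ins = build_insilico_spectrum(POPC9, "[M+H]+")
    chain_mzs = [mz for group in ins.plan.chain_groups for mz in group]
    broken = delete_peaks(spec, chain_mzs)
    res = annotate_spectrum(broken, parse_lipid_name("PC 16:0_18:1"),
                            "[M+H]+")
    assert res.status == "species"
    assert res.level is AnnotationLevel.SPECIES
    assert res.name == "PC 34:1"


def test_missing_sn_ion_reports_unassigned_sn(noise_free):
    spec = noise_free(POPC9)
    ins = build_insilico_spectrum(POPC9, "[M+H]+")
    sn_mzs = [mz for group in ins.plan.position_groups for mz in group]
    broken = delete_peaks(spec, sn_mzs)
    res = annotate_spectrum(broken, parse_lipid_name("PC 16:0_18:1"),
                            "[M+H]+")
    assert res.status == "annotated"
    assert res.name == "PC 16:0_18:1(9)"
    assert res.level is AnnotationLevel.DB_RESOLVED


def test_pe_protonated_cannot_reach_sn_level(noise_free):
    truth = parse_lipid_name("PE 16:0/18:1(9)")
    spec = noise_free(truth, "[M+H]+")
    res = annotate_spectrum(spec, parse_lipid_name("PE 16:0_18:1"), "[M+H]+")
    assert res.status == "annotated"
    assert "_" in res.name          # sn not assignable at [M+H]+
    sodium = noise_free(truth, "[M+Na]+")
    res_na = annotate_spectrum(sodium, parse_lipid_name("PE 16:0_18:1"),
                               "[M+Na]+")
    assert res_na.name == "PE 16:0/18:1(9)"


def test_species_query_resolves(noise_free):
    spec = noise_free(PAPC)
    res = annotate_spectrum(spec, parse_lipid_name("PC 36:4"), "[M+H]+")
    assert res.name == "PC 16:0/20:4(5,8,11,14)"
    assert res.level is AnnotationLevel.SN_DB_RESOLVED


def test_noise_model_is_applied(noise_free):
    spec = noise_free(POPC9)
    # bury the spectrum under the absolute threshold: nothing detectable
    tiny = CentroidSpectrum(spec.mz, spec.intensity * (10.0 / spec.intensity.max()),
                            precursor_mz=spec.precursor_mz)
    res = annotate_spectrum(tiny, parse_lipid_name("PC 16:0_18:1"), "[M+H]+",
                            noise=NoiseModel())
    assert res.status == "unannotated"


def test_ranking_is_deterministic(noise_free):
    spec = noise_free(POPC9)
    r1 = annotate_spectrum(spec, parse_lipid_name("PC 16:0_18:1"), "[M+H]+")
    r2 = annotate_spectrum(spec, parse_lipid_name("PC 16:0_18:1"), "[M+H]+")
    assert [s.structure.format() for s in r1.ranked] == [
        s.structure.format() for s in r2.ranked
    ]
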