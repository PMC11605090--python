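import pytest

from eadlipid.candidates import (
    CandidateConfig,
    enumerate_candidates,
    mufa_positions,
    pufa_series,
    sphingoid_positions,
)
from eadlipid.lipids import parse_lipid_name


def test_mufa_positions_18():
    # curated (9, 11, 13) plus omega-3/6/9 (15, 12, 9)
    assert mufa_positions(18) == [9, 11, 12, 13, 15]
    assert 8 not in mufa_positions(18)


def test_mufa_positions_uncurated_length():
    # only the omega rule applies
    assert mufa_positions(15) == [6, 9, 12]


def test_pufa_series_dha():
    assert (4, 7, 10, 13, 16, 19) in pufa_series(22, 6)


def test_pufa_series_families_that_do_not_fit_are_dropped():
    series = pufa_series(18, 3)
    assert (9, 12, 15) in series          # n-3
    assert all(s[0] >= 2 for s in series)


def test_pufa_series_methylene_interrupted():
    for s in pufa_series(20, 4):
        assert all(b - a == 3 for a, b in zip(s, s[1:]))


def test_sphingoid_positions():
    assert sphingoid_positions(0) == [()]
    assert sphingoid_positions(1) == [(4,)]
    assert (4, 14) in sphingoid_positions(2)
    with pytest.warns(UserWarning):
        assert sphingoid_positions(4) == []


def test_enumerate_contains_both_sn_orders_and_positions():
    names = [
        c.structure.format()
        for c in enumerate_candidates(parse_lipid_name("PC 16:0_18:1"))
    ]
    for want in ("PC 16:0/18:1(9)", "PC 18:1(9)/16:0",
                 "PC 16:0/18:1(11)", "PC 18:1(11)/16:0"):
        assert want in names
    assert not any("18:1(8)" in n for n in names)


def test_enumerate_curated_before_omega_fallback():
    cands = enumerate_candidates(parse_lipid_name("PC 16:0_18:1"))
    provs = [c.provenance for c in cands]
    first_omega = provs.index("omega-rule")
    assert "curated" not in provs[first_omega:]


def test_identical_chains_collapse():
    cands = enumerate_candidates(parse_lipid_name("PC 16:0_16:0"))
    assert [c.structure.format() for c in cands] == ["PC 16:0/16:0"]


def test_lyso_gets_both_sn_slots():
    names = [
        c.structure.format()
        for c in enumerate_candidates(parse_lipid_name("LPC 18:0_0:0"))
    ]
    assert "LPC 18:0/0:0" in names and "LPC 0:0/18:0" in names


def test_sphingoid_single_db_fixed_at_4():
    names = [
        c.structure.format()
        for c in enumerate_candidates(parse_lipid_name("SM 18:1;O2/16:0"))
    ]
    assert names == ["SM 18:1(4);(1OH,3OH)/16:0"]


def test_species_level_query_splits_chains():
    names = [
        c.structure.format()
        for c in enumerate_candidates(parse_lipid_name("PC 34:1"))
    ]
    assert "PC 16:0/18:1(9)" in names
    assert any(n.startswith("PC 14:0/20:1") for n in names)


def test_cap_truncates_deterministically():
    config = CandidateConfig(max_candidates=5)
    cands = enumerate_candidates(parse_lipid_name("PC 34:2"), config)
    assert cands.truncated and len(cands) == 5


def test_enumeration_is_deterministic():
    a = enumerate_candidates(parse_lipid_name("PE 16:0_22:6"))
    b = enumerate_candidates(parse_lipid_name("PE 16:0_22:6"))
    assert [c.structure.format() for c in a] == [c.structure.format() for c in b]


def test_config_from_toml(tmp_path):
    p = tmp_path / "space.toml"
    p.write_text("omega_offsets = [9]\nmax_candidates = 7\n")
    config = CandidateConfig.from_toml(str(p))
    assert config.omega_offsets == (9,) and config.max_candidates == 7


def test_config_from_yaml(tmp_path):
    p = tmp_path / "space.yaml"
    p.write_text("mufa_positions:\n  18: [9]\n")
    config = CandidateConfig.from_yaml(str(p))
    assert config.mufa_positions[18] == (9,)
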