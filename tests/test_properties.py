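"""Property-based tests (deterministic: derandomized, fixed profile)."""

import math

import numpy as np
from hypothesis import given, settings, strategies as st

from eadlipid.chains import AcylChain
from eadlipid.elements import H_ATOM_MASS, formula
from eadlipid.fragmentation import (
    Series,
    classify_abundance,
    crf_fragment_mz,
    crf_loss_formula,
)
from eadlipid.lipids import LipidStructure, parse_lipid_name
from eadlipid.metrics import modified_dot_product, spectral_entropy
from eadlipid.spectra import CentroidSpectrum

SETTINGS = settings(derandomize=True, max_examples=50, deadline=None)


def mufa_chain():
    return st.integers(12, 26).flatmap(
        lambda n: st.integers(2, n - 1).map(
            lambda p: AcylChain(n, 1, db_positions=(p,))
        )
    )


@SETTINGS
@given(mufa_chain(), st.integers(1, 40))
def test_crf_series_always_one_h_apart(chain, k):
    if k > chain.carbons - 1:
        return
    lipid = LipidStructure("PC", (AcylChain(16, 0), chain), sn_assigned=True)
    r = crf_fragment_mz(lipid, "[M+H]+", 1, k, Series.RADICAL)
    lo = crf_fragment_mz(lipid, "[M+H]+", 1, k, Series.H_LOSS)
    hi = crf_fragment_mz(lipid, "[M+H]+", 1, k, Series.H_GAIN)
    assert math.isclose(r - lo, H_ATOM_MASS, abs_tol=1e-12)
    assert math.isclose(hi - r, H_ATOM_MASS, abs_tol=1e-12)


@SETTINGS
@given(mufa_chain())
def test_crf_losses_telescope_to_full_chain(chain):
    # successive losses differ by CH2 except across the double bond
    masses = [crf_loss_formula(chain, k).mass for k in range(1, chain.carbons)]
    diffs = np.diff(masses)
    assert all(d < 0 for d in diffs)   # retaining more carbons loses less


@SETTINGS
@given(mufa_chain())
def test_classify_covers_every_cleavage(chain):
    labels = classify_abundance(chain)
    assert len(labels) == 3 * (chain.carbons - 1)


@SETTINGS
@given(st.integers(18, 24), st.integers(0, 4))
def test_species_formula_consistent_with_resolved(carbons, db):
    resolved = LipidStructure(
        "PE",
        (AcylChain(16, 0),
         AcylChain(carbons, db,
                   db_positions=tuple(range(5, 5 + 3 * db, 3)) if db else None)),
        sn_assigned=True,
    )
    species = parse_lipid_name(f"PE {16 + carbons}:{db}")
    assert species.neutral_formula().hill() == resolved.neutral_formula().hill()


@SETTINGS
@given(st.lists(st.floats(1.0, 1e6), min_size=1, max_size=30),
       st.floats(0.1, 100.0))
def test_entropy_scale_invariance(intensities, scale):
    mz = np.arange(len(intensities)) * 2.0 + 100.0
    a = CentroidSpectrum(mz, np.array(intensities))
    b = CentroidSpectrum(mz, np.array(intensities) * scale)
    assert math.isclose(spectral_entropy(a), spectral_entropy(b),
                        rel_tol=1e-9, abs_tol=1e-9)
    assert spectral_entropy(a) <= math.log(len(intensities)) + 1e-9


@SETTINGS
@given(st.lists(st.tuples(st.floats(100.0, 900.0), st.floats(60.0, 1e5)),
                min_size=1, max_size=20))
def test_mdp_self_similarity_and_symmetry(peaks):
    mz = np.array(sorted(p[0] for p in peaks))
    inten = np.array([p[1] for p in peaks])
    s = CentroidSpectrum(mz, inten)
    if modified_dot_product(s, s) == 0.0:
        return  # everything fell below the noise cutoffs
    assert math.isclose(modified_dot_product(s, s), 1.0, abs_tol=1e-9)


@SETTINGS
@given(st.text(alphabet="PCE O-18:2(9,1)/_;", max_size=25))
def test_parser_never_crashes_unhandled(text):
    from eadlipid.chains import ChainParseError
    from eadlipid.lipids import LipidParseError

    try:
        parse_lipid_name(text)
    except (LipidParseError, ChainParseError, ValueError):
        pass
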