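import numpy as np
import pytest

from eadlipid import CentroidSpectrum
from eadlipid.fragmentation import build_insilico_spectrum
from eadlipid.lipids import parse_lipid_name


def make_noise_free(structure, adduct="[M+H]+", base=10_000.0):
    """Noise-free experimental spectrum from the in-silico model."""
    if isinstance(structure, str):
        structure = parse_lipid_name(structure)
    ins = build_insilico_spectrum(structure, adduct)
    mz, inten = ins.merged_arrays()
    return CentroidSpectrum(
        mz, inten * (base / inten.max()), precursor_mz=ins.precursor_mz,
        metadata={"name": structure.format()},
    )


@pytest.fixture
def noise_free():
    return make_noise_free


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
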