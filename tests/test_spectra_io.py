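import numpy as np
import pytest

from eadlipid.io import FormatError, read_msp, write_msp
from eadlipid.spectra import (
    CentroidSpectrum,
    NoiseModel,
    SpectrumError,
    accumulate_scans,
    is_detected,
    matched_intensity,
    subtract_background,
)


def spec(mz, inten, **kw):
    return CentroidSpectrum(np.asarray(mz, float), np.asarray(inten, float), **kw)


def test_spectrum_sorts_peaks():
    s = spec([300.0, 100.0, 200.0], [1, 2, 3])
    assert list(s.mz) == [100.0, 200.0, 300.0]
    assert list(s.intensity) == [2.0, 3.0, 1.0]


def test_spectrum_rejects_bad_shapes_and_values():
    with pytest.raises(SpectrumError):
        spec([1.0, 2.0], [1.0])
    with pytest.raises(SpectrumError):
        spec([1.0], [-1.0])
    with pytest.raises(SpectrumError):
        spec([np.nan], [1.0])


def test_nearest_peak():
    s = spec([100.0, 100.04, 200.0], [1, 2, 3])
    assert s.nearest_peak(100.041, tolerance=0.025) == 1
    assert s.nearest_peak(150.0, tolerance=0.025) is None


def test_accumulate_scans_bin_centers_and_average():
    a = spec([100.01], [10.0])
    b = spec([100.02], [30.0])
    acc = accumulate_scans([a, b], bin_width=0.05)
    assert len(acc) == 1
    assert acc.mz[0] == pytest.approx(100.025)
    assert acc.intensity[0] == pytest.approx(20.0)   # summed / n_scans


def test_subtract_background_clamps_and_drops():
    sample = accumulate_scans([spec([100.01, 200.01], [50.0, 5.0])], 0.05)
    bg = accumulate_scans([spec([100.02, 200.02], [20.0, 50.0])], 0.05)
    out = subtract_background(sample, bg)
    assert len(out) == 1
    assert out.intensity[0] == pytest.approx(30.0)


def test_subtract_background_bin_mismatch():
    sample = accumulate_scans([spec([100.0], [1.0])], 0.05)
    bg = accumulate_scans([spec([100.0], [1.0])], 0.1)
    with pytest.raises(SpectrumError):
        subtract_background(sample, bg)


def test_noise_filter_strictly_below_threshold():
    s = spec([100.0, 200.0, 300.0], [10.999, 11.0, 50.0])
    filt = NoiseModel().filter(s)
    assert list(filt.mz) == [200.0, 300.0]
    assert NoiseModel().min_peak_intensity(s) == 11.0


def test_detection_boundary_22_vs_23():
    s = spec([100.0, 200.0, 300.0], [11.0, 22.0, 23.0])
    model = NoiseModel()
    assert model.detection_floor(s) == 22.0
    assert not is_detected(s, 200.0, model)   # 22 is not strictly above 2x11
    assert is_detected(s, 300.0, model)


def test_detection_without_noise_model_is_presence():
    s = spec([100.0], [1.0])
    assert is_detected(s, 100.0)
    assert not is_detected(s, 101.0)


def test_matched_intensity():
    s = spec([100.0], [42.0])
    assert matched_intensity(s, 100.01) == 42.0
    assert matched_intensity(s, 101.0) == 0.0


def test_msp_roundtrip(tmp_path):
    path = str(tmp_path / "lib.msp")
    s1 = spec([100.0, 200.5], [1.0, 2.0], precursor_mz=500.1234,
              metadata={"name": "A"})
    s2 = spec([150.0], [3.0], metadata={"name": "B"})
    write_msp(path, [s1, s2])
    back = read_msp(path)
    assert [r.metadata["name"] for r in back] == ["A", "B"]
    assert back[0].precursor_mz == pytest.approx(500.1234)
    assert list(back[0].mz) == [100.0, 200.5]


def test_msp_strict_peak_count(tmp_path):
    path = tmp_path / "bad.msp"
    path.write_text("Name: X\nNum Peaks: 2\n100.0 1\n")
    with pytest.raises(FormatError, match="declares 2"):
        read_msp(str(path))


def test_msp_non_numeric_peak_row(tmp_path):
    path = tmp_path / "bad.msp"
    path.write_text("Name: X\nNum Peaks: 1\nfoo bar\n")
    with pytest.raises(FormatError, match="line 3"):
        read_msp(str(path))


def test_msp_missing_num_peaks(tmp_path):
    path = tmp_path / "bad.msp"
    path.write_text("Name: X\nPrecursorMz: 100.0\n\n")
    with pytest.raises(FormatError, match="Num Peaks"):
        read_msp(str(path))


def test_mgf_read(tmp_path):
    path = tmp_path / "one.mgf"
    path.write_text(
        "BEGIN IONS\nTITLE=demo\nPEPMASS=500.25\nCHARGE=1+\n"
        "100.0 10.0\n200.0 20.0\nEND IONS\n"
    )
    from eadlipid.io import read_mgf

    specs = read_mgf(str(path))
    assert len(specs) == 1
    assert specs[0].precursor_mz == pytest.approx(500.25)
    assert len(specs[0]) == 2
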