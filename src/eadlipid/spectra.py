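"""Centroid spectrum model, scan accumulation and the noise model.

EAD spectra carry a dense low-intensity "barcode" of chemical noise.  The
noise model removes peaks strictly below an absolute threshold (default 11
counts) and then requires a diagnostic peak to exceed both the threshold and
a multiple (default 2x) of the smallest retained peak intensity before it
counts as detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

#: Default m/z matching tolerance for peak annotation, Da.
DEFAULT_MZ_TOLERANCE = 0.025

#: Default accumulation bin width, Da.
DEFAULT_BIN_WIDTH = 0.05


class SpectrumError(ValueError):
    pass


@dataclass(frozen=True)
class CentroidSpectrum:
    """An immutable centroided spectrum with m/z-sorted peaks."""

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or intensity.ndim != 1:
            raise SpectrumError("mz and intensity must be 1-D arrays")
        if mz.shape != intensity.shape:
            raise SpectrumError(
                f"mz ({mz.size}) and intensity ({intensity.size}) differ in length"
            )
        if mz.size and np.any(np.diff(mz) < 0):
            order = np.argsort(mz, kind="stable")
            mz, intensity = mz[order], intensity[order]
        if np.any(intensity < 0):
            raise SpectrumError("negative peak intensity")
        if np.any(~np.isfinite(mz)) or np.any(~np.isfinite(intensity)):
            raise SpectrumError("non-finite peak values")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0

    def scaled_to(self, base: float = 10_000.0) -> "CentroidSpectrum":
        if not len(self):
            return self
        return replace(self, intensity=self.intensity * (base / self.base_peak_intensity))

    def nearest_peak(
        self, mz: float, tolerance: float = DEFAULT_MZ_TOLERANCE
    ) -> Optional[int]:
        """Index of the closest peak within ``tolerance`` Da, else None."""
        if not len(self):
            return None
        i = int(np.searchsorted(self.mz, mz))
        best, dist = None, tolerance
        for j in (i - 1, i):
            if 0 <= j < len(self):
                d = abs(float(self.mz[j]) - mz)
                if d <= dist:
                    best, dist = j, d
        return best


def accumulate_scans(
    scans: Iterable[CentroidSpectrum],
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> CentroidSpectrum:
    """Average several scans on a common m/z grid.

    Peaks are pooled into bins of ``bin_width`` Da; each occupied bin yields
    one peak at the bin centre whose intensity is the summed intensity
    divided by the number of scans.
    """
    scans = list(scans)
    if not scans:
        raise SpectrumError("no scans to accumulate")
    if bin_width <= 0:
        raise SpectrumError("bin width must be positive")
    totals: dict[int, float] = {}
    for scan in scans:
        for m, i in zip(scan.mz, scan.intensity):
            b = int(np.floor(m / bin_width))
            totals[b] = totals.get(b, 0.0) + float(i)
    bins = sorted(totals)
    mz = np.array([(b + 0.5) * bin_width for b in bins])
    intensity = np.array([totals[b] / len(scans) for b in bins])
    precursor = scans[0].precursor_mz
    return CentroidSpectrum(mz, intensity, precursor_mz=precursor,
                            metadata={"n_scans": len(scans),
                                      "bin_width": bin_width})


def subtract_background(
    sample: CentroidSpectrum,
    background: CentroidSpectrum,
    bin_width: Optional[float] = None,
) -> CentroidSpectrum:
    """Bin-wise background subtraction of two accumulated spectra.

    Both spectra must share the same accumulation grid; intensities are
    clamped at zero and emptied bins dropped.
    """
    bw_s = sample.metadata.get("bin_width")
    bw_b = background.metadata.get("bin_width")
    bw = bin_width or bw_s or bw_b
    if bw is None:
        raise SpectrumError("bin width unknown; accumulate both spectra first")
    if bw_s is not None and bw_b is not None and bw_s != bw_b:
        raise SpectrumError(
            f"bin-width mismatch: sample {bw_s} vs background {bw_b}"
        )
    bg = {int(np.floor(m / bw)): float(i)
          for m, i in zip(background.mz, background.intensity)}
    mz_out, int_out = [], []
    for m, i in zip(sample.mz, sample.intensity):
        v = float(i) - bg.get(int(np.floor(m / bw)), 0.0)
        if v > 0:
            mz_out.append(float(m))
            int_out.append(v)
    return CentroidSpectrum(np.array(mz_out), np.array(int_out),
                            precursor_mz=sample.precursor_mz,
                            metadata=dict(sample.metadata))


@dataclass(frozen=True)
class NoiseModel:
    """Absolute threshold plus noise-relative detection rule."""

    threshold: float = 11.0
    multiplier: float = 2.0

    def filter(self, spectrum: CentroidSpectrum) -> CentroidSpectrum:
        """Remove peaks strictly below the absolute threshold."""
        keep = spectrum.intensity >= self.threshold
        return replace(spectrum, mz=spectrum.mz[keep],
                       intensity=spectrum.intensity[keep])

    def min_peak_intensity(self, spectrum: CentroidSpectrum) -> float:
        """Smallest intensity among the retained peaks (0 if empty)."""
        filt = self.filter(spectrum)
        return float(filt.intensity.min()) if len(filt) else 0.0

    def detection_floor(self, spectrum: CentroidSpectrum) -> float:
        """Intensity a peak must strictly exceed to count as detected."""
        return max(self.threshold, self.multiplier * self.min_peak_intensity(spectrum))


def is_detected(
    spectrum: CentroidSpectrum,
    mz: float,
    noise: Optional[NoiseModel] = None,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
    floor: Optional[float] = None,
) -> bool:
    """Whether a diagnostic m/z is present above the detection floor.

    With a noise model (or precomputed ``floor``), the matched peak must be
    strictly greater than max(threshold, multiplier x min retained
    intensity); without one, any tolerance match counts.
    """
    idx = spectrum.nearest_peak(mz, tolerance)
    if idx is None:
        return False
    if noise is None and floor is None:
        return True
    if floor is None:
        floor = noise.detection_floor(spectrum)
    return float(spectrum.intensity[idx]) > floor


def matched_intensity(
    spectrum: CentroidSpectrum,
    mz: float,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
) -> float:
    idx = spectrum.nearest_peak(mz, tolerance)
    return float(spectrum.intensity[idx]) if idx is not None else 0.0
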