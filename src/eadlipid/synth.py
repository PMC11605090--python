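"""Synthetic EAD spectra and imaging phantoms for testing and simulation.

Spectra are generated from the in-silico fragmentation model, scaled to a
fixed base-peak intensity, and perturbed with lognormal intensity jitter,
Gaussian m/z jitter, optional dropout of unremarkable CRF peaks, and a dense
low-intensity "barcode" of chemical-noise peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .adducts import Adduct, get_adduct
from .fragmentation import (
    AbundanceClass,
    FragmentIon,
    Series,
    build_insilico_spectrum,
)
from .lipids import LipidStructure, parse_lipid_name
from .msi import CCSCalibration, MsiPixel
from .spectra import CentroidSpectrum

_CRF_SERIES = {Series.H_LOSS, Series.RADICAL, Series.H_GAIN}


@dataclass(frozen=True)
class SpectrumNoiseConfig:
    base_peak: float = 10_000.0
    mz_sigma: float = 0.002            # Da
    intensity_sigma: float = 0.15      # lognormal sigma
    dropout: float = 0.02              # plain CRF peaks only
    noise_peaks_per_da: float = 0.5    # barcode density
    noise_intensity: tuple[float, float] = (4.0, 11.0)
    low_mass: float = 150.0


DEFAULT_NOISE = SpectrumNoiseConfig()


def _jitter_and_noise(
    mz: np.ndarray,
    intensity: np.ndarray,
    precursor: float,
    rng: np.random.Generator,
    config: SpectrumNoiseConfig,
) -> CentroidSpectrum:
    intensity = intensity * (config.base_peak / intensity.max())
    intensity = intensity * rng.lognormal(0.0, config.intensity_sigma, intensity.size)
    mz = mz + rng.normal(0.0, config.mz_sigma, mz.size)
    span = max(precursor - config.low_mass, 1.0)
    n_noise = rng.poisson(config.noise_peaks_per_da * span)
    noise_mz = rng.uniform(config.low_mass, precursor, n_noise)
    lo, hi = config.noise_intensity
    noise_int = rng.uniform(lo, hi, n_noise)
    return CentroidSpectrum(
        np.concatenate([mz, noise_mz]),
        np.concatenate([intensity, noise_int]),
        precursor_mz=precursor,
    )


def _model_peaks(
    structure: LipidStructure,
    adduct: Adduct,
    rng: np.random.Generator,
    config: SpectrumNoiseConfig,
) -> tuple[list[FragmentIon], float]:
    ins = build_insilico_spectrum(structure, adduct, config.low_mass)
    peaks = []
    for p in ins.peaks:
        if (p.series in _CRF_SERIES
                and p.abundance_class is AbundanceClass.PLAIN
                and rng.random() < config.dropout):
            continue
        peaks.append(p)
    return peaks, ins.precursor_mz


def _merge(peaks: Sequence[tuple[float, float]], tol: float = 1e-4
           ) -> tuple[np.ndarray, np.ndarray]:
    mzs: list[float] = []
    ints: list[float] = []
    for m, i in sorted(peaks):
        if mzs and m - mzs[-1] <= tol:
            ints[-1] += i
        else:
            mzs.append(m)
            ints.append(i)
    return np.asarray(mzs), np.asarray(ints)


def synth_spectrum(
    structure: LipidStructure | str,
    adduct: Adduct | str,
    rng: np.random.Generator,
    config: SpectrumNoiseConfig = DEFAULT_NOISE,
) -> CentroidSpectrum:
    """Noisy synthetic EAD spectrum of one fully resolved lipid."""
    if isinstance(structure, str):
        structure = parse_lipid_name(structure)
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    peaks, precursor = _model_peaks(structure, adduct, rng, config)
    mz, inten = _merge([(p.mz, p.model_intensity) for p in peaks])
    spec = _jitter_and_noise(mz, inten, precursor, rng, config)
    return replace(spec, metadata={"name": structure.format(),
                                   "adduct": adduct.name})


def synth_mixture(
    components: Sequence[tuple[LipidStructure | str, float]],
    adduct: Adduct | str,
    rng: np.random.Generator,
    config: SpectrumNoiseConfig = DEFAULT_NOISE,
) -> CentroidSpectrum:
    """Synthetic spectrum of co-isolated isomers with given weights."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    pooled: list[tuple[float, float]] = []
    precursor = None
    names = []
    for structure, weight in components:
        if isinstance(structure, str):
            structure = parse_lipid_name(structure)
        peaks, precursor = _model_peaks(structure, adduct, rng, config)
        pooled.extend((p.mz, weight * p.model_intensity) for p in peaks)
        names.append(f"{structure.format()}*{weight:g}")
    mz, inten = _merge(pooled)
    spec = _jitter_and_noise(mz, inten, precursor, rng, config)
    return replace(spec, metadata={"name": " + ".join(names),
                                   "adduct": adduct.name})


def synth_dilution_series(
    structure: LipidStructure | str,
    adduct: Adduct | str,
    rng: np.random.Generator,
    scales: Sequence[float] = (1.0, 0.3, 0.1, 0.03, 0.01),
    config: SpectrumNoiseConfig = DEFAULT_NOISE,
) -> list[CentroidSpectrum]:
    """Spectra of decreasing abundance over a constant noise floor."""
    out = []
    for s in scales:
        spec = synth_spectrum(
            structure, adduct, rng,
            replace(config, base_peak=config.base_peak * s),
        )
        out.append(replace(spec, metadata={**spec.metadata, "scale": s}))
    return out


# ---------------------------------------------------------------------------
# Imaging phantom
# ---------------------------------------------------------------------------

@dataclass
class MsiPhantom:
    pixels: list[MsiPixel]
    truth: pd.DataFrame                 # name/adduct/mz/ccs/source
    calibration: CCSCalibration
    pick_min_intensity: float           # safe feature-picking floor
    regions: dict[str, np.ndarray] = None  # name -> boolean mask [y, x]

    @property
    def shape(self) -> tuple[int, int]:
        h = max(px.y for px in self.pixels) + 1
        w = max(px.x for px in self.pixels) + 1
        return (h, w)


_PHANTOM_SPECIES = (
    ("PC 16:0/18:1(9)", "[M+H]+"),
    ("PC 18:2(9,12)/18:2(9,12)", "[M+H]+"),
    ("PE 16:0/20:4(5,8,11,14)", "[M+H]+"),
    ("SM 18:1(4);(1OH,3OH)/16:0", "[M+H]+"),
)


def _region_mask(index: int, h: int, w: int) -> np.ndarray:
    """Deterministic, partially overlapping spatial regions."""
    yy, xx = np.mgrid[0:h, 0:w]
    if index % 4 == 0:      # disc
        cy, cx, r = h * 0.35, w * 0.35, min(h, w) * 0.22
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
    if index % 4 == 1:      # square
        return (yy > h * 0.55) & (yy < h * 0.9) & (xx > w * 0.55) & (xx < w * 0.9)
    if index % 4 == 2:      # horizontal band
        return (yy > h * 0.4) & (yy < h * 0.55)
    return xx < w * 0.25    # left stripe


def synth_msi_phantom(
    rng: np.random.Generator,
    width: int = 100,
    height: int = 100,
    species: Sequence[tuple[str, str]] = _PHANTOM_SPECIES,
    calibration: CCSCalibration = CCSCalibration(slope=40.0, intercept=120.0),
    signal_intensity: float = 100.0,
    noise_rate: float = 0.1,
    mz_sigma: float = 0.0005,
    dt_sigma: float = 0.002,
) -> MsiPhantom:
    """Imaging phantom with known lipid channels in geometric regions.

    Each species occupies a deterministic region; per covered pixel one
    event is emitted near its (m/z, drift time) with small jitter.  Sparse
    random low-intensity events (intensity <= 5) model chemical noise; the
    returned ``pick_min_intensity`` sits far above any noise accumulation
    and far below any signal feature.
    """
    truth_rows = []
    channels = []
    for idx, (name, adduct_name) in enumerate(species):
        structure = parse_lipid_name(name)
        adduct = get_adduct(adduct_name)
        mz = structure.precursor_mz(adduct)
        # synthetic mass-mobility trend with a per-species offset
        ccs = 180.0 + 0.12 * mz + 7.0 * (idx % 3)
        truth_rows.append({
            "name": name, "adduct": adduct_name, "mz": round(mz, 4),
            "ccs": round(ccs, 2), "source": "phantom",
        })
        channels.append((mz, calibration.drift_time(ccs),
                         _region_mask(idx, height, width)))
    pixels = []
    for y in range(height):
        for x in range(width):
            mzs, dts, ints = [], [], []
            for mz, dt, mask in channels:
                if mask[y, x]:
                    mzs.append(mz + rng.normal(0.0, mz_sigma))
                    dts.append(dt + rng.normal(0.0, dt_sigma))
                    ints.append(signal_intensity * rng.lognormal(0.0, 0.2))
            if rng.random() < noise_rate:
                mzs.append(rng.uniform(400.0, 900.0))
                dts.append(rng.uniform(calibration.drift_time(200.0),
                                       calibration.drift_time(350.0)))
                ints.append(rng.uniform(1.0, 5.0))
            pixels.append(MsiPixel(x, y, np.array(mzs), np.array(dts),
                                   np.array(ints)))
    return MsiPhantom(
        pixels=pixels,
        truth=pd.DataFrame(truth_rows),
        calibration=calibration,
        pick_min_intensity=50.0,
        regions={row["name"]: channels[i][2]
                 for i, row in enumerate(truth_rows)},
    )
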