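"""Mass-spectrometry imaging with ion mobility: feature finding, reference
matching and ion images.

Pixel events are pooled into a sparse 2-D histogram over (m/z, drift time);
features are strict 8-neighborhood local maxima of that histogram.  Drift
times convert to collision cross sections (CCS) through a linear single-field
calibration, and features are matched to a reference table within m/z and
CCS tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_MZ_BIN = 0.005        # Da
DEFAULT_DT_BIN = 0.01         # ms
MATCH_MZ_TOL = 0.01           # Da
MATCH_CCS_TOL = 20.0          # squared angstroms
IMAGE_MZ_TOL = 0.01           # Da
IMAGE_CCS_TOL = 5.0           # squared angstroms

REFERENCE_COLUMNS = ("name", "adduct", "mz", "ccs", "source")


@dataclass(frozen=True)
class CCSCalibration:
    """Linear single-field calibration: ccs = slope * drift_time + intercept."""

    slope: float
    intercept: float = 0.0

    def ccs(self, drift_time: float) -> float:
        return self.slope * drift_time + self.intercept

    def drift_time(self, ccs: float) -> float:
        return (ccs - self.intercept) / self.slope


@dataclass
class MsiPixel:
    x: int
    y: int
    mz: np.ndarray
    drift_time: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.drift_time = np.asarray(self.drift_time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (self.mz.shape == self.drift_time.shape == self.intensity.shape):
            raise ValueError("pixel arrays must share one length")


@dataclass(frozen=True)
class MsiFeature:
    mz: float
    drift_time: float
    intensity: float
    ccs: Optional[float] = None     # direct CCS, bypasses the calibration


def accumulate_features(
    pixels: Iterable[MsiPixel],
    mz_bin: float = DEFAULT_MZ_BIN,
    dt_bin: float = DEFAULT_DT_BIN,
) -> dict[tuple[int, int], float]:
    """Sparse (m/z bin, drift-time bin) -> summed intensity over all pixels."""
    hist: dict[tuple[int, int], float] = {}
    for px in pixels:
        for m, t, i in zip(px.mz, px.drift_time, px.intensity):
            key = (int(np.floor(m / mz_bin)), int(np.floor(t / dt_bin)))
            hist[key] = hist.get(key, 0.0) + float(i)
    return hist


_NEIGHBORS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
              if (di, dj) != (0, 0)]


def pick_features(
    hist: dict[tuple[int, int], float],
    min_intensity: float = 0.0,
    mz_bin: float = DEFAULT_MZ_BIN,
    dt_bin: float = DEFAULT_DT_BIN,
) -> list[MsiFeature]:
    """Strict local maxima of the accumulated histogram.

    A bin is a feature when its summed intensity is at least
    ``min_intensity`` and strictly greater than all eight neighbouring bins
    (absent neighbours count as zero).  Reported coordinates are bin
    centres.
    """
    out = []
    for (bi, bj), v in hist.items():
        if v < min_intensity:
            continue
        if all(v > hist.get((bi + di, bj + dj), 0.0)
               for di, dj in _NEIGHBORS):
            out.append(
                MsiFeature((bi + 0.5) * mz_bin, (bj + 0.5) * dt_bin, v)
            )
    out.sort(key=lambda f: (-f.intensity, f.mz))
    return out


def read_reference(path: str) -> pd.DataFrame:
    """Read a tab-separated reference table (name/adduct/mz/ccs/source)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"reference table missing columns: {missing}")
    return df


def match_features(
    features: Sequence[MsiFeature],
    reference: pd.DataFrame,
    calibration: Optional[CCSCalibration] = None,
    mz_tol: float = MATCH_MZ_TOL,
    ccs_tol: float = MATCH_CCS_TOL,
) -> pd.DataFrame:
    """Annotate picked features against the reference by m/z and CCS.

    Features carrying a direct ``ccs`` value use it; otherwise the
    calibration converts drift time.  One row per (feature, reference hit);
    the closest reference by combined normalized distance is ranked first
    per feature.
    """
    rows = []
    for idx, feat in enumerate(features):
        if feat.ccs is not None:
            ccs = feat.ccs
        elif calibration is not None:
            ccs = calibration.ccs(feat.drift_time)
        else:
            raise ValueError(
                f"feature {idx} has no CCS and no calibration was given"
            )
        dmz = (reference["mz"] - feat.mz).abs()
        dccs = (reference["ccs"] - ccs).abs()
        hits = reference[(dmz <= mz_tol) & (dccs <= ccs_tol)]
        if hits.empty:
            rows.append({
                "feature": idx, "feature_mz": feat.mz, "feature_ccs": ccs,
                "intensity": feat.intensity, "name": None, "adduct": None,
                "ref_mz": np.nan, "ref_ccs": np.nan, "source": None,
                "distance": np.nan,
            })
            continue
        dist = (dmz[hits.index] / mz_tol) ** 2 + (dccs[hits.index] / ccs_tol) ** 2
        for ref_idx in dist.sort_values().index:
            ref = reference.loc[ref_idx]
            rows.append({
                "feature": idx, "feature_mz": feat.mz, "feature_ccs": ccs,
                "intensity": feat.intensity, "name": ref["name"],
                "adduct": ref["adduct"], "ref_mz": ref["mz"],
                "ref_ccs": ref["ccs"], "source": ref["source"],
                "distance": float(np.sqrt(dist[ref_idx])),
            })
    return pd.DataFrame(rows)


def ion_image(
    pixels: Sequence[MsiPixel],
    mz: float,
    ccs: Optional[float],
    calibration: Optional[CCSCalibration] = None,
    mz_tol: float = IMAGE_MZ_TOL,
    ccs_tol: float = IMAGE_CCS_TOL,
    shape: Optional[tuple[int, int]] = None,
) -> np.ndarray:
    """Summed-intensity image of one (m/z, CCS) channel.

    CCS gating needs a calibration; pass ``ccs=None`` to gate on m/z only.
    The returned array is indexed [y, x].
    """
    if ccs is not None and calibration is None:
        raise ValueError("CCS gating requires a calibration")
    if shape is None:
        h = max(px.y for px in pixels) + 1
        w = max(px.x for px in pixels) + 1
    else:
        h, w = shape
    img = np.zeros((h, w))
    for px in pixels:
        sel = np.abs(px.mz - mz) <= mz_tol
        if ccs is not None:
            ccs_vals = calibration.slope * px.drift_time + calibration.intercept
            sel &= np.abs(ccs_vals - ccs) <= ccs_tol
        if sel.any():
            img[px.y, px.x] += float(px.intensity[sel].sum())
    return img
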