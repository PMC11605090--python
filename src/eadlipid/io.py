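"""Spectrum file formats.

MSP (NIST text libraries) is read and written with a strict hand-rolled
parser so that malformed records fail with a line number; MGF and mzML are
delegated to :mod:`pyteomics`.  Only centroided data is accepted.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Optional

import numpy as np

from .spectra import CentroidSpectrum, SpectrumError


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# MSP
# ---------------------------------------------------------------------------

def read_msp(path: str) -> list[CentroidSpectrum]:
    """Read an MSP library strictly.

    Each record needs a Name, an exact Num Peaks count, and numeric peak
    rows; violations raise :class:`FormatError` with the offending line.
    """
    records: list[CentroidSpectrum] = []
    meta: dict = {}
    peaks: list[tuple[float, float]] = []
    expected: Optional[int] = None
    start_line = 0

    def flush(line_no: int) -> None:
        nonlocal meta, peaks, expected
        if not meta and not peaks:
            return
        if "name" not in meta:
            raise FormatError(f"line {start_line}: record without Name")
        if expected is None:
            raise FormatError(f"line {line_no}: record {meta['name']!r} "
                              "missing Num Peaks")
        if len(peaks) != expected:
            raise FormatError(
                f"line {line_no}: record {meta['name']!r} declares "
                f"{expected} peaks but lists {len(peaks)}"
            )
        mz = np.array([p[0] for p in peaks])
        inten = np.array([p[1] for p in peaks])
        precursor = meta.pop("precursormz", None)
        records.append(CentroidSpectrum(mz, inten, precursor_mz=precursor,
                                        metadata=dict(meta)))
        meta, peaks, expected = {}, [], None

    with open(path) as fh:
        for ln, rawline in enumerate(fh, 1):
            line = rawline.strip()
            if not line:
                flush(ln)
                continue
            if expected is not None and len(peaks) < expected:
                parts = line.replace("\t", " ").split()
                if len(parts) < 2:
                    raise FormatError(f"line {ln}: malformed peak row {line!r}")
                try:
                    peaks.append((float(parts[0]), float(parts[1])))
                except ValueError:
                    raise FormatError(
                        f"line {ln}: non-numeric peak row {line!r}"
                    ) from None
                continue
            if ":" not in line:
                raise FormatError(f"line {ln}: expected 'Key: value', got {line!r}")
            key, _, value = line.partition(":")
            key_n = key.strip().lower().replace(" ", "")
            value = value.strip()
            if key_n == "name":
                if meta or peaks:
                    flush(ln)
                start_line = ln
                meta["name"] = value
            elif key_n == "numpeaks":
                try:
                    expected = int(value)
                except ValueError:
                    raise FormatError(
                        f"line {ln}: Num Peaks is not an integer: {value!r}"
                    ) from None
                if expected < 0:
                    raise FormatError(f"line {ln}: negative Num Peaks")
            elif key_n == "precursormz":
                try:
                    meta["precursormz"] = float(value)
                except ValueError:
                    raise FormatError(
                        f"line {ln}: PrecursorMz is not a number: {value!r}"
                    ) from None
            else:
                meta[key.strip().lower()] = value
        flush(ln if 'ln' in dir() else 0)
    return records


def write_msp(path: str, spectra: Iterable[CentroidSpectrum]) -> None:
    with open(path, "w") as fh:
        for spec in spectra:
            name = spec.metadata.get("name", "unknown")
            fh.write(f"Name: {name}\n")
            if spec.precursor_mz is not None:
                fh.write(f"PrecursorMz: {spec.precursor_mz:.4f}\n")
            for key, value in spec.metadata.items():
                if key == "name":
                    continue
                fh.write(f"{key.capitalize()}: {value}\n")
            fh.write(f"Num Peaks: {len(spec)}\n")
            for m, i in zip(spec.mz, spec.intensity):
                fh.write(f"{m:.4f}\t{i:.1f}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# MGF / mzML via pyteomics
# ---------------------------------------------------------------------------

def _from_pyteomics(entry: dict, source: str) -> CentroidSpectrum:
    mz = np.asarray(entry["m/z array"], dtype=float)
    inten = np.asarray(entry["intensity array"], dtype=float)
    params = entry.get("params", entry)
    precursor = None
    if "pepmass" in params:
        pep = params["pepmass"]
        precursor = float(pep[0] if isinstance(pep, (tuple, list)) else pep)
    elif "precursorList" in entry:
        try:
            sel = entry["precursorList"]["precursor"][0]["selectedIonList"][
                "selectedIon"][0]
            precursor = float(sel.get("selected ion m/z"))
        except (KeyError, IndexError, TypeError):
            precursor = None
    meta = {"source": source}
    title = params.get("title") or entry.get("id")
    if title:
        meta["name"] = str(title)
    return CentroidSpectrum(mz, inten, precursor_mz=precursor, metadata=meta)


def read_mgf(path: str) -> list[CentroidSpectrum]:
    from pyteomics import mgf

    with mgf.MGF(path) as reader:
        return [_from_pyteomics(e, os.path.basename(path)) for e in reader]


def read_mzml(path: str, ms_level: Optional[int] = 2) -> list[CentroidSpectrum]:
    """Read centroided spectra from an mzML file.

    Profile-mode spectra are rejected: this pipeline operates on centroids.
    """
    from pyteomics import mzml

    out = []
    with mzml.MzML(path) as reader:
        for entry in reader:
            if ms_level is not None and entry.get("ms level") != ms_level:
                continue
            if "profile spectrum" in entry:
                raise SpectrumError(
                    f"{path}: spectrum {entry.get('id')} is profile mode; "
                    "centroid the data first"
                )
            out.append(_from_pyteomics(entry, os.path.basename(path)))
    return out
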