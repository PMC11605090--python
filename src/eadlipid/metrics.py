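"""Spectral summary metrics and molecular networking.

Spectral entropy is the Shannon entropy (natural log) of the normalized
intensity distribution.  The modified dot product used for networking
preprocesses both spectra the same way - noise cutoffs, square-root
intensity weighting, rescaling, coarse binning - and is the cosine of the
binned weight vectors, so related spectra with shifted fragments still
overlap through shared bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import entropy as _shannon_entropy

from .spectra import CentroidSpectrum


def spectral_entropy(spectrum: CentroidSpectrum) -> float:
    """Shannon entropy (nats) of the normalized peak intensities."""
    if not len(spectrum):
        return 0.0
    return float(_shannon_entropy(spectrum.intensity))


@dataclass(frozen=True)
class NetworkParams:
    """Preprocessing and similarity parameters for molecular networking."""

    relative_cutoff: float = 0.001     # fraction of the base peak
    absolute_cutoff: float = 50.0      # counts
    power: float = 0.5                 # intensity weighting exponent
    rescale: float = 100.0             # max weight after rescaling
    bin_width: float = 1.0             # Da
    merge_tolerance: float = 0.05      # Da, within-spectrum peak merging
    edge_threshold: float = 0.7        # minimum similarity for an edge


DEFAULT_NETWORK_PARAMS = NetworkParams()


def preprocess_for_network(
    spectrum: CentroidSpectrum, params: NetworkParams = DEFAULT_NETWORK_PARAMS
) -> tuple[np.ndarray, np.ndarray]:
    """(m/z, weight) arrays after cutoff, merging and sqrt rescaling."""
    if not len(spectrum):
        return np.array([]), np.array([])
    base = spectrum.base_peak_intensity
    floor = max(params.absolute_cutoff, params.relative_cutoff * base)
    keep = spectrum.intensity >= floor
    mz, inten = spectrum.mz[keep], spectrum.intensity[keep]
    if mz.size == 0:
        return np.array([]), np.array([])
    merged_mz: list[float] = []
    merged_int: list[float] = []
    for m, i in zip(mz, inten):
        if merged_mz and m - merged_mz[-1] <= params.merge_tolerance:
            # intensity-weighted centroid of the merged pair
            tot = merged_int[-1] + i
            merged_mz[-1] = (merged_mz[-1] * merged_int[-1] + m * i) / tot
            merged_int[-1] = tot
        else:
            merged_mz.append(float(m))
            merged_int.append(float(i))
    w = np.asarray(merged_int) ** params.power
    w *= params.rescale / w.max()
    return np.asarray(merged_mz), w


def modified_dot_product(
    a: CentroidSpectrum,
    b: CentroidSpectrum,
    params: NetworkParams = DEFAULT_NETWORK_PARAMS,
) -> float:
    """Cosine similarity of the preprocessed, coarsely binned spectra."""
    vecs = []
    for spec in (a, b):
        mz, w = preprocess_for_network(spec, params)
        binned: dict[int, float] = {}
        for m, weight in zip(mz, w):
            key = int(np.floor(m / params.bin_width))
            binned[key] = binned.get(key, 0.0) + float(weight)
        vecs.append(binned)
    va, vb = vecs
    if not va or not vb:
        return 0.0
    dot = sum(w * vb[k] for k, w in va.items() if k in vb)
    na = np.sqrt(sum(w * w for w in va.values()))
    nb = np.sqrt(sum(w * w for w in vb.values()))
    return float(min(1.0, dot / (na * nb)))


def build_network(
    spectra: Sequence[CentroidSpectrum],
    params: NetworkParams = DEFAULT_NETWORK_PARAMS,
    labels: Iterable[str] | None = None,
):
    """Similarity network: nodes are spectra, edges modified dot products
    at or above ``params.edge_threshold``.  Returns a networkx Graph."""
    import networkx as nx

    names = (
        list(labels) if labels is not None
        else [s.metadata.get("name", f"spectrum_{i}")
              for i, s in enumerate(spectra)]
    )
    if len(names) != len(spectra):
        raise ValueError("labels length does not match spectra")
    graph = nx.Graph()
    for name, spec in zip(names, spectra):
        graph.add_node(name, precursor_mz=spec.precursor_mz, n_peaks=len(spec))
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            score = modified_dot_product(spectra[i], spectra[j], params)
            if score >= params.edge_threshold:
                graph.add_edge(names[i], names[j], weight=round(score, 4))
    return graph
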