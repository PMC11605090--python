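# eadlipid

Structure-level lipid annotation from electron-activated dissociation (EAD)
tandem mass spectra. Given an MS1-level lipid hypothesis (e.g. `PC 16:0_18:1`)
and a centroided EAD MS/MS spectrum, `eadlipid` enumerates the plausible
fully resolved structures, predicts an in-silico fragmentation spectrum for
each (charge-remote fragmentation ladders plus class/chain/sn-position
diagnostic ions), scores the candidates against the observed spectrum, and
reports an annotation at the deepest structural level the evidence supports —
down to acyl-chain composition, sn-position, and double-bond location.

The package also ships spectral-similarity metrics for molecular networking,
drift-tube ion-mobility feature matching for mass-spectrometry imaging (MSI),
strict MSP/MGF/mzML readers, and seeded synthetic-data generators for
spectra, isomer mixtures, dilution series, and MSI phantoms.

## Quick start (API)

```python
import numpy as np
from eadlipid import (
    parse_lipid_name, build_insilico_spectrum, annotate_spectrum,
    CentroidSpectrum, NoiseModel,
)

# Predict the EAD spectrum of a fully resolved lipid
lipid = parse_lipid_name("PC 16:0/18:1(9)")
ins = build_insilico_spectrum(lipid, "[M+H]+")
mz, intensity = ins.merged_arrays()

# Annotate an observed spectrum against an MS1 hypothesis
observed = CentroidSpectrum(mz, intensity * 1000.0,
                            precursor_mz=ins.precursor_mz)
result = annotate_spectrum(observed, parse_lipid_name("PC 16:0_18:1"),
                           "[M+H]+", noise=NoiseModel())
print(result.name)                      # PC 16:0/18:1(9)
print(result.level)                     # e.g. "double-bond-position"
print(result.best.score.total)          # 0..6 structure score
print(result.best.score.high_confidence)
```

Key entry points:

- `eadlipid.lipids.parse_lipid_name` / `LipidStructure` — shorthand parsing
  at species, molecular-species, sn-resolved, and fully resolved levels.
- `eadlipid.candidates.enumerate_candidates` — candidate structures for an
  MS1 hypothesis (sn permutations, curated double-bond positions, PUFA
  methylene-interrupted families, sphingoid variants).
- `eadlipid.fragmentation.build_insilico_spectrum` — CRF ladder with the
  rule-based intensity model plus the diagnostic-ion plan.
- `eadlipid.annotate.annotate_spectrum` — full scoring and decision tree.
- `eadlipid.metrics` — spectral entropy, modified dot product,
  `build_network` (networkx molecular network).
- `eadlipid.msi` — sparse 2-D (m/z × drift time) feature accumulation and
  picking, CCS calibration, reference matching, ion images.
- `eadlipid.synth` — seeded synthetic spectra, mixtures, dilution series,
  and MSI phantoms.
- `eadlipid.io` — strict MSP reader/writer, MGF and mzML readers
  (via pyteomics).

## Command line

All functionality is exposed through the `eadlipid` command:

```bash
eadlipid mass --formula C5H15NO4P --charge 1
eadlipid parse "PC 16:0/18:1(9)"
eadlipid insilico --lipid "PC 16:0/18:1(9)" --adduct "[M+H]+" --out popc.msp
eadlipid preprocess --in scans.msp --bin 0.05 --out averaged.msp
eadlipid annotate --in spectra.msp --adducts "[M+H]+,[M+Na]+" --out hits.tsv
eadlipid network --in library.msp --threshold 0.7 --out edges.tsv
eadlipid msi-match --features feats.tsv --db reference.tsv --out matches.tsv
eadlipid msi-image --spots spots.tsv --mz 760.5851 --ccs 281.4 --out image.tsv
eadlipid simulate spectrum --lipid "PC 16:0/18:1(9)" --seed 7 --out out/
eadlipid simulate msi --seed 7 --out out/
```

`eadlipid annotate` reads the MS1 hypothesis from each MSP entry's `Name`
field, picks the adduct whose precursor m/z matches, and writes a ranked TSV
with the per-component score breakdown. Scoring parameters can be overridden
with `--config settings.toml` (or `.yaml`).

## Method summary

Scoring assigns one point each for class, chain-composition, and sn-position
evidence, plus up to three points of double-bond evidence (template cosine,
matched-peak fraction, V-shape bonus at the cleavage flanking a double bond,
and a PUFA H-gain bonus), for a maximum of 6.0; totals above 4.8 are flagged
high-confidence. Candidates whose amplified diagnostic CRF peaks are absent
are eliminated, and the reported name is truncated to the structural level
the passing checks actually support. See [docs/methods.md](docs/methods.md)
for the full fragmentation rules, intensity model, scoring equations, and
decision tree.

## Tests

```bash
pytest -q
```

The suite is fully offline and deterministic (seeded generators,
derandomized property tests).
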