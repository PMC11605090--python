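# Methods

This document specifies the rules implemented by `eadlipid`: the
charge-remote fragmentation (CRF) mass rule, the rule-based intensity model,
the diagnostic-ion plans, the candidate space, the noise model, the scoring
equations and decision tree, the spectral-similarity metrics, and the
ion-mobility/MSI matching rules.

## 1. Masses and adducts

All masses are monoisotopic, computed from CODATA/NIST atomic masses
(`eadlipid.elements`). Ion m/z uses the electron-corrected convention
`m/z = (M + Σ adduct gains − Σ adduct losses − z·m_e) / z`. Supported
positive-mode adducts: `[M+H]+`, `[M+Na]+`, `[M+NH4]+`, `[M+K]+`.

## 2. Lipid model and nomenclature

`LipidStructure` holds a subclass (head group + backbone linkage) and a
tuple of chains, each an `AcylChain(carbons, double_bonds, db_positions,
oh_positions, linkage)` where linkage is acyl, alkyl (O-), or alkenyl (P-).
Shorthand names are parsed at four levels:

- species — `PC 34:1` (summed carbons:double bonds);
- molecular species — `PC 16:0_18:1` (chains known, sn unknown);
- sn-resolved — `PC 16:0/18:1` (slash = sn order fixed);
- fully resolved — `PC 16:0/18:1(9)` (double-bond positions), with
  sphingoid hydroxyls as `SM 18:1(4);(1OH,3OH)/16:0`.

27 subclasses support in-depth (positional) annotation: PC, PE, PG, PI, PS,
BMP, LPC, LPE, LPG, LPI, LPS, PC O-, PC P-, PE O-, PE P-, SM, Cer, HexCer,
Hex2Cer, SHexCer, DG, TG, CAR, DGTS, DGTA, LDGTS, LDGTA.

## 3. Charge-remote fragmentation rule

EAD cleaves each C(k)–C(k+1) bond of a fatty chain (counting from the
carbonyl/head end, k = 1 … n−1) without moving the charge. For a chain of n
carbons the neutral loss at cleavage k is the terminal fragment

```
C_(n−k) H_(2(n−k)+1−2d) O_h        (radical loss)
```

where `d` is the number of chain double bonds at position ≥ k — a double
bond between carbons k and k+1 spans the cleavage and counts toward the
loss — and `h` is the number of hydroxyls at position > k. Each cleavage
yields a triplet of product ions:

- **radical**: `precursor − mass(loss)`;
- **H-loss**: radical − 1.0078250 (one hydrogen atom lighter);
- **H-gain**: radical + 1.0078250.

Consequently consecutive cleavages differ by CH₂ (14.0157 Da) along a
saturated stretch, but crossing a double bond (k = p → p+1) shifts the
ladder by a bare carbon (12.0000 Da): the loss drops one C while regaining
the two H the double bond had removed. This 12 Da step is the positional
signature read by the scoring stage. Ladder ions below a low-mass cutoff
(default 150 Da) are discarded.

## 4. Rule-based intensity model

Each cleavage triplet (H-loss, radical, H-gain) receives model intensities
by abundance class. With `p` a double-bond position of the chain:

| context | H-loss | radical | H-gain | class labels |
|---|---|---|---|---|
| plain cleavage | 0.5 | 1 | 0.05 | plain |
| k = p (on the bond) | 0.25 | 0.5 | 0.05 | cc_low |
| k = p − 2 | 2 | 4 | 0.05 | cc_high_hloss |
| k = p + 2 | 4 | 2 | 0.05 | cc_high_radical |
| k = p + 1, PUFA pair | — | — | 4.0 | cc_pufa_high |

Rules apply in order: high rules, then the on-bond suppression, then the
PUFA override. The PUFA H-gain amplification fires at k = p + 1 for every
methylene-interrupted pair (p, p+3) of a chain with ≥ 3 double bonds. The
amplified peaks flanking a suppressed on-bond cleavage produce the
characteristic V-shape intensity profile centred on each double bond.

Diagnostic ions (section 5) that coincide with a CRF ladder m/z (within
1e-4 Da) stay in the detection plan but are not duplicated as peaks, so a
model spectrum never double-counts intensity.

## 5. Diagnostic-ion plans

For each candidate and adduct a `DiagnosticPlan` defines requirement groups
per role (class, chain, sn-position); a group is a list of alternative m/z
values, and a role passes iff every group has a detected member.

**Glycerophospholipids.** Class: the protonated head-group ion (e.g.
phosphocholine 184.0733) required, with optional head-related satellites
and the head-group neutral loss. Chain: per acyl chain, one group of
[precursor − fatty acid, precursor − ketene]; ether chains are exempt.
sn-position: the sn1 ion, a neutral loss of the sn1 chain plus the glycerol
C1 methylene — `C(n+1)H(2n+1−2d)O(2+h)` for acyl sn1 (alkyl/alkenyl
variants analogously). This rule is practical at `[M+H]+` only for
choline-headed lipids (PC, PC O-, PC P-, LPC) and lyso forms; other
glycerolipids require `[M+Na]+`. Lyso species instead confirm sn2-lyso via
the CH₃O loss. Betaine lipids DGTS/DGTA are discriminated by the
204.1230 (C₉H₁₈NO₄⁺) and 236.1492 (C₁₀H₂₂NO₅⁺) markers with an intensity
ratio rule — DGTS: I(236) > I(204); DGTA: I(204) > I(236) — applied to
diacyl forms only, because a lyso species' single-chain ketene loss is
isobaric with the 236 marker; LDGTS/LDGTA require marker presence only.

**Sphingolipids.** Class: head-group neutral losses (water, hexose,
dihexose, sulfohexose; SM additionally 184.0733). Chain: the sphingoid-base
ion plus the N-acyl ketene loss. Position: hydroxyl markers — the CRF
radical at k = q for each backbone hydroxyl at q ≥ 2 (the C1 hydroxyl is
structurally uninformative).

**Glycerolipids and others.** MG/DG/TG class: any fatty-acid neutral loss.
CAR class: the 85.0284 acylium-related marker; chain: the acylium ion.

## 6. Candidate space

From an MS1 hypothesis, `enumerate_candidates` expands every structural
dimension left unspecified: chain splits of a species-level composition,
sn permutations of a molecular species, curated double-bond positions for
MUFAs (Δ6, Δ7, Δ9, Δ11, Δ13), methylene-interrupted families for PUFAs
(n−3/n−6/n−9 series as appropriate to the chain), and sphingoid
hydroxylation variants. Fully resolved input passes through unchanged.

## 7. Spectrum processing and noise model

Profile data must be centroided upstream; readers reject profile mzML.
Accumulation averages repeated scans on a fixed m/z grid (default 0.05 Da)
with optional background subtraction. The noise model removes peaks with
intensity strictly below a threshold (default 11 counts) and defines a
detection floor `max(threshold, 2 × min retained intensity)`; a peak is
*detected* only if a match within tolerance (default 0.025 Da) exceeds the
floor strictly. At the default settings an intensity of 22 over a minimum
of 11 is therefore undetected and 23 is detected.

## 8. Scoring

Each surviving candidate receives

```
total = class + chain + position + double_bond          (max 6.0)
double_bond = rdp + mpp + vshape + pufa                 (max 3.0)
```

- **class / chain / position** ∈ {0, 1}: the diagnostic roles of section 5.
  A position role with no applicable rule scores 1 vacuously unless the
  candidate claims an sn assignment that the adduct cannot test (then 0).
- **rdp** ∈ [0, 1]: reverse dot product — the √intensity-weighted cosine
  between the CRF template and the matched experimental intensities, over
  the template's merged peak list.
- **mpp** ∈ [0, 1]: fraction of template peaks with an experimental match
  within tolerance.
- **vshape** ∈ {0, 0.5}: 0.5 iff the mean detected intensity of the
  amplified (cc-high) peaks strictly exceeds 1.5 × the mean detected
  intensity of the suppressed (cc-low) peaks.
- **pufa** ∈ {0, 0.5}: 0.5 iff the mean detected PUFA H-gain intensity
  strictly exceeds 3 × the mean of the other detected H-gain peaks.

Totals strictly above 4.8 are flagged **high confidence**.

**Presence check (elimination).** For each chain the amplified cc-high
peaks are required to be detected; a candidate expecting more than five
such peaks on a chain tolerates one missing, otherwise none. A candidate
missing more is eliminated from in-depth ranking regardless of its score —
a positional claim whose signature peaks are absent is not reported.

## 9. Decision tree

1. Noise-filter the spectrum; enumerate and score all candidates.
2. No candidate passes the class check → **unannotated**.
3. Class passes but no candidate passes the chain check → **species-level**
   annotation (subclass + summed composition only).
4. Otherwise rank chain-passing, non-eliminated candidates by
   (total desc, rdp desc, name); fall back to chain-passing candidates if
   elimination empties the pool.
5. The reported name strips structural detail the evidence did not
   confirm: sn order if the position role failed, double-bond positions if
   the presence check failed, hydroxyl positions for sphingolipids if the
   hydroxyl markers failed.

## 10. Spectral metrics and networking

Spectral entropy is the Shannon entropy (nats) of the normalised intensity
vector (`scipy.stats.entropy`); a single peak scores 0 and n equal peaks
score ln n. The modified dot product preprocesses each spectrum with
absolute (50) and relative (0.1 %) intensity cutoffs, merges peaks within
0.05 Da by intensity-weighted centroid, square-root transforms and rescales
to 100, bins at 1.0 Da, and returns the cosine similarity (clamped to
≤ 1.0). `build_network` connects spectra whose similarity exceeds an edge
threshold (default 0.7) in a networkx graph.

## 11. Ion mobility and MSI

Drift-tube data are calibrated by a linear single-field relation
`CCS = slope × drift_time + intercept`. Imaging events are accumulated into
a sparse 2-D histogram over (m/z, drift time) bins (0.005 Da × 0.01 ms);
features are strict local maxima over the 8-neighbourhood above a minimum
intensity. Features are matched to a reference table (name, adduct, m/z,
CCS) within tolerances of 0.01 Da and 20 Å², ranked by combined normalised
distance. Ion images gate pixel events at 0.01 Da and 5 Å² around a target
and return a 2-D intensity array.

## 12. Synthetic data

Seeded generators produce: single-lipid spectra (model peaks scaled to a
base peak, lognormal intensity jitter, Gaussian m/z jitter, dropout of
plain CRF peaks only, and a uniform low-intensity chemical-noise barcode);
weighted isomer mixtures; dilution series over a constant noise floor; and
MSI phantoms placing known lipids in deterministic geometric regions with
per-pixel jittered events plus sparse sub-threshold noise.
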