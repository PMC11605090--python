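"""Structure annotation: diagnostic evaluation, scoring and the decision tree.

A candidate's total score is the sum of four components:

* class score (0/1)    - subclass diagnostic ions detected;
* chain score (0/1)    - every chain's neutral-loss/fragment group detected;
* position score (0/1) - sn (glycerolipids) or hydroxyl (sphingolipids)
  markers detected; 1 when the candidate has no positional freedom;
* double-bond score (0..3) - reverse dot product against the in-silico CRF
  template, plus matched-peak fraction, plus a 0.5 V-shape bonus (amplified
  "C=C high" peaks clearly above the "C=C low" valley) and a 0.5 PUFA bonus
  (amplified H-gain at methylene-interrupted positions).

The maximum is 6.0; totals above ``HIGH_CONFIDENCE_THRESHOLD`` (4.8) are
flagged high-confidence.  Candidates missing two or more of their expected
amplified double-bond peaks on any chain are eliminated outright (one miss
is tolerated for chains expecting more than five such peaks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .adducts import Adduct, get_adduct
from .candidates import CandidateConfig, DEFAULT_CONFIG, enumerate_candidates
from .fragmentation import (
    DEFAULT_LOW_MASS_CUTOFF,
    DiagnosticPlan,
    InSilicoSpectrum,
    Series,
    AbundanceClass,
    build_insilico_spectrum,
    diagnostic_plan,
)
from .lipids import AnnotationLevel, LipidStructure
from .spectra import (
    CentroidSpectrum,
    DEFAULT_MZ_TOLERANCE,
    NoiseModel,
    is_detected,
    matched_intensity,
)

HIGH_CONFIDENCE_THRESHOLD = 4.8
VSHAPE_RATIO = 1.5
PUFA_RATIO = 3.0
PRESENCE_ALLOWANCE_MIN_PEAKS = 5   # > this many expected highs tolerates 1 miss


@dataclass(frozen=True)
class DiagnosticOutcome:
    class_passed: bool
    chain_passed: bool
    position_passed: bool
    detected: dict[str, list[float]]   # role -> detected m/z values
    missing: dict[str, list[float]]    # role -> required-but-missing m/z


def evaluate_diagnostics(
    plan: DiagnosticPlan,
    spectrum: CentroidSpectrum,
    noise: Optional[NoiseModel] = None,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
    structure: Optional[LipidStructure] = None,
) -> DiagnosticOutcome:
    """Apply the per-role requirement groups of a diagnostic plan.

    A group passes when any of its alternative ions is detected; a role
    passes when all its groups do.  The position role passes vacuously when
    the candidate has no positional freedom, and fails when it does but the
    adduct offers no practical positional cleavage.
    """
    floor = noise.detection_floor(spectrum) if noise is not None else None

    def hit(mz: float) -> bool:
        return is_detected(spectrum, mz, tolerance=tolerance, floor=floor)

    detected: dict[str, list[float]] = {"class": [], "chain": [], "position": []}
    missing: dict[str, list[float]] = {"class": [], "chain": [], "position": []}

    def run(groups: Sequence[Sequence[float]], role: str) -> bool:
        ok = True
        for group in groups:
            hits = [mz for mz in group if hit(mz)]
            detected[role].extend(hits)
            if not hits:
                missing[role].extend(group)
                ok = False
        return ok

    class_passed = run(plan.class_groups, "class")
    if class_passed and plan.ratio_rule is not None:
        greater, lesser = plan.ratio_rule
        class_passed = (
            matched_intensity(spectrum, greater, tolerance)
            > matched_intensity(spectrum, lesser, tolerance)
        )
    chain_passed = run(plan.chain_groups, "chain")
    if plan.position_groups:
        position_passed = run(plan.position_groups, "position")
    elif (structure is not None and structure.has_sn_dimension
          and not plan.position_applicable):
        position_passed = False
    else:
        position_passed = True
    return DiagnosticOutcome(class_passed, chain_passed, position_passed,
                             detected, missing)


@dataclass(frozen=True)
class PresenceCheck:
    passed: bool
    per_chain: dict[int, tuple[int, int]]   # slot -> (missing, expected)


def cc_presence_check(
    insilico: InSilicoSpectrum,
    spectrum: CentroidSpectrum,
    noise: Optional[NoiseModel] = None,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
) -> PresenceCheck:
    """Require the amplified double-bond peaks of every chain to be present.

    Per chain, at most one expected "C=C high" peak may be undetected, and
    only when that chain expects more than ``PRESENCE_ALLOWANCE_MIN_PEAKS``
    of them; otherwise the candidate is eliminated.
    """
    floor = noise.detection_floor(spectrum) if noise is not None else None
    per_chain: dict[int, tuple[int, int]] = {}
    passed = True
    by_slot: dict[int, list[float]] = {}
    for ion in insilico.expected_cc_high():
        by_slot.setdefault(ion.chain_ref, []).append(ion.mz)
    for slot, mzs in sorted(by_slot.items()):
        miss = sum(
            0 if is_detected(spectrum, mz, tolerance=tolerance, floor=floor)
            else 1
            for mz in mzs
        )
        per_chain[slot] = (miss, len(mzs))
        allowed = 1 if len(mzs) > PRESENCE_ALLOWANCE_MIN_PEAKS else 0
        if miss > allowed:
            passed = False
    return PresenceCheck(passed, per_chain)


# ---------------------------------------------------------------------------
# Double-bond score components
# ---------------------------------------------------------------------------

def reverse_dot_product(
    insilico: InSilicoSpectrum,
    spectrum: CentroidSpectrum,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
) -> float:
    """Cosine similarity restricted to the in-silico CRF template peaks.

    Library and experimental intensities are square-root weighted;
    experimental intensity is the nearest tolerance match (0 if absent).
    """
    lib_mz, lib_int = insilico.merged_arrays(insilico.crf_subset())
    if lib_mz.size == 0:
        return 0.0
    exp = np.array([matched_intensity(spectrum, m, tolerance) for m in lib_mz])
    wl, we = np.sqrt(lib_int), np.sqrt(exp)
    denom = math.sqrt(float(wl @ wl) * float(we @ we))
    if denom == 0:
        return 0.0
    return float(wl @ we) / denom


def matched_peaks_percentage(
    insilico: InSilicoSpectrum,
    spectrum: CentroidSpectrum,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
) -> float:
    """Fraction of in-silico CRF template peaks with an experimental match."""
    lib_mz, _ = insilico.merged_arrays(insilico.crf_subset())
    if lib_mz.size == 0:
        return 0.0
    hits = sum(1 for m in lib_mz if spectrum.nearest_peak(m, tolerance) is not None)
    return hits / lib_mz.size


def _class_intensities(
    insilico: InSilicoSpectrum,
    spectrum: CentroidSpectrum,
    classes: frozenset | set,
    series: Optional[set] = None,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
    invert_class: bool = False,
) -> list[float]:
    out = []
    for ion in insilico.crf_subset():
        in_class = ion.abundance_class in classes
        if invert_class:
            in_class = not in_class
        if not in_class:
            continue
        if series is not None and ion.series not in series:
            continue
        i = matched_intensity(spectrum, ion.mz, tolerance)
        if i > 0:
            out.append(i)
    return out


def vshape_bonus(
    insilico: InSilicoSpectrum,
    spectrum: CentroidSpectrum,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
) -> float:
    """0.5 when the amplified peaks clearly dominate the valley peaks.

    Mean experimental intensity of the detected "C=C high" peaks must
    strictly exceed ``VSHAPE_RATIO`` times the mean of the detected "C=C
    low" peaks; candidates without positioned double bonds score 0.
    """
    highs = _class_intensities(
        insilico, spectrum,
        {AbundanceClass.CC_HIGH_HLOSS, AbundanceClass.CC_HIGH_RADICAL,
         AbundanceClass.CC_PUFA_HIGH},
        tolerance=tolerance,
    )
    lows = _class_intensities(
        insilico, spectrum, {AbundanceClass.CC_LOW}, tolerance=tolerance
    )
    if not highs or not lows:
        return 0.0
    return 0.5 if float(np.mean(highs)) > VSHAPE_RATIO * float(np.mean(lows)) else 0.0


def pufa_hgain_bonus(
    insilico: InSilicoSpectrum,
    spectrum: CentroidSpectrum,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
) -> float:
    """0.5 when methylene-interrupted H-gain peaks are clearly amplified.

    Mean experimental intensity of the detected PUFA H-gain peaks must
    strictly exceed ``PUFA_RATIO`` times the mean of the other detected
    H-gain peaks; 0 for candidates without a qualifying polyunsaturated
    chain.
    """
    pufa = _class_intensities(
        insilico, spectrum, {AbundanceClass.CC_PUFA_HIGH},
        series={Series.H_GAIN}, tolerance=tolerance,
    )
    if not pufa:
        return 0.0
    other = _class_intensities(
        insilico, spectrum, {AbundanceClass.CC_PUFA_HIGH},
        series={Series.H_GAIN}, tolerance=tolerance, invert_class=True,
    )
    if not other:
        return 0.0
    return 0.5 if float(np.mean(pufa)) > PUFA_RATIO * float(np.mean(other)) else 0.0


# ---------------------------------------------------------------------------
# Candidate scoring and decision tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreBreakdown:
    class_score: float
    chain_score: float
    position_score: float
    rdp: float
    mpp: float
    vshape: float
    pufa: float
    eliminated: bool = False

    @property
    def double_bond_score(self) -> float:
        return self.rdp + self.mpp + self.vshape + self.pufa

    @property
    def total(self) -> float:
        return (self.class_score + self.chain_score + self.position_score
                + self.double_bond_score)

    @property
    def high_confidence(self) -> bool:
        return self.total > HIGH_CONFIDENCE_THRESHOLD


@dataclass(frozen=True)
class ScoredCandidate:
    structure: LipidStructure
    score: ScoreBreakdown
    outcome: DiagnosticOutcome
    presence: PresenceCheck


def score_candidate(
    candidate: LipidStructure,
    adduct: Adduct | str,
    spectrum: CentroidSpectrum,
    noise: Optional[NoiseModel] = None,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
    low_mass_cutoff: float = DEFAULT_LOW_MASS_CUTOFF,
) -> ScoredCandidate:
    """Score one fully resolved candidate against an experimental spectrum."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    insilico = build_insilico_spectrum(candidate, adduct, low_mass_cutoff)
    outcome = evaluate_diagnostics(insilico.plan, spectrum, noise, tolerance,
                                   structure=candidate)
    presence = cc_presence_check(insilico, spectrum, noise, tolerance)
    score = ScoreBreakdown(
        class_score=1.0 if outcome.class_passed else 0.0,
        chain_score=1.0 if outcome.chain_passed else 0.0,
        position_score=1.0 if outcome.position_passed else 0.0,
        rdp=reverse_dot_product(insilico, spectrum, tolerance),
        mpp=matched_peaks_percentage(insilico, spectrum, tolerance),
        vshape=vshape_bonus(insilico, spectrum, tolerance),
        pufa=pufa_hgain_bonus(insilico, spectrum, tolerance),
        eliminated=not presence.passed,
    )
    return ScoredCandidate(candidate, score, outcome, presence)


def _strip_unconfirmed(
    candidate: LipidStructure, sn_ok: bool, db_ok: bool, oh_ok: bool
) -> LipidStructure:
    """Reported structure with unconfirmed detail removed."""
    chains = []
    for c in candidate.chains:
        if c is None:
            chains.append(None)
            continue
        if not db_ok and c.db_positions is not None:
            c = replace(c, db_positions=None)
        if not oh_ok and c.oh_positions is not None:
            c = replace(c, oh_positions=None)
        chains.append(c)
    sn = candidate.sn_assigned and (sn_ok or not candidate.has_sn_dimension)
    return LipidStructure(candidate.subclass, tuple(chains), sn_assigned=sn)


@dataclass
class AnnotationResult:
    status: str                               # annotated | species | unannotated
    adduct: Adduct
    annotation: Optional[LipidStructure]      # confirmed-detail structure
    level: Optional[AnnotationLevel]
    best: Optional[ScoredCandidate]
    ranked: list[ScoredCandidate] = field(default_factory=list)

    @property
    def name(self) -> Optional[str]:
        return self.annotation.format() if self.annotation else None


def annotate_spectrum(
    spectrum: CentroidSpectrum,
    query: LipidStructure,
    adduct: Adduct | str,
    noise: Optional[NoiseModel] = None,
    config: CandidateConfig = DEFAULT_CONFIG,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
    low_mass_cutoff: float = DEFAULT_LOW_MASS_CUTOFF,
) -> AnnotationResult:
    """Run the annotation decision tree for one precursor.

    The query fixes subclass and chain totals (from MS1); candidates are
    enumerated within the constrained positional space, eliminated on
    missing amplified peaks, scored, and ranked.  Failure of the class
    diagnostics leaves the precursor unannotated; failure of every
    candidate's chain diagnostics demotes the result to species level; the
    reported structure of the winning candidate keeps only the detail its
    evidence confirmed.
    """
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    if noise is not None:
        spectrum = noise.filter(spectrum)
    candidates = enumerate_candidates(query, config)
    scored = [
        score_candidate(c.structure, adduct, spectrum, noise, tolerance,
                        low_mass_cutoff)
        for c in candidates
    ]
    if not scored:
        return AnnotationResult("unannotated", adduct, None, None, None, [])
    if not any(s.outcome.class_passed for s in scored):
        return AnnotationResult("unannotated", adduct, None, None, None, scored)
    chain_ok = [s for s in scored if s.outcome.chain_passed]
    if not chain_ok:
        species = LipidStructure(
            query.subclass, (), species_totals=(
                query.total_carbons, query.total_double_bonds,
                query.total_hydroxyls,
            ),
        )
        return AnnotationResult(
            "species", adduct, species, species.level,
            None, _rank(scored),
        )
    survivors = [s for s in chain_ok if not s.score.eliminated] or chain_ok
    ranked = _rank(survivors)
    best = ranked[0]
    is_sp = best.structure.info.category == "SP"
    pos_ok = best.outcome.position_passed
    db_ok = best.presence.passed and any(
        c is not None and c.db_positions for c in best.structure.chains
    )
    reported = _strip_unconfirmed(
        best.structure,
        sn_ok=pos_ok and not is_sp,
        db_ok=db_ok,
        oh_ok=pos_ok if is_sp else True,
    )
    return AnnotationResult("annotated", adduct, reported, reported.level,
                            best, ranked)


def _rank(scored: list[ScoredCandidate]) -> list[ScoredCandidate]:
    return sorted(
        scored,
        key=lambda s: (-s.score.total, -s.score.rdp, s.structure.format()),
    )
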