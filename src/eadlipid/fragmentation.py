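"""In-silico EAD spectrum generation.

Charge-remote fragmentation (CRF) produces three ions per carbon-carbon
cleavage of an acyl chain — H-loss, radical and H-gain, spaced by one
hydrogen-atom mass.  The radical ion retaining k chain carbons is the
precursor minus the neutral radical C_(n-k) H_(2(n-k)+1-2d) O_h, where d
counts the chain's double bonds at positions >= k (a bond spanning the
cleavage belongs to the lost part) and h its hydroxyls beyond carbon k.

Relative intensities follow a fixed abundance model: (H-loss, radical,
H-gain) = (0.5, 1, 0.05) for plain positions, (0.25, 0.5, 0.05) at the
double-bond valley ("C=C low"), (2.0, 4.0, 0.05) two carbons below the bond
(H-loss increase) and (4.0, 2.0, 0.05) two carbons above (radical increase);
the H-gain factor rises to 4.0 at the methylene carbon between
methylene-interrupted double bonds of polyunsaturated chains ("C=C PUFA
high").  Subclass diagnostic ions (polar-head ions, neutral losses of
chains, sn- and OH-position markers) are appended from a per-subclass table.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .adducts import Adduct, get_adduct
from .chains import AcylChain, ChainKind
from .elements import H_ATOM_MASS, ElementalFormula, formula
from .lipids import LipidStructure

#: m/z below which CRF series ions are not reported (instrument TOF start
#: mass); diagnostic ions are exempt.
DEFAULT_LOW_MASS_CUTOFF = 150.0

#: Minimum count of chain double bonds for PUFA H-gain behaviour.
PUFA_MIN_DOUBLE_BONDS = 3


class Series(str, enum.Enum):
    H_LOSS = "H-loss"
    RADICAL = "radical"
    H_GAIN = "H-gain"
    DIAGNOSTIC = "diagnostic"
    NEUTRAL_LOSS_ION = "neutral-loss-ion"


class AbundanceClass(str, enum.Enum):
    PLAIN = "plain"
    CC_LOW = "cc_low"
    CC_HIGH_HLOSS = "cc_high_hloss"
    CC_HIGH_RADICAL = "cc_high_radical"
    CC_PUFA_HIGH = "cc_pufa_high"
    DIAGNOSTIC = "diagnostic"


CC_HIGH_CLASSES = frozenset(
    {AbundanceClass.CC_HIGH_HLOSS, AbundanceClass.CC_HIGH_RADICAL,
     AbundanceClass.CC_PUFA_HIGH}
)

#: (H-loss, radical, H-gain) model intensity triplets.
PLAIN_TRIPLET = (0.5, 1.0, 0.05)
LOW_TRIPLET = (0.25, 0.5, 0.05)
HLOSS_INCREASE_TRIPLET = (2.0, 4.0, 0.05)
RADICAL_INCREASE_TRIPLET = (4.0, 2.0, 0.05)
PUFA_HGAIN_FACTOR = 4.0

_SERIES_INDEX = {Series.H_LOSS: 0, Series.RADICAL: 1, Series.H_GAIN: 2}


@dataclass(frozen=True)
class FragmentIon:
    mz: float
    series: Series
    chain_ref: Optional[int] = None      # slot index in the candidate
    position: Optional[int] = None       # carbons retained (k)
    abundance_class: AbundanceClass = AbundanceClass.PLAIN
    model_intensity: float = 1.0
    label: str = ""
    role: Optional[str] = None           # "class" | "chain" | "position"
    required: bool = False

    def __post_init__(self) -> None:
        if self.model_intensity <= 0:
            raise ValueError("model intensity must be positive")


class FragmentationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# CRF series
# ---------------------------------------------------------------------------

def crf_loss_formula(chain: AcylChain, k: int) -> ElementalFormula:
    """Neutral radical lost when the chain is cleaved retaining k carbons."""
    n = chain.carbons
    if not 1 <= k <= n - 1:
        raise FragmentationError(
            f"cleavage position k={k} outside 1..{n - 1} for {chain.format()}"
        )
    if not chain.db_resolved:
        raise FragmentationError(
            f"chain {chain.format()} has unresolved double bonds"
        )
    d = sum(1 for p in (chain.db_positions or ()) if p >= k)
    h = sum(1 for q in (chain.oh_positions or ()) if q > k)
    m = n - k
    return ElementalFormula({"C": m, "H": 2 * m + 1 - 2 * d, "O": h})


def crf_fragment_mz(
    structure: LipidStructure,
    adduct: Adduct | str,
    chain: AcylChain | int,
    k: int,
    series: Series | str,
) -> float:
    """m/z of one CRF ion of a resolved candidate.

    ``chain`` may be a slot index or the chain object itself; ``series`` one
    of H-loss / radical / H-gain.
    """
    if isinstance(chain, int):
        chain = structure.chains[chain]
    series = Series(series)
    precursor = structure.precursor_mz(adduct)
    radical = precursor - crf_loss_formula(chain, k).mass
    if series is Series.RADICAL:
        return radical
    if series is Series.H_LOSS:
        return radical - H_ATOM_MASS
    if series is Series.H_GAIN:
        return radical + H_ATOM_MASS
    raise FragmentationError(f"{series} is not a CRF series")


def classify_abundance(
    chain: AcylChain,
) -> dict[tuple[int, Series], AbundanceClass]:
    """Label every (cleavage position, series) of a resolved chain.

    Per double bond at p: the valley ("C=C low") sits on the H-loss and
    radical ions at k=p; the amplified "C=C high" peaks are the H-loss ion
    at k=p-2 and the radical ion at k=p+2.  For chains with at least
    ``PUFA_MIN_DOUBLE_BONDS`` double bonds, the H-gain ion at k=p+1 of every
    methylene-interrupted bond pair (p, p+3) is "C=C PUFA high".
    """
    if not chain.db_resolved:
        raise FragmentationError(
            f"chain {chain.format()} has unresolved double bonds"
        )
    n = chain.carbons
    labels: dict[tuple[int, Series], AbundanceClass] = {}
    for k in range(1, n):
        for s in (Series.H_LOSS, Series.RADICAL, Series.H_GAIN):
            labels[(k, s)] = AbundanceClass.PLAIN
    positions = chain.db_positions or ()
    for p in positions:
        if 1 <= p - 2:
            labels[(p - 2, Series.H_LOSS)] = AbundanceClass.CC_HIGH_HLOSS
        if p + 2 <= n - 1:
            labels[(p + 2, Series.RADICAL)] = AbundanceClass.CC_HIGH_RADICAL
    for p in positions:
        labels[(p, Series.H_LOSS)] = AbundanceClass.CC_LOW
        labels[(p, Series.RADICAL)] = AbundanceClass.CC_LOW
    if chain.double_bonds >= PUFA_MIN_DOUBLE_BONDS:
        for p in positions:
            if p + 3 in positions and p + 1 <= n - 1:
                labels[(p + 1, Series.H_GAIN)] = AbundanceClass.CC_PUFA_HIGH
    return labels


def _intensity_triplets(chain: AcylChain) -> dict[int, tuple[float, float, float]]:
    """Model (H-loss, radical, H-gain) intensities per cleavage position."""
    n = chain.carbons
    trip = {k: list(PLAIN_TRIPLET) for k in range(1, n)}
    positions = chain.db_positions or ()
    for p in positions:
        if p - 2 >= 1:
            trip[p - 2][:] = HLOSS_INCREASE_TRIPLET
        if p + 2 <= n - 1:
            trip[p + 2][:] = RADICAL_INCREASE_TRIPLET
    for p in positions:  # the valley overrides adjacent-bond increases
        trip[p][:] = LOW_TRIPLET
    if chain.double_bonds >= PUFA_MIN_DOUBLE_BONDS:
        for p in positions:
            if p + 3 in positions and p + 1 <= n - 1:
                trip[p + 1][2] = PUFA_HGAIN_FACTOR
    return {k: tuple(v) for k, v in trip.items()}


def crf_ions(
    structure: LipidStructure,
    adduct: Adduct | str,
    low_mass_cutoff: float = DEFAULT_LOW_MASS_CUTOFF,
) -> list[FragmentIon]:
    """All CRF series ions over every chain of a resolved candidate."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    precursor = structure.precursor_mz(adduct)
    ions: list[FragmentIon] = []
    for slot, chain in enumerate(structure.chains):
        if chain is None:
            continue
        labels = classify_abundance(chain)
        trips = _intensity_triplets(chain)
        for k in range(1, chain.carbons):
            radical = precursor - crf_loss_formula(chain, k).mass
            for s in (Series.H_LOSS, Series.RADICAL, Series.H_GAIN):
                mz = radical + (_SERIES_INDEX[s] - 1) * H_ATOM_MASS
                if mz < low_mass_cutoff:
                    continue
                ions.append(
                    FragmentIon(
                        mz=mz,
                        series=s,
                        chain_ref=slot,
                        position=k,
                        abundance_class=labels[(k, s)],
                        model_intensity=trips[k][_SERIES_INDEX[s]],
                        label=f"{s.value} at {chain.format()} C{k}",
                    )
                )
    ions.sort(key=lambda i: i.mz)
    return ions


# ---------------------------------------------------------------------------
# Diagnostic ions
# ---------------------------------------------------------------------------

_PH_C3H4 = formula("C3H4")
_PH_C2H2O = formula("C2H2O")
_PROTON = formula("H", 1)
_H2O = formula("H2O")
_CH2 = formula("CH2")
_CH3O = formula("CH3O")      # "NL of CH2OH" of sn2-lysophospholipids
_HEXOSE_NL = formula("C6H10O5")
_DIHEXOSE_NL = formula("C12H20O10")
_SHEX_NL = formula("C6H10O8S")
_CAR_CLASS_ION = formula("C4H5O2", 1)       # m/z 85.028
_DGTX_LIGHT = formula("C9H18NO4", 1)        # m/z 204.123
_DGTX_HEAVY = formula("C10H22NO5", 1)       # m/z 236.149

#: (subclass display, adduct) pairs with a practical sn rule on the glycerol
#: C1-C2 homolytic cleavage; sodium adducts are practical across GP/GL.
_SN_PRACTICAL_PROTONATED = {"PC", "PC O-", "PC P-", "LPC"}


@dataclass
class DiagnosticPlan:
    """Diagnostic ions of a candidate plus the decision-tree requirements.

    Each role (class / chain / position) holds requirement groups: a group
    passes when at least one of its alternative ions is detected and a role
    passes when all its groups do.  ``ratio_rule`` carries the DGTS/DGTA
    head-marker intensity-order requirement as (greater_mz, lesser_mz).
    """

    ions: list[FragmentIon] = field(default_factory=list)
    class_groups: list[list[float]] = field(default_factory=list)
    chain_groups: list[list[float]] = field(default_factory=list)
    position_groups: list[list[float]] = field(default_factory=list)
    position_applicable: bool = True
    ratio_rule: Optional[tuple[float, float]] = None


def _acyl_nl_losses(chain: AcylChain) -> tuple[ElementalFormula, ElementalFormula]:
    """(fatty-acid loss, ketene loss) neutral compositions of an acyl chain."""
    n, d, h = chain.carbons, chain.double_bonds, chain.hydroxyls
    fa = ElementalFormula({"C": n, "H": 2 * n - 2 * d, "O": 2 + h})
    ketene = ElementalFormula({"C": n, "H": 2 * n - 2 - 2 * d, "O": 1 + h})
    return fa, ketene


def _sn1_ch2_loss(chain: AcylChain) -> ElementalFormula:
    """Neutral loss of the sn1 chain plus one backbone CH2 (C1-C2 cleavage)."""
    n, d, h = chain.carbons, chain.double_bonds, chain.hydroxyls
    if chain.kind is ChainKind.ACYL:
        # acyloxy radical + CH2: C_(n+1) H_(2n+1-2d) O_(2+h)
        return ElementalFormula({"C": n + 1, "H": 2 * n + 1 - 2 * d, "O": 2 + h})
    # O-alkyl / alkenyl ether: alkoxy radical + CH2
    extra = 0 if chain.kind is ChainKind.ALKYL else -2
    return ElementalFormula(
        {"C": n + 1, "H": 2 * n + 3 - 2 * d + extra, "O": 1 + h}
    )


def _ion(mz, label, role, required, series=Series.DIAGNOSTIC, chain_ref=None):
    return FragmentIon(
        mz=mz, series=series, chain_ref=chain_ref,
        abundance_class=AbundanceClass.DIAGNOSTIC, model_intensity=1.0,
        label=label, role=role, required=required,
    )


def diagnostic_plan(
    structure: LipidStructure, adduct: Adduct | str
) -> DiagnosticPlan:
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    info = structure.info
    if info.category not in ("GP", "SP", "GL", "FA"):
        raise FragmentationError(f"unsupported subclass {structure.subclass}")
    precursor = structure.precursor_mz(adduct)
    plan = DiagnosticPlan()
    chains = structure.chains

    def add(ion: FragmentIon, group: Optional[list[list[float]]] = None,
            new_group: bool = True) -> None:
        plan.ions.append(ion)
        if group is not None:
            if new_group or not group:
                group.append([ion.mz])
            else:
                group[-1].append(ion.mz)

    sn_practical = (
        adduct.name == "[M+Na]+"
        or (adduct.name == "[M+H]+"
            and (structure.subclass_display() in _SN_PRACTICAL_PROTONATED
                 or info.lyso))
    )

    if info.category == "GP":
        ph = info.head
        ph_ion = (ph + _PROTON).mz
        add(_ion(ph_ion, f"polar head {ph.hill()}+H", "class", True),
            plan.class_groups)
        add(_ion((ph + _PH_C3H4 + _PROTON).mz, "PH+C3H4", "class", False))
        add(_ion((ph + _PH_C2H2O + _PROTON).mz, "PH+C2H2O", "class", False))
        add(_ion(precursor - ph.mass, "NL of polar head", "class", False,
                 series=Series.NEUTRAL_LOSS_ION))
        for slot, chain in enumerate(chains):
            if chain is None or chain.kind not in (ChainKind.ACYL, ChainKind.NACYL):
                continue
            fa, ketene = _acyl_nl_losses(chain)
            add(_ion(precursor - fa.mass, f"NL of {chain.format()} (acid)",
                     "chain", True, Series.NEUTRAL_LOSS_ION, slot),
                plan.chain_groups, new_group=True)
            add(_ion(precursor - ketene.mass, f"NL of {chain.format()} (ketene)",
                     "chain", True, Series.NEUTRAL_LOSS_ION, slot),
                plan.chain_groups, new_group=False)
        plan.position_applicable = sn_practical
        if sn_practical and structure.sn_assigned:
            if info.lyso:
                if chains and chains[0] is not None:      # sn1-lyso
                    loss = _sn1_ch2_loss(chains[0])
                    add(_ion(precursor - loss.mass,
                             f"NL of sn1 {chains[0].format()}+CH2",
                             "position", True, Series.NEUTRAL_LOSS_ION, 0),
                        plan.position_groups)
                elif len(chains) > 1 and chains[1] is not None:  # sn2-lyso
                    add(_ion(precursor - _CH3O.mass, "NL of CH2OH (sn2-LPL)",
                             "position", True, Series.NEUTRAL_LOSS_ION, 1),
                        plan.position_groups)
            elif chains and chains[0] is not None:
                loss = _sn1_ch2_loss(chains[0])
                add(_ion(precursor - loss.mass,
                         f"NL of sn1 {chains[0].format()}+CH2",
                         "position", True, Series.NEUTRAL_LOSS_ION, 0),
                    plan.position_groups)

    elif info.category == "SP":
        sph, nacyl = chains[0], chains[1] if len(chains) > 1 else None
        if structure.subclass == "SM":
            sm_head = formula("C5H14NO4P")
            add(_ion((sm_head + _PROTON).mz, "phosphocholine head", "class",
                     True), plan.class_groups)
        elif structure.subclass == "Cer":
            add(_ion(precursor - _H2O.mass, "NL of H2O", "class", True,
                     Series.NEUTRAL_LOSS_ION), plan.class_groups)
        elif structure.subclass == "HexCer":
            add(_ion(precursor - _HEXOSE_NL.mass, "NL of hexose", "class",
                     True, Series.NEUTRAL_LOSS_ION), plan.class_groups)
        elif structure.subclass == "Hex2Cer":
            add(_ion(precursor - _DIHEXOSE_NL.mass, "NL of dihexose", "class",
                     True, Series.NEUTRAL_LOSS_ION), plan.class_groups)
            add(_ion(precursor - _HEXOSE_NL.mass, "NL of hexose", "class",
                     False, Series.NEUTRAL_LOSS_ION))
        elif structure.subclass == "SHexCer":
            add(_ion(precursor - _SHEX_NL.mass, "NL of sulfohexose", "class",
                     True, Series.NEUTRAL_LOSS_ION), plan.class_groups)
        if sph is not None:
            waters = min(2, sph.hydroxyls)
            spb = sph.residue_formula() + _PROTON - _H2O * waters
            add(_ion(spb.mz, f"sphingobase {sph.format()} ion", "chain", True,
                     chain_ref=0), plan.chain_groups, new_group=True)
        if nacyl is not None:
            _, ketene = _acyl_nl_losses(nacyl)
            add(_ion(precursor - ketene.mass,
                     f"NL of N-acyl {nacyl.format()}", "chain", True,
                     Series.NEUTRAL_LOSS_ION, 1),
                plan.chain_groups, new_group=True)
        # OH-position markers: CRF radical cleavage at each hydroxylated
        # carbon beyond C1 (the head-linked oxygen carries no information).
        for slot, chain in enumerate(chains):
            if chain is None or not chain.oh_positions:
                continue
            for q in chain.oh_positions:
                if q < 2 or q > chain.carbons - 1:
                    continue
                mz = precursor - crf_loss_formula(chain, q).mass
                add(_ion(mz, f"OH marker at {chain.format()} C{q}",
                         "position", True, Series.DIAGNOSTIC, slot),
                    plan.position_groups)

    elif info.category == "GL":
        if structure.subclass in ("DGTS", "DGTA", "LDGTS", "LDGTA"):
            light, heavy = _DGTX_LIGHT.mz, _DGTX_HEAVY.mz
            lo = _ion(light, "betaine head marker 204", "class", True)
            hi = _ion(heavy, "betaine head marker 236", "class", True)
            # The 204/236 intensity order separates DGTS from DGTA only for
            # the diacyl classes: in lyso species the ketene neutral loss of
            # the single chain lands exactly on the 236 marker and confounds
            # the ratio, so LDGTS/LDGTA require presence only.
            if structure.subclass == "DGTS":
                plan.ratio_rule = (heavy, light)
                hi = FragmentIon(**{**hi.__dict__, "model_intensity": 2.0})
            elif structure.subclass == "DGTA":
                plan.ratio_rule = (light, heavy)
                lo = FragmentIon(**{**lo.__dict__, "model_intensity": 2.0})
            add(lo, plan.class_groups, new_group=True)
            add(hi, plan.class_groups, new_group=True)
        elif structure.subclass == "CAR":
            add(_ion(_CAR_CLASS_ION.mz, "carnitine marker 85", "class", True),
                plan.class_groups)
        else:  # MG / DG / TG: any acyl neutral loss marks the glyceride class
            group: list[float] = []
            for slot, chain in enumerate(chains):
                if chain is None:
                    continue
                fa, _ = _acyl_nl_losses(chain)
                ion = _ion(precursor - fa.mass,
                           f"NL of {chain.format()} (acid)", "class", True,
                           Series.NEUTRAL_LOSS_ION, slot)
                plan.ions.append(ion)
                group.append(ion.mz)
            if group:
                plan.class_groups.append(group)
        for slot, chain in enumerate(chains):
            if chain is None:
                continue
            if structure.subclass == "CAR":
                n, d = chain.carbons, chain.double_bonds
                acylium = ElementalFormula(
                    {"C": n, "H": 2 * n - 1 - 2 * d, "O": 1}, 1
                )
                add(_ion(acylium.mz, f"{chain.format()} acylium", "chain",
                         True, chain_ref=slot),
                    plan.chain_groups, new_group=True)
                _, ketene = _acyl_nl_losses(chain)
                add(_ion(precursor - ketene.mass,
                         f"NL of {chain.format()} (ketene)", "chain", True,
                         Series.NEUTRAL_LOSS_ION, slot),
                    plan.chain_groups, new_group=False)
            else:
                fa, ketene = _acyl_nl_losses(chain)
                add(_ion(precursor - fa.mass,
                         f"NL of {chain.format()} (acid)", "chain", True,
                         Series.NEUTRAL_LOSS_ION, slot),
                    plan.chain_groups, new_group=True)
                add(_ion(precursor - ketene.mass,
                         f"NL of {chain.format()} (ketene)", "chain", True,
                         Series.NEUTRAL_LOSS_ION, slot),
                    plan.chain_groups, new_group=False)
        lyso_gl = structure.subclass in ("LDGTS", "LDGTA", "MG")
        plan.position_applicable = sn_practical or lyso_gl
        if structure.sn_assigned and plan.position_applicable:
            if lyso_gl:
                if chains and chains[0] is not None:
                    loss = _sn1_ch2_loss(chains[0])
                    add(_ion(precursor - loss.mass,
                             f"NL of sn1 {chains[0].format()}+CH2",
                             "position", True, Series.NEUTRAL_LOSS_ION, 0),
                        plan.position_groups)
                elif len(chains) > 1 and chains[1] is not None:
                    add(_ion(precursor - _CH3O.mass, "NL of CH2OH (sn2)",
                             "position", True, Series.NEUTRAL_LOSS_ION, 1),
                        plan.position_groups)
            elif chains and chains[0] is not None and sn_practical:
                loss = _sn1_ch2_loss(chains[0])
                add(_ion(precursor - loss.mass,
                         f"NL of sn1 {chains[0].format()}+CH2",
                         "position", True, Series.NEUTRAL_LOSS_ION, 0),
                    plan.position_groups)

    else:  # FA
        add(_ion(precursor - _H2O.mass, "NL of H2O", "class", True,
                 Series.NEUTRAL_LOSS_ION), plan.class_groups)

    plan.ions.sort(key=lambda i: i.mz)
    return plan


def diagnostic_ions(
    structure: LipidStructure, adduct: Adduct | str
) -> list[FragmentIon]:
    """Subclass diagnostic ions of a candidate (class/chain/position roles)."""
    return diagnostic_plan(structure, adduct).ions


# ---------------------------------------------------------------------------
# Full in-silico spectrum
# ---------------------------------------------------------------------------

@dataclass
class InSilicoSpectrum:
    candidate: LipidStructure
    adduct: Adduct
    precursor_mz: float
    peaks: list[FragmentIon]            # sorted by m/z, unmerged
    plan: DiagnosticPlan

    def crf_subset(self) -> list[FragmentIon]:
        """The acyl-chain CRF ions (the spectral-fitting template)."""
        crf = {Series.H_LOSS, Series.RADICAL, Series.H_GAIN}
        return [p for p in self.peaks if p.series in crf]

    def expected_cc_high(self) -> list[FragmentIon]:
        return [p for p in self.peaks if p.abundance_class in CC_HIGH_CLASSES]

    def merged_arrays(
        self, peaks: Optional[list[FragmentIon]] = None, tol: float = 1e-4
    ) -> tuple[np.ndarray, np.ndarray]:
        """(m/z, intensity) arrays with peaks within ``tol`` Da summed."""
        src = sorted(self.peaks if peaks is None else peaks, key=lambda p: p.mz)
        mzs: list[float] = []
        ints: list[float] = []
        for p in src:
            if mzs and p.mz - mzs[-1] <= tol:
                ints[-1] += p.model_intensity
            else:
                mzs.append(p.mz)
                ints.append(p.model_intensity)
        return np.asarray(mzs), np.asarray(ints)


def _near_any(mz: float, sorted_mzs: list[float], tol: float) -> bool:
    import bisect

    i = bisect.bisect_left(sorted_mzs, mz)
    for j in (i - 1, i):
        if 0 <= j < len(sorted_mzs) and abs(sorted_mzs[j] - mz) <= tol:
            return True
    return False


def build_insilico_spectrum(
    structure: LipidStructure,
    adduct: Adduct | str,
    low_mass_cutoff: float = DEFAULT_LOW_MASS_CUTOFF,
) -> InSilicoSpectrum:
    """Theoretical EAD spectrum of a fully resolved candidate."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    if not structure.fully_resolved:
        raise FragmentationError(
            f"{structure.format()} is not fully resolved "
            f"(level {structure.level.value})"
        )
    peaks = crf_ions(structure, adduct, low_mass_cutoff)
    plan = diagnostic_plan(structure, adduct)
    # A diagnostic that coincides with a CRF ion (e.g. the hydroxyl-position
    # markers, which are CRF radical cleavages) stays in the detection plan
    # but must not duplicate the peak, or the spectrum would carry intensity
    # the CRF scoring template does not.
    crf_mzs = sorted(p.mz for p in peaks)
    extra = [
        ion for ion in plan.ions
        if not _near_any(ion.mz, crf_mzs, 1e-4)
    ]
    peaks = sorted(peaks + extra, key=lambda p: p.mz)
    return InSilicoSpectrum(
        candidate=structure,
        adduct=adduct,
        precursor_mz=structure.precursor_mz(adduct),
        peaks=peaks,
        plan=plan,
    )
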