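"""Lipid structures, shorthand-name parsing and precursor m/z.

Shorthand follows shorthand-nomenclature conventions used across lipidomics:
``/`` separates chains with known positions on the backbone (sn-assigned),
``_`` separates an unordered chain bag (molecular-species level), delta
double-bond positions sit in parentheses, and ``;O``/``;O2`` count hydroxyls.
E/Z descriptors in positions are accepted and discarded.

Backbone compositions per subclass live in a versioned table below; a
subclass absent from the table fails loudly rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

from .adducts import Adduct, get_adduct
from .chains import AcylChain, ChainKind, ChainParseError
from .elements import ElementalFormula, formula

BACKBONE_TABLE_VERSION = "1.0"


class AnnotationLevel(str, Enum):
    SPECIES = "species"
    MOLECULAR_SPECIES = "molecular_species"
    SN_RESOLVED = "sn_resolved"
    OH_RESOLVED = "oh_resolved"
    DB_RESOLVED = "db_resolved"
    SN_DB_RESOLVED = "sn_db_resolved"
    OH_DB_RESOLVED = "oh_db_resolved"


@dataclass(frozen=True)
class SubclassInfo:
    name: str
    category: str                 # "GP", "SP", "GL", "FA"
    backbone: ElementalFormula    # neutral backbone / head extension (SP)
    n_chains: int                 # chains actually esterified/amidated
    n_slots: int                  # backbone positions a chain could occupy
    head: Optional[ElementalFormula] = None   # GP polar-head neutral (PH)
    lyso: bool = False


def _info(name, category, backbone, n_chains, n_slots, head=None, lyso=False):
    return SubclassInfo(
        name, category, formula(backbone), n_chains, n_slots,
        formula(head) if head else None, lyso,
    )


#: Neutral backbone compositions; chains are added as residues (acid - H2O for
#: esters/amides).  For sphingolipids the entry is the head extension beyond
#: the free ceramide assembly (sphingoid base + N-acyl residue).
SUBCLASSES: dict[str, SubclassInfo] = {
    # --- glycerophospholipids -----------------------------------------
    "PC":  _info("PC",  "GP", "C8H20NO6P", 2, 2, head="C5H14NO4P"),
    "PE":  _info("PE",  "GP", "C5H14NO6P", 2, 2, head="C2H8NO4P"),
    "PG":  _info("PG",  "GP", "C6H15O8P",  2, 2, head="C3H9O6P"),
    "PI":  _info("PI",  "GP", "C9H19O11P", 2, 2, head="C6H13O9P"),
    "PS":  _info("PS",  "GP", "C6H14NO8P", 2, 2, head="C3H8NO6P"),
    "BMP": _info("BMP", "GP", "C6H15O8P",  2, 2, head="C3H9O6P"),
    "LPC": _info("LPC", "GP", "C8H20NO6P", 1, 2, head="C5H14NO4P", lyso=True),
    "LPE": _info("LPE", "GP", "C5H14NO6P", 1, 2, head="C2H8NO4P", lyso=True),
    "LPG": _info("LPG", "GP", "C6H15O8P",  1, 2, head="C3H9O6P", lyso=True),
    "LPI": _info("LPI", "GP", "C9H19O11P", 1, 2, head="C6H13O9P", lyso=True),
    "LPS": _info("LPS", "GP", "C6H14NO8P", 1, 2, head="C3H8NO6P", lyso=True),
    # --- sphingolipids (backbone = head extension beyond ceramide) ----
    "Cer":     _info("Cer",     "SP", "H0",        2, 2),
    "SM":      _info("SM",      "SP", "C5H12NO3P", 2, 2),
    "HexCer":  _info("HexCer",  "SP", "C6H10O5",   2, 2),
    "Hex2Cer": _info("Hex2Cer", "SP", "C12H20O10", 2, 2),
    "SHexCer": _info("SHexCer", "SP", "C6H10O8S",  2, 2),
    # --- glycerolipids -------------------------------------------------
    "MG":    _info("MG",    "GL", "C3H8O3",    1, 3),
    "DG":    _info("DG",    "GL", "C3H8O3",    2, 3),
    "TG":    _info("TG",    "GL", "C3H8O3",    3, 3),
    "DGTS":  _info("DGTS",  "GL", "C10H21NO5", 2, 2),
    "DGTA":  _info("DGTA",  "GL", "C10H21NO5", 2, 2),
    "LDGTS": _info("LDGTS", "GL", "C10H21NO5", 1, 2, lyso=True),
    "LDGTA": _info("LDGTA", "GL", "C10H21NO5", 1, 2, lyso=True),
    "CAR":   _info("CAR",   "GL", "C7H15NO3",  1, 1),
    # --- fatty acyls ---------------------------------------------------
    "FA":    _info("FA",    "FA", "H2O",       1, 1),
}

#: The 27 subclasses with in-depth (position-level) annotation support.
IN_DEPTH_SUBCLASSES: tuple[str, ...] = (
    "PC", "PE", "PG", "PI", "PS", "BMP",
    "LPC", "LPE", "LPG", "LPI", "LPS",
    "PC O-", "PC P-", "PE O-", "PE P-",
    "SM", "Cer", "HexCer", "Hex2Cer", "SHexCer",
    "DG", "TG", "CAR", "DGTS", "DGTA", "LDGTS", "LDGTA",
)


class LipidParseError(ValueError):
    """Malformed or unsupported lipid shorthand."""


@dataclass(frozen=True)
class LipidStructure:
    """A lipid at any resolution level, from species to fully resolved.

    ``chains`` is slot-ordered when ``sn_assigned`` (``None`` marks an empty
    backbone position of a lyso species), otherwise an unordered bag.  A
    species-level structure has ``chains=()`` and carries only totals.
    """

    subclass: str
    chains: tuple[Optional[AcylChain], ...] = ()
    sn_assigned: bool = False
    species_totals: Optional[tuple[int, int, int]] = None  # (C, DB, OH)
    adduct_hint: Optional[str] = None

    def __post_init__(self) -> None:
        if self.subclass not in SUBCLASSES:
            raise LipidParseError(
                f"unknown lipid subclass {self.subclass!r}; supported: "
                f"{sorted(SUBCLASSES)}"
            )
        if self.species_totals is None and not self.chains:
            raise LipidParseError("structure needs chains or species totals")

    # ---- accessors -----------------------------------------------------
    @property
    def info(self) -> SubclassInfo:
        return SUBCLASSES[self.subclass]

    @property
    def present_chains(self) -> tuple[AcylChain, ...]:
        return tuple(c for c in self.chains if c is not None)

    @property
    def is_species_level(self) -> bool:
        return self.species_totals is not None

    @property
    def is_ether(self) -> bool:
        return any(
            c.kind in (ChainKind.ALKYL, ChainKind.ALKENYL)
            for c in self.present_chains
        )

    @property
    def total_carbons(self) -> int:
        if self.species_totals:
            return self.species_totals[0]
        return sum(c.carbons for c in self.present_chains)

    @property
    def total_double_bonds(self) -> int:
        if self.species_totals:
            return self.species_totals[1]
        return sum(c.double_bonds for c in self.present_chains)

    @property
    def total_hydroxyls(self) -> int:
        if self.species_totals:
            return self.species_totals[2]
        return sum(c.hydroxyls for c in self.present_chains)

    def subclass_display(self) -> str:
        """Subclass name including the ether designation, e.g. ``PC O-``."""
        for c in self.present_chains:
            if c.kind is ChainKind.ALKYL:
                return f"{self.subclass} O-"
            if c.kind is ChainKind.ALKENYL:
                return f"{self.subclass} P-"
        return self.subclass

    # ---- resolution dimensions -----------------------------------------
    @property
    def has_sn_dimension(self) -> bool:
        """Whether distinct backbone positions are chemically distinguishable."""
        info = self.info
        if info.category == "SP":
            return False  # sphingoid vs N-acyl roles are fixed
        if info.lyso:
            return True   # sn1- vs sn2-lyso isomerism
        distinct = len({c.format() for c in self.present_chains})
        return info.n_chains > 1 and distinct > 1

    @property
    def has_oh_dimension(self) -> bool:
        return self.total_hydroxyls > 0

    @property
    def sn_resolved(self) -> bool:
        return (not self.has_sn_dimension) or self.sn_assigned

    @property
    def db_positions_resolved(self) -> bool:
        return not self.is_species_level and all(
            c.db_resolved for c in self.present_chains
        )

    @property
    def oh_positions_resolved(self) -> bool:
        return not self.is_species_level and all(
            c.oh_resolved for c in self.present_chains
        )

    @property
    def fully_resolved(self) -> bool:
        return (
            not self.is_species_level
            and self.sn_resolved
            and self.db_positions_resolved
            and self.oh_positions_resolved
        )

    @property
    def level(self) -> AnnotationLevel:
        if self.is_species_level:
            return AnnotationLevel.SPECIES
        db = self.db_positions_resolved and self.total_double_bonds > 0
        if self.info.category == "SP":
            pos = self.oh_positions_resolved and self.has_oh_dimension
            if pos and db:
                return AnnotationLevel.OH_DB_RESOLVED
            if pos:
                return AnnotationLevel.OH_RESOLVED
        else:
            pos = self.sn_assigned and self.has_sn_dimension
            if pos and db:
                return AnnotationLevel.SN_DB_RESOLVED
            if pos:
                return AnnotationLevel.SN_RESOLVED
        if db:
            return AnnotationLevel.DB_RESOLVED
        return AnnotationLevel.MOLECULAR_SPECIES

    # ---- composition ----------------------------------------------------
    def neutral_formula(self) -> ElementalFormula:
        info = self.info
        if self.is_species_level:
            c, d, h = self.species_totals
            n = info.n_chains
            if info.category == "SP":
                # sphingoid base + (n-1) N-acyl residues (one carbonyl O each)
                return info.backbone + ElementalFormula(
                    {"C": c, "H": 2 * c + 3 - 2 * d - 2 * (n - 1), "N": 1,
                     "O": h + (n - 1)}
                )
            return info.backbone + ElementalFormula(
                {"C": c, "H": 2 * c - 2 * n - 2 * d, "O": n + h}
            )
        out = info.backbone
        for chain in self.present_chains:
            out = out + chain.residue_formula()
        return out

    def precursor_mz(self, adduct: Adduct | str) -> float:
        if isinstance(adduct, str):
            adduct = get_adduct(adduct)
        return adduct.mz(self.neutral_formula())

    # ---- text form -------------------------------------------------------
    def format(self) -> str:
        if self.is_species_level:
            c, d, h = self.species_totals
            oh = f";O{h if h > 1 else ''}" if h else ""
            return f"{self.subclass} {c}:{d}{oh}"
        sep = "/" if self.sn_assigned else "_"
        toks = [("0:0" if c is None else c.format()) for c in self.chains]
        return f"{self.subclass} {sep.join(toks)}"

    def __str__(self) -> str:
        return self.format()

    def with_adduct_hint(self, adduct: str) -> "LipidStructure":
        return replace(self, adduct_hint=adduct)


def parse_lipid_name(text: str) -> LipidStructure:
    """Parse shorthand such as ``PC 16:0/18:1(9)`` or ``Cer 18:1;O2/16:0``."""
    text = text.strip()
    if not text:
        raise LipidParseError("empty lipid name")
    parts = text.split(None, 1)
    if len(parts) != 2:
        raise LipidParseError(f"missing chain descriptor in {text!r} (position {len(text)})")
    subclass, rest = parts
    if subclass not in SUBCLASSES:
        raise LipidParseError(
            f"unknown subclass token {subclass!r} at position 0 in {text!r}"
        )
    info = SUBCLASSES[subclass]
    if "/" in rest and "_" in rest:
        raise LipidParseError(f"mixed '/' and '_' separators in {text!r}")
    sep = "/" if "/" in rest else "_" if "_" in rest else None
    tokens = rest.split(sep) if sep else [rest]

    def parse_tok(i: int, tok: str, kind=None) -> Optional[AcylChain]:
        if tok == "0:0":
            return None
        try:
            return AcylChain.parse(tok, kind=kind)
        except ChainParseError as exc:
            raise LipidParseError(
                f"bad chain descriptor {tok!r} (chain {i + 1}) in {text!r}: {exc}"
            ) from exc

    if info.category == "SP":
        if len(tokens) == 1:
            c = parse_tok(0, tokens[0], ChainKind.SPHINGOID)
            if c is None:
                raise LipidParseError(f"empty sphingoid base in {text!r}")
            # a single token is species level for a two-chain sphingolipid
            return LipidStructure(
                subclass, (), species_totals=(c.carbons, c.double_bonds, c.hydroxyls)
            )
        if len(tokens) != info.n_chains:
            raise LipidParseError(
                f"{subclass} expects {info.n_chains} chains, got {len(tokens)}"
            )
        sph = parse_tok(0, tokens[0], ChainKind.SPHINGOID)
        nac = parse_tok(1, tokens[1], ChainKind.NACYL)
        if sph is None or nac is None:
            raise LipidParseError(f"sphingolipid chains cannot be 0:0 in {text!r}")
        return LipidStructure(subclass, (sph, nac), sn_assigned=True)

    chains = tuple(parse_tok(i, t) for i, t in enumerate(tokens))
    n_present = sum(c is not None for c in chains)
    if len(tokens) == 1 and info.n_chains > 1:
        c = chains[0]
        if c is None:
            raise LipidParseError(f"no chains in {text!r}")
        return LipidStructure(
            subclass, (), species_totals=(c.carbons, c.double_bonds, c.hydroxyls)
        )
    if n_present != info.n_chains:
        raise LipidParseError(
            f"{subclass} expects {info.n_chains} chain(s), got {n_present} in {text!r}"
        )
    if sep == "/" or len(tokens) == 1:
        expected_tokens = info.n_slots if info.lyso else info.n_chains
        if sep == "/" and len(tokens) not in (info.n_chains, expected_tokens):
            raise LipidParseError(
                f"{subclass} expects {expected_tokens} slots, got {len(tokens)}"
            )
        sn_assigned = sep == "/"
        return LipidStructure(subclass, chains, sn_assigned=sn_assigned)
    return LipidStructure(subclass, tuple(c for c in chains if c is not None))


def format_lipid_name(structure: LipidStructure) -> str:
    return structure.format()
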