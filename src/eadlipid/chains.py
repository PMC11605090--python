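"""Acyl/alkyl/sphingoid chain descriptors.

Double-bond positions are delta positions: position p denotes a C=C between
carbon p and p+1 counted from the carbonyl (or amino) carbon C1.  Hydroxyl
positions use the same carbon numbering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .elements import ElementalFormula


class ChainKind(str, Enum):
    ACYL = "acyl"
    ALKYL = "alkyl"        # O- ether
    ALKENYL = "alkenyl"    # P- vinyl ether (plasmalogen)
    SPHINGOID = "sphingoid"
    NACYL = "n-acyl"


_KIND_PREFIX = {"O-": ChainKind.ALKYL, "P-": ChainKind.ALKENYL}
_PREFIX_FOR_KIND = {ChainKind.ALKYL: "O-", ChainKind.ALKENYL: "P-"}

_CHAIN_RE = re.compile(
    r"^(?P<prefix>[OP]-)?(?P<c>\d+):(?P<d>\d+)"
    r"(?:\((?P<db>[\dEZ,]+)\))?"
    r"(?:;(?:O(?P<oh>\d*)|\((?P<ohpos>[\dOH,]+)\)))?$"
)


class ChainParseError(ValueError):
    """Malformed chain descriptor."""


@dataclass(frozen=True)
class AcylChain:
    carbons: int
    double_bonds: int = 0
    kind: ChainKind = ChainKind.ACYL
    db_positions: Optional[tuple[int, ...]] = None
    hydroxyls: int = 0
    oh_positions: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise ValueError("chain needs at least one carbon")
        if self.db_positions is not None:
            ps = tuple(self.db_positions)
            if len(ps) != self.double_bonds:
                raise ValueError(
                    f"{len(ps)} double-bond positions but count {self.double_bonds}"
                )
            if any(not (1 <= p <= self.carbons - 1) for p in ps):
                raise ValueError(f"double-bond position out of range: {ps}")
            if any(b - a < 2 for a, b in zip(ps, ps[1:])):
                raise ValueError(f"double-bond positions closer than 2: {ps}")
            if list(ps) != sorted(ps):
                raise ValueError("double-bond positions must be ascending")
            object.__setattr__(self, "db_positions", ps)
        if self.oh_positions is not None:
            ps = tuple(sorted(self.oh_positions))
            if len(ps) != self.hydroxyls:
                raise ValueError(
                    f"{len(ps)} hydroxyl positions but count {self.hydroxyls}"
                )
            if any(not (1 <= p <= self.carbons) for p in ps):
                raise ValueError(f"hydroxyl position out of range: {ps}")
            object.__setattr__(self, "oh_positions", ps)

    # ---- resolution state ---------------------------------------------
    @property
    def db_resolved(self) -> bool:
        return self.double_bonds == 0 or self.db_positions is not None

    @property
    def oh_resolved(self) -> bool:
        return self.hydroxyls == 0 or self.oh_positions is not None

    # ---- composition ---------------------------------------------------
    def residue_formula(self) -> ElementalFormula:
        """Contribution of this chain to the neutral lipid formula.

        An esterified/amidated acyl n:d;Oh contributes C_n H_(2n-2-2d) O_(1+h)
        (the fatty acid minus water); an O-alkyl ether contributes C_n
        H_(2n-2d) O_h; an alkenyl (plasmalogen) chain carries one extra,
        uncounted vinyl double bond at the ether; a sphingoid base n:d;Om
        contributes its full formula C_n H_(2n+3-2d) N O_m.
        """
        n, d, h = self.carbons, self.double_bonds, self.hydroxyls
        if self.kind in (ChainKind.ACYL, ChainKind.NACYL):
            return ElementalFormula({"C": n, "H": 2 * n - 2 - 2 * d, "O": 1 + h})
        if self.kind is ChainKind.ALKYL:
            return ElementalFormula({"C": n, "H": 2 * n - 2 * d, "O": h})
        if self.kind is ChainKind.ALKENYL:
            return ElementalFormula({"C": n, "H": 2 * n - 2 - 2 * d, "O": h})
        if self.kind is ChainKind.SPHINGOID:
            return ElementalFormula({"C": n, "H": 2 * n + 3 - 2 * d, "N": 1, "O": h})
        raise AssertionError(self.kind)

    # ---- text form -----------------------------------------------------
    @classmethod
    def parse(cls, text: str, kind: Optional[ChainKind] = None) -> "AcylChain":
        m = _CHAIN_RE.match(text.strip())
        if not m:
            raise ChainParseError(f"malformed chain descriptor: {text!r}")
        prefix = m.group("prefix")
        if prefix and kind in (None, ChainKind.ACYL):
            kind = _KIND_PREFIX[prefix]
        elif kind is None:
            kind = ChainKind.ACYL
        carbons = int(m.group("c"))
        dcount = int(m.group("d"))
        db_positions = None
        if m.group("db") is not None:
            db_positions = tuple(
                int(re.sub(r"[EZ]", "", tok)) for tok in m.group("db").split(",")
            )
        oh = 0
        oh_positions = None
        if m.group("oh") is not None:
            oh = int(m.group("oh")) if m.group("oh") else 1
        elif m.group("ohpos") is not None:
            oh_positions = tuple(
                int(tok.replace("OH", "")) for tok in m.group("ohpos").split(",")
            )
            oh = len(oh_positions)
        return cls(carbons, dcount, kind, db_positions, oh, oh_positions)

    def format(self) -> str:
        s = _PREFIX_FOR_KIND.get(self.kind, "")
        s += f"{self.carbons}:{self.double_bonds}"
        if self.db_positions is not None and self.double_bonds:
            s += "(" + ",".join(str(p) for p in self.db_positions) + ")"
        if self.hydroxyls:
            if self.oh_positions is not None:
                s += ";(" + ",".join(f"{p}OH" for p in self.oh_positions) + ")"
            else:
                s += ";O" + (str(self.hydroxyls) if self.hydroxyls > 1 else "")
        return s

    def __str__(self) -> str:
        return self.format()
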