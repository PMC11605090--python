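"""Elemental-formula arithmetic and monoisotopic mass computation.

Masses of charged species are electron-mass corrected: a +1 cation is one
electron lighter than the sum of its atoms.  All printed fragment values in
positive-mode lipidomics (e.g. the phosphocholine head ion at m/z 184.073)
match only with this correction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

# CODATA/IUPAC monoisotopic atomic masses, Da (6+ d.p.)
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.007825032,
    "N": 14.003074005,
    "O": 15.994914620,
    "P": 30.973761998,
    "S": 31.972071174,
    "Na": 22.989769282,
    "K": 38.963706487,
    "Li": 7.016003437,
}

ELECTRON_MASS = 0.000548580
PROTON_MASS = ATOMIC_MASS["H"] - ELECTRON_MASS  # 1.007276
H_ATOM_MASS = ATOMIC_MASS["H"]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownElementError(ValueError):
    """Raised when a formula references an element outside the supported set."""


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition with an integer charge.

    Counts are non-negative; subtraction that would drive any element
    negative raises ``ValueError`` (element conservation is enforced, not
    silently clipped).
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        clean = {}
        for sym, n in self.counts.items():
            if sym not in ATOMIC_MASS:
                raise UnknownElementError(f"unknown element symbol: {sym!r}")
            if n < 0:
                raise ValueError(f"negative count for element {sym}: {n}")
            if n:
                clean[sym] = int(n)
        object.__setattr__(self, "counts", clean)

    # ---- constructors -------------------------------------------------
    @classmethod
    def parse(cls, text: str, charge: int = 0) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``C9H18NO4``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"malformed formula {text!r} at offset {pos}")
            pos = m.end()
            sym = m.group(1)
            if sym not in ATOMIC_MASS:
                raise UnknownElementError(f"unknown element symbol: {sym!r}")
            counts[sym] = counts.get(sym, 0) + (int(m.group(2)) if m.group(2) else 1)
        if pos != len(text):
            raise ValueError(f"malformed formula {text!r} at offset {pos}")
        return cls(counts, charge)

    # ---- arithmetic ---------------------------------------------------
    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for sym, n in other.counts.items():
            counts[sym] = counts.get(sym, 0) + n
        return ElementalFormula(counts, self.charge + other.charge)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for sym, n in other.counts.items():
            new = counts.get(sym, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative {sym} count "
                    f"({self.hill()} - {other.hill()})"
                )
            counts[sym] = new
        return ElementalFormula(counts, self.charge - other.charge)

    def __mul__(self, k: int) -> "ElementalFormula":
        return ElementalFormula({s: n * k for s, n in self.counts.items()}, self.charge * k)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(sorted(self.counts.items()))

    # ---- properties ---------------------------------------------------
    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da, electron-mass corrected for the charge."""
        m = sum(ATOMIC_MASS[s] * n for s, n in self.counts.items())
        return m - self.charge * ELECTRON_MASS

    @property
    def mz(self) -> float:
        """m/z of the species (mass over |charge|); charge must be nonzero."""
        if self.charge == 0:
            raise ValueError("m/z undefined for a neutral species")
        return self.mass / abs(self.charge)

    def with_charge(self, charge: int) -> "ElementalFormula":
        return ElementalFormula(dict(self.counts), charge)

    def hill(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        order = sorted(self.counts, key=lambda s: (s != "C", s != "H", s))
        return "".join(f"{s}{self.counts[s] if self.counts[s] != 1 else ''}" for s in order)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        q = f"{self.charge:+d}" if self.charge else ""
        return f"ElementalFormula({self.hill()}{q})"


def formula(text: str, charge: int = 0) -> ElementalFormula:
    """Shorthand for :meth:`ElementalFormula.parse`."""
    return ElementalFormula.parse(text, charge)


def monoisotopic_mass(f: ElementalFormula | str, charge: int | None = None) -> float:
    """Monoisotopic mass of a formula (string or object), in Da.

    When ``f`` is a string, ``charge`` (default 0) is applied.
    """
    if isinstance(f, str):
        f = ElementalFormula.parse(f, charge or 0)
    elif charge is not None:
        f = f.with_charge(charge)
    return f.mass
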