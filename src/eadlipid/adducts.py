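"""Adduct definitions for positive-mode lipid annotation.

Only singly charged positive adducts are supported; the mass shift of each
adduct equals the formula mass of the attached species minus one electron
mass (the charge carrier).
"""

from __future__ import annotations

from dataclasses import dataclass

from .elements import ElementalFormula, formula


@dataclass(frozen=True)
class Adduct:
    name: str
    added: ElementalFormula  # neutral composition attached to M
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")

    @property
    def shift(self) -> float:
        """Mass shift applied to the neutral monoisotopic mass, Da."""
        return self.added.with_charge(self.charge).mass

    def mz(self, neutral: ElementalFormula) -> float:
        """m/z of the adduct ion of a neutral molecule."""
        return (neutral + self.added.with_charge(self.charge)).mz

    def ion_formula(self, neutral: ElementalFormula) -> ElementalFormula:
        return neutral + self.added.with_charge(self.charge)


_REGISTRY: dict[str, Adduct] = {}


def _register(name: str, added: str, charge: int) -> None:
    _REGISTRY[name] = Adduct(name, formula(added), charge)


_register("[M+H]+", "H", 1)
_register("[M+NH4]+", "NH4", 1)
_register("[M+Na]+", "Na", 1)
_register("[M+K]+", "K", 1)
_register("[M+Li]+", "Li", 1)


def get_adduct(name: str) -> Adduct:
    try:
        return _REGISTRY[name.strip()]
    except KeyError:
        raise KeyError(
            f"unsupported adduct {name!r}; supported: {sorted(_REGISTRY)}"
        ) from None


def supported_adducts() -> list[str]:
    return sorted(_REGISTRY)
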