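"""Molecular formulas over C, H, N, O, S, P.

FTICR-MS formula assignment for natural organic matter is restricted to
these six elements, so a compact fixed-slot representation is enough.
All masses are neutral monoisotopic masses in Da.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

# Monoisotopic masses (Da) of the most abundant isotope of each element.
# Values follow the CODATA/AME compilations used by standard proteomics
# tooling; a unit test cross-checks them against pyteomics.
MONOISOTOPIC = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

#: Mass of a proton (Da), added to a negative-mode m/z to recover the
#: neutral monoisotopic mass of a singly deprotonated molecule.
PROTON_MASS = 1.007276

ELEMENT_ORDER = ("C", "H", "N", "O", "S", "P")

_FORMULA_TOKEN = re.compile(r"([CHNOSP])(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts of a neutral organic molecule.

    Counts must be non-negative; the charge is implicitly zero. ``c >= 1``
    (and for most index computations ``h >= 1``) is required downstream but
    is not enforced here so that moieties such as HPO3 remain representable.
    """

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s", "p"):
            value = getattr(self, name)
            if value < 0 or value != int(value):
                raise ValueError(f"element count {name}={value!r} must be a non-negative integer")

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        """Parse a composition string such as ``"C3H5NO"``.

        Only C, H, N, O, S, P are accepted; a missing count means 1.
        """
        counts = {e: 0 for e in ELEMENT_ORDER}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise ValueError(f"unparseable composition string: {text!r}")
            element, digits = match.groups()
            counts[element] += int(digits) if digits else 1
            pos = match.end()
        if pos != len(text) or pos == 0:
            raise ValueError(f"unparseable composition string: {text!r}")
        return cls(
            c=counts["C"], h=counts["H"], n=counts["N"],
            o=counts["O"], s=counts["S"], p=counts["P"],
        )

    def to_string(self) -> str:
        """Composition string in C, H, N, O, S, P order, zeros omitted."""
        parts = []
        for element, count in zip(ELEMENT_ORDER, (self.c, self.h, self.n, self.o, self.s, self.p)):
            if count == 1:
                parts.append(element)
            elif count > 1:
                parts.append(f"{element}{count}")
        return "".join(parts)

    @property
    def mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        return (
            self.c * MONOISOTOPIC["C"]
            + self.h * MONOISOTOPIC["H"]
            + self.n * MONOISOTOPIC["N"]
            + self.o * MONOISOTOPIC["O"]
            + self.s * MONOISOTOPIC["S"]
            + self.p * MONOISOTOPIC["P"]
        )

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return MolecularFormula(
            c=self.c + other.c, h=self.h + other.h, n=self.n + other.n,
            o=self.o + other.o, s=self.s + other.s, p=self.p + other.p,
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()
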