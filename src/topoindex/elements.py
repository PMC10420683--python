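"""Periodic data for the supported element set.

The supported set {C, N, O, F, S, Cl} (plus suppressed hydrogens) covers the
ten study compounds.  Extending support to another main-group element is a
data edit here, not a code change: add its atomic number, valence-electron
count and the total valences it may carry in a neutral connection table.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ElementData:
    symbol: str
    atomic_number: int
    valence_electrons: int
    allowed_valences: tuple[int, ...]


#: symbol -> (Z, Z^v, neutral valences admitted in a connection table).
#: Nitrogen admits 5 so that nitro groups can be written as neutral
#: pentavalent N(=O)=O, the hand-calculation convention used throughout.
ELEMENTS: dict[str, ElementData] = {
    "C": ElementData("C", 6, 4, (4,)),
    "N": ElementData("N", 7, 5, (3, 5)),
    "O": ElementData("O", 8, 6, (2,)),
    "F": ElementData("F", 9, 7, (1,)),
    "S": ElementData("S", 16, 6, (2, 4, 6)),
    "Cl": ElementData("Cl", 17, 7, (1,)),
}


class UnsupportedElementError(ValueError):
    """Raised when a structure contains an element outside the supported set."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(
            f"element {symbol!r} is outside the supported set "
            f"{sorted(ELEMENTS)}; add it to topoindex.elements.ELEMENTS"
        )


def element(symbol: str) -> ElementData:
    try:
        return ELEMENTS[symbol]
    except KeyError:
        raise UnsupportedElementError(symbol) from None
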