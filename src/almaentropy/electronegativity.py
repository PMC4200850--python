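"""Embedded Pauling electronegativity table.

The Markov chain on the molecular graph is weighted by atomic
electronegativity, so these values are part of the descriptor definition:
changing them changes every theta_k. They are therefore pinned here rather
than taken from a runtime dependency. Values are the standard Pauling-scale
electronegativities (dimensionless); charged atoms use the neutral element.
"""

from __future__ import annotations

from .errors import ConfigurationError

PAULING: dict[str, float] = {
    "H": 2.20,
    "Li": 0.98,
    "Be": 1.57,
    "B": 2.04,
    "C": 2.55,
    "N": 3.04,
    "O": 3.44,
    "F": 3.98,
    "Na": 0.93,
    "Mg": 1.31,
    "Al": 1.61,
    "Si": 1.90,
    "P": 2.19,
    "S": 2.58,
    "Cl": 3.16,
    "K": 0.82,
    "Ca": 1.00,
    "Ti": 1.54,
    "Cr": 1.66,
    "Mn": 1.55,
    "Fe": 1.83,
    "Co": 1.88,
    "Ni": 1.91,
    "Cu": 1.90,
    "Zn": 1.65,
    "Ga": 1.81,
    "Ge": 2.01,
    "As": 2.18,
    "Se": 2.55,
    "Br": 2.96,
    "Rb": 0.82,
    "Sr": 0.95,
    "Mo": 2.16,
    "Ru": 2.20,
    "Rh": 2.28,
    "Pd": 2.20,
    "Ag": 1.93,
    "Cd": 1.69,
    "In": 1.78,
    "Sn": 1.96,
    "Sb": 2.05,
    "Te": 2.10,
    "I": 2.66,
    "Cs": 0.79,
    "Ba": 0.89,
    "Pt": 2.28,
    "Au": 2.54,
    "Hg": 2.00,
    "Tl": 1.62,
    "Pb": 2.33,
    "Bi": 2.02,
}


def chi_of(symbol: str) -> float:
    """Electronegativity of an element symbol.

    Raises
    ------
    ConfigurationError
        If the element has no entry in the embedded table.
    """
    try:
        return PAULING[symbol]
    except KeyError:
        raise ConfigurationError(
            f"element {symbol!r} has no entry in the embedded "
            "Pauling electronegativity table"
        ) from None
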