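"""Monoisotopic mass arithmetic for small-molecule annotation.

Masses are summed from IUPAC monoisotopic atomic masses (via ``pyteomics``),
restricted to the element alphabet that covers conjugation chemistry seen in
gut-microbial biotransformations (C, H, N, O, S, P, Cl, Na, K). The proton
mass is exposed for adduct arithmetic such as [M+H]+.
"""

from __future__ import annotations

import re

from pyteomics import mass as _pt_mass

__all__ = ["monoisotopic_mass", "PROTON_MASS", "FormulaError", "ALLOWED_ELEMENTS"]

#: Mass of a proton in Da (CODATA); [M+H]+ = M + PROTON_MASS.
PROTON_MASS = 1.007276466812

ALLOWED_ELEMENTS = frozenset({"C", "H", "N", "O", "S", "P", "Cl", "Na", "K"})

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when a molecular formula cannot be parsed."""


def _parse(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormulaError(f"unparseable formula {formula!r} at position {pos}")
        pos = m.end()
        element, n = m.group(1), m.group(2)
        if element not in ALLOWED_ELEMENTS:
            raise FormulaError(f"unknown element {element!r} in formula {formula!r}")
        counts[element] = counts.get(element, 0) + (int(n) if n else 1)
    if pos != len(formula):
        raise FormulaError(f"unparseable formula {formula!r} at position {pos}")
    return counts


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass of a molecular formula in Da.

    Parameters
    ----------
    formula:
        Hill-style formula such as ``"C15H22O5"`` or ``"C3H6NO3S"``.
        The empty string has mass 0.

    Examples
    --------
    >>> round(monoisotopic_mass("H2O"), 5)
    18.01056
    """
    counts = _parse(formula)
    if not counts:
        return 0.0
    return float(_pt_mass.calculate_mass(composition=counts))
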