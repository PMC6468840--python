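"""Elemental-formula mass arithmetic for small-molecule annotation.

Monoisotopic masses are the masses of each element's most abundant isotope;
they are what a high-resolution mass spectrometer measures for an unfragmented,
non-isotopic ion. Adduct arithmetic works on ions, so the proton mass
(1.00727646 Da, i.e. the hydrogen atom minus its electron) is used for
protonation/deprotonation shifts.
"""

from __future__ import annotations

import re

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "FormulaError",
    "parse_formula",
    "serialize_formula",
    "monoisotopic_mass",
    "adduct_mz",
]

# Most-abundant-isotope masses, Da (CODATA 2018 / AME2020 atomic masses).
# Frozen in-code for bit-reproducibility of every downstream m/z.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Br": 78.9183371,
    "Se": 73.9224764,
    "I": 126.904473,
    "Mg": 23.9850417,
    "Ca": 39.96259098,
    "Fe": 55.9349375,
    "Zn": 63.9291422,
}

PROTON_MASS = 1.00727646
ELECTRON_MASS = 0.00054857990907

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when an elemental formula cannot be parsed."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style elemental formula into an element -> count map.

    Repeated element symbols accumulate ("CH3CH3" -> {C: 2, H: 6}).
    Parentheses and isotope labels are not supported; the library format
    stores expanded formulas.

    Raises
    ------
    FormulaError
        On empty input, unknown element symbols, or an explicit zero count.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("empty formula")
    formula = formula.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _TOKEN.match(formula, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"cannot parse formula {formula!r} at position {pos} ({formula[pos:]!r})"
            )
        symbol, digits = m.group(1), m.group(2)
        if symbol not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element symbol {symbol!r} in formula {formula!r}")
        count = int(digits) if digits else 1
        if count <= 0:
            raise FormulaError(f"non-positive count for {symbol!r} in formula {formula!r}")
        counts[symbol] = counts.get(symbol, 0) + count
        pos = m.end()
    if not counts:
        raise FormulaError(f"formula {formula!r} contains no elements")
    return counts


def serialize_formula(counts: dict[str, int]) -> str:
    """Serialize an element-count map in Hill order (C, H, then alphabetical)."""
    if not counts:
        raise FormulaError("empty element map")
    order = []
    if "C" in counts:
        order.append("C")
        if "H" in counts:
            order.append("H")
        order += sorted(k for k in counts if k not in ("C", "H"))
    else:
        order = sorted(counts)
    parts = []
    for el in order:
        n = counts[el]
        if not isinstance(n, int) or n <= 0:
            raise FormulaError(f"non-positive count for {el!r}")
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a neutral formula, in Da."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(ELEMENT_MASSES[el] * n for el, n in counts.items())


def adduct_mz(neutral_mass: float, multiplier: int, shift: float, charge: int) -> float:
    """m/z of an ion formed from a neutral molecule by an adduct rule.

    Computes (multiplier * M + shift) / |charge|. ``shift`` already carries
    the proton/electron bookkeeping of the rule.

    Raises
    ------
    ValueError
        If the neutral mass is non-positive, the charge is zero, or the rule
        yields a non-positive m/z.
    """
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    if charge == 0:
        raise ValueError("adduct charge must be non-zero")
    mz = (multiplier * neutral_mass + shift) / abs(charge)
    if mz <= 0:
        raise ValueError(
            f"adduct rule (n={multiplier}, shift={shift}, z={charge}) gives "
            f"non-positive m/z for M={neutral_mass}"
        )
    return mz
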