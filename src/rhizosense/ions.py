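"""Bundled ion reference table and salt-formula parsing.

Covers the cations and anions of the salts used in the uptake panel.  Each
ion carries its charge, molar mass (g/mol, from standard atomic weights), the
periodic-table group of its (central) element, and its nutrient class:
cations are macronutrients (K+, NH4+), secondary nutrients (Ca2+, Mg2+),
sodium, or heavy metals; anions are macronutrients (NO3-, phosphates),
secondary nutrients (SO4 2-), micronutrients (Cl-) or neutral (CO3 2-, OH-).
Lanthanides (La, Gd) are filed under group 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

__all__ = [
    "Ion",
    "CATIONS",
    "ANIONS",
    "SALT_PANEL",
    "UnknownIonError",
    "parse_salt",
    "salt_molar_mass",
]

_ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "Mg": 24.305,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Ni": 58.693,
    "Cu": 63.546,
    "Ag": 107.868,
    "Cd": 112.414,
    "Ba": 137.327,
    "La": 138.905,
    "Gd": 157.25,
}


def _mass(formula: Dict[str, int]) -> float:
    return sum(_ATOMIC_MASS[el] * n for el, n in formula.items())


@dataclass(frozen=True)
class Ion:
    symbol: str
    charge: int
    mass: float
    group: int
    nutrient_class: str


def _cation(symbol, charge, formula, group, nutrient_class) -> Ion:
    return Ion(symbol, charge, _mass(formula), group, nutrient_class)


CATIONS: Dict[str, Ion] = {
    "K": _cation("K", +1, {"K": 1}, 1, "macronutrient"),
    "NH4": _cation("NH4", +1, {"N": 1, "H": 4}, 15, "macronutrient"),
    "Ca": _cation("Ca", +2, {"Ca": 1}, 2, "secondary_nutrient"),
    "Mg": _cation("Mg", +2, {"Mg": 1}, 2, "secondary_nutrient"),
    "Na": _cation("Na", +1, {"Na": 1}, 1, "sodium"),
    "Ag": _cation("Ag", +1, {"Ag": 1}, 11, "heavy_metal"),
    "Ba": _cation("Ba", +2, {"Ba": 1}, 2, "heavy_metal"),
    "Cd": _cation("Cd", +2, {"Cd": 1}, 12, "heavy_metal"),
    "Cu": _cation("Cu", +2, {"Cu": 1}, 11, "heavy_metal"),
    "Gd": _cation("Gd", +3, {"Gd": 1}, 3, "heavy_metal"),
    "La": _cation("La", +3, {"La": 1}, 3, "heavy_metal"),
    "Ni": _cation("Ni", +2, {"Ni": 1}, 10, "heavy_metal"),
}

ANIONS: Dict[str, Ion] = {
    "NO3": Ion("NO3", -1, _mass({"N": 1, "O": 3}), 15, "macronutrient"),
    "H2PO4": Ion("H2PO4", -1, _mass({"H": 2, "P": 1, "O": 4}), 15, "macronutrient"),
    "PO4": Ion("PO4", -3, _mass({"P": 1, "O": 4}), 15, "macronutrient"),
    "SO4": Ion("SO4", -2, _mass({"S": 1, "O": 4}), 16, "secondary_nutrient"),
    "Cl": Ion("Cl", -1, _mass({"Cl": 1}), 17, "micronutrient"),
    "CO3": Ion("CO3", -2, _mass({"C": 1, "O": 3}), 14, "neutral"),
    "OH": Ion("OH", -1, _mass({"O": 1, "H": 1}), 16, "neutral"),
}

#: All salts with a bundled calibration identity (the uptake/calibration panel).
SALT_PANEL = (
    "AgNO3",
    "BaCl2",
    "CaCl2",
    "Ca(NO3)2",
    "CdCl2",
    "Cd(NO3)2",
    "CdSO4",
    "CuCl2",
    "Cu(NO3)2",
    "CuSO4",
    "GdCl3",
    "K2SO4",
    "KCl",
    "KH2PO4",
    "KNO3",
    "LaCl3",
    "MgCl2",
    "Mg(NO3)2",
    "Na2CO3",
    "Na2SO4",
    "NaCl",
    "NaH2PO4",
    "NaNO3",
    "NaOH",
    "NH4Cl",
    "NH4H2PO4",
    "NH4NO3",
    "NiCl2",
    "Ni(NO3)2",
)


class UnknownIonError(ValueError):
    """A salt formula contains an ion absent from the reference table."""


def _anion_suffixes(symbol: str):
    """Candidate (suffix, count) spellings of an anion at the end of a formula."""
    yield symbol, 1
    yield f"({symbol})", 1
    for m in (2, 3, 4):
        yield f"({symbol}){m}", m
        if len(symbol) <= 2 and not symbol[-1].isdigit():
            # single-element anions may be written without parentheses: Cl2
            yield f"{symbol}{m}", m


def _match_cation(prefix: str):
    """Return (symbol, count) when prefix is a known cation with optional count."""
    for sym in CATIONS:
        if prefix == sym:
            return sym, 1
        if prefix.startswith(sym):
            rest = prefix[len(sym) :]
            if rest.isdigit() and int(rest) >= 2:
                return sym, int(rest)
    return None


def parse_salt(name: str) -> Tuple[str, str, int, int]:
    """Parse a simple binary-salt formula into (cation, anion, n_cat, n_an).

    Accepts the conventional spellings used in the panel — ``KNO3``,
    ``Ca(NO3)2``, ``Na2CO3``, ``CuCl2``, ``NH4H2PO4`` ... — and checks
    stoichiometric charge neutrality.  Unknown ions raise
    :class:`UnknownIonError` naming the offending fragment.
    """
    name = name.strip()
    if not name:
        raise UnknownIonError("empty salt name")
    parses = set()
    unknown_fragments = []
    for an_sym, an in ANIONS.items():
        for suffix, m in _anion_suffixes(an_sym):
            if not name.endswith(suffix) or len(suffix) >= len(name):
                continue
            prefix = name[: -len(suffix)]
            cat = _match_cation(prefix)
            if cat is None:
                unknown_fragments.append(prefix)
                continue
            cat_sym, n = cat
            if n * CATIONS[cat_sym].charge + m * an.charge == 0:
                parses.add((cat_sym, an_sym, n, m))
    if not parses:
        if unknown_fragments:
            frag = min(unknown_fragments, key=len)
            raise UnknownIonError(f"unknown cation {frag!r} in salt {name!r}")
        raise UnknownIonError(f"cannot parse salt {name!r}: no known anion matches")
    if len(parses) > 1:
        raise UnknownIonError(f"ambiguous salt formula {name!r}: {sorted(parses)}")
    return next(iter(parses))


def salt_molar_mass(name: str) -> float:
    """Molar mass of the neutral salt in g/mol."""
    cat, an, n, m = parse_salt(name)
    return n * CATIONS[cat].mass + m * ANIONS[an].mass
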