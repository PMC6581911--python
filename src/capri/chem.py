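"""Monoisotopic mass bookkeeping for peptides, nucleobases and RNA adducts.

Every mass reported anywhere in this package derives from the single atomic
mass table below (IUPAC/CODATA monoisotopic values), so marker-ion m/z,
adduct masses and fragment ladders all trace to one source.  The table can be
dumped to TSV for audit with :func:`export_reference_table`.

Conventions
-----------
* Masses are neutral monoisotopic masses in Da unless a function says m/z.
* Peptide mass = sum of residue masses + one water (the condensation model
  used by every proteomics search engine).
* ``mz(M, z) = (M + z * PROTON) / z`` for positive ions.
* Nominal m/z rounds half-up to the nearest integer, matching how diagnostic
  ions are quoted in the literature (e.g. the protonated adenine at 136).
"""

from __future__ import annotations

import math
import re
from typing import Dict, Iterable, Mapping

__all__ = [
    "ATOMIC_MASSES",
    "PROTON",
    "ElementalComposition",
    "composition_mass",
    "RESIDUE_COMPOSITIONS",
    "CARBAMIDOMETHYL",
    "WATER",
    "HPO3",
    "residue_masses",
    "peptide_mono_mass",
    "mz",
    "neutral_mass",
    "nominal_mz",
    "export_reference_table",
]

#: Monoisotopic atomic masses (Da) of the elements used in peptide and
#: ribonucleotide chemistry.  Single source of truth for the whole package.
ATOMIC_MASSES: Dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

#: Mass of the proton (Da); charge carrier for positive-mode ESI.
PROTON: float = 1.00727646688

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d*)")


class ElementalComposition(dict):
    """Element symbol -> signed integer count.

    Signed counts allow losses (e.g. a cyclic phosphate is ``rest - H2O``).
    Supports ``+``, ``-`` and scalar ``*``; arithmetic is element-wise, so
    ``mass(a + b) == mass(a) + mass(b)`` exactly (float addition aside).
    """

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-style formula like ``C5H5N5`` or ``H-2O-1``."""
        comp = cls()
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = match.end()
            symbol, count = match.group(1), match.group(2)
            comp[symbol] = comp.get(symbol, 0) + (int(count) if count else 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
        comp._prune()
        return comp

    def _prune(self) -> None:
        for k in [k for k, v in self.items() if v == 0]:
            del self[k]

    def __add__(self, other: Mapping[str, int]) -> "ElementalComposition":
        out = ElementalComposition(self)
        for k, v in other.items():
            out[k] = out.get(k, 0) + v
        out._prune()
        return out

    def __sub__(self, other: Mapping[str, int]) -> "ElementalComposition":
        out = ElementalComposition(self)
        for k, v in other.items():
            out[k] = out.get(k, 0) - v
        out._prune()
        return out

    def __mul__(self, n: int) -> "ElementalComposition":
        out = ElementalComposition({k: v * n for k, v in self.items()})
        out._prune()
        return out

    __rmul__ = __mul__

    def formula(self) -> str:
        """Hill-ish formula string (C, H first, then alphabetical)."""
        order = sorted(self, key=lambda s: (s != "C", s != "H", s))
        parts = []
        for sym in order:
            n = self[sym]
            parts.append(f"{sym}{n}" if n != 1 else sym)
        return "".join(parts)

    @property
    def mass(self) -> float:
        return composition_mass(self)


def composition_mass(comp: Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of an elemental composition.

    Raises ``KeyError`` naming the symbol if an element is not in
    :data:`ATOMIC_MASSES`.
    """
    total = 0.0
    for symbol, count in comp.items():
        try:
            total += count * ATOMIC_MASSES[symbol]
        except KeyError:
            raise KeyError(f"unknown element symbol: {symbol!r}") from None
    return total


def _f(formula: str) -> ElementalComposition:
    return ElementalComposition.from_formula(formula)


#: Residue (i.e. water-free) compositions of the 20 standard amino acids.
RESIDUE_COMPOSITIONS: Dict[str, ElementalComposition] = {
    "G": _f("C2H3NO"),
    "A": _f("C3H5NO"),
    "S": _f("C3H5NO2"),
    "P": _f("C5H7NO"),
    "V": _f("C5H9NO"),
    "T": _f("C4H7NO2"),
    "C": _f("C3H5NOS"),
    "L": _f("C6H11NO"),
    "I": _f("C6H11NO"),
    "N": _f("C4H6N2O2"),
    "D": _f("C4H5NO3"),
    "Q": _f("C5H8N2O2"),
    "K": _f("C6H12N2O"),
    "E": _f("C5H7NO3"),
    "M": _f("C5H9NOS"),
    "H": _f("C6H7N3O"),
    "F": _f("C9H9NO"),
    "R": _f("C6H12N4O"),
    "Y": _f("C9H9NO2"),
    "W": _f("C11H10N2O"),
}

#: Carbamidomethylation of cysteine (iodoacetamide alkylation), fixed
#: modification in the CAPRI searches; +57.021464 Da.
CARBAMIDOMETHYL: ElementalComposition = _f("C2H3NO")

WATER: float = composition_mass(_f("H2O"))
HPO3: float = composition_mass(_f("HPO3"))


def residue_masses(carbamidomethyl_cys: bool = False) -> Dict[str, float]:
    """One-letter code -> monoisotopic residue mass (Da).

    With ``carbamidomethyl_cys`` the cysteine entry carries the fixed
    +57.021464 Da alkylation.
    """
    masses = {aa: composition_mass(c) for aa, c in RESIDUE_COMPOSITIONS.items()}
    if carbamidomethyl_cys:
        masses["C"] += composition_mass(CARBAMIDOMETHYL)
    return masses


def peptide_mono_mass(sequence: str, carbamidomethyl_cys: bool = False) -> float:
    """Neutral monoisotopic mass of a peptide: sum of residues + water."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    masses = residue_masses(carbamidomethyl_cys)
    total = WATER
    for aa in sequence:
        try:
            total += masses[aa]
        except KeyError:
            raise ValueError(f"non-standard residue {aa!r} in {sequence!r}") from None
    return total


def mz(neutral: float, charge: int) -> float:
    """m/z of a positive ion carrying ``charge`` protons."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral + charge * PROTON) / charge


def neutral_mass(mz_value: float, charge: int) -> float:
    """Inverse of :func:`mz`."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz_value * charge - charge * PROTON


def nominal_mz(mz_value: float) -> int:
    """Round half-up to integer, the convention for quoting diagnostic ions."""
    return int(math.floor(mz_value + 0.5))


def export_reference_table(path) -> None:
    """Dump the atomic and residue mass constants to a TSV audit file."""
    with open(path, "w") as fh:
        fh.write("kind\tname\tformula\tmonoisotopic_mass\n")
        for sym, m in ATOMIC_MASSES.items():
            fh.write(f"element\t{sym}\t{sym}\t{m:.6f}\n")
        fh.write(f"constant\tproton\t\t{PROTON:.6f}\n")
        fh.write(f"constant\twater\tH2O\t{WATER:.6f}\n")
        fh.write(f"constant\tHPO3\tHPO3\t{HPO3:.6f}\n")
        for aa, comp in sorted(RESIDUE_COMPOSITIONS.items()):
            fh.write(f"residue\t{aa}\t{comp.formula()}\t{composition_mass(comp):.6f}\n")
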