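"""The split base/"rest" RNA-adduct PTM catalogue and combination rules.

UV crosslinking leaves a short RNA oligomer (1-3 nt after exhaustive nuclease
trimming) covalently attached to a peptide.  In HCD/CID the glycosidic and
phosphodiester bonds cleave preferentially while the base-to-side-chain bond
survives, so each crosslinked ribonucleotide behaves as *two* modifications:

* the nucleobase (A', G', C', U'), which stays on the amino-acid residue and
  pinpoints the crosslink site, and
* the "rest" of the nucleotide (ribose + phosphate), which dissociates as a
  neutral loss and is formally annotated at a peptide terminus.

Longer adducts fold every non-crosslinked nucleotide into the terminal
modification: a dinucleotide crosslinked via U is annotated as U' on the
residue plus "A + rest" (one full mononucleotide plus the crosslinked
nucleotide's ribose-phosphate) at a terminus.  A "cyclic-rest" variant
(rest - H2O) accounts for the 2',3'-cyclic phosphate left by RNases.  The
full enumeration for adducts of up to 3 nt is 34 definitions:
4 bases + 2 rests + 4x2 mononucleotide composites + 10x2 (unordered)
dinucleotide composites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations_with_replacement
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .chem import ElementalComposition, composition_mass, _f

__all__ = [
    "NUCLEOBASE_COMPOSITIONS",
    "REST",
    "AdductDefinition",
    "PtmAssignment",
    "ValidationResult",
    "RnaSummary",
    "build_catalog",
    "adduct_mass",
    "validate_combination",
    "infer_rna",
    "catalog_to_tsv",
    "catalog_from_tsv",
]

#: Elemental compositions of the four standard ribonucleobases.
NUCLEOBASE_COMPOSITIONS: Dict[str, ElementalComposition] = {
    "A": _f("C5H5N5"),    # adenine, 135.054495
    "G": _f("C5H5N5O"),   # guanine, 151.049410
    "C": _f("C4H5N3O"),   # cytosine, 111.043262
    "U": _f("C4H4N2O2"),  # uracil, 112.027277
}

#: Ribose + phosphate left after carving the base out of a mononucleotide:
#: NMP - base = C5H9O7P, 212.008590 Da.
REST: ElementalComposition = _f("C5H9O7P")

_H2O = _f("H2O")


def _nmp(nt: str) -> ElementalComposition:
    """Full mononucleotide (base + rest); e.g. AMP = 347.063085 Da."""
    return NUCLEOBASE_COMPOSITIONS[nt] + REST


@dataclass(frozen=True)
class AdductDefinition:
    """One RNA-PTM.

    ``category`` is ``nucleobase`` (sits on the crosslinked residue),
    ``terminal`` (bare rest / cyclic-rest) or ``composite_terminal``
    (non-crosslinked mononucleotides folded together with rest).
    ``nt_multiset`` lists the nucleotides the definition implies: the
    crosslinked base itself for nucleobase adducts, the non-crosslinked
    members for terminal adducts (empty for bare rest).
    """

    name: str
    category: str
    nt_multiset: Tuple[str, ...]
    composition: ElementalComposition
    placement: str  # "on_residue" | "on_terminus"
    cyclic: bool = False

    @property
    def mass(self) -> float:
        return composition_mass(self.composition)


def adduct_mass(definition: AdductDefinition) -> float:
    """Monoisotopic mass (Da) of a catalogue definition."""
    return definition.mass


def build_catalog(max_nt: int = 3, include_cyclic: bool = True) -> List[AdductDefinition]:
    """Enumerate the RNA-PTM definitions covering adducts of up to ``max_nt`` nt.

    Defaults reproduce the 34-definition design; ``max_nt=1`` gives 6 and
    ``max_nt=2`` gives 14.  Dinucleotide terminal compositions are unordered
    multisets (a mass modification cannot encode sequence order).
    """
    if max_nt not in (1, 2, 3):
        raise ValueError(f"max_nt must be 1, 2 or 3, got {max_nt!r}")

    defs: List[AdductDefinition] = []
    for nt, comp in NUCLEOBASE_COMPOSITIONS.items():
        defs.append(
            AdductDefinition(
                name=f"{nt}_base",
                category="nucleobase",
                nt_multiset=(nt,),
                composition=comp,
                placement="on_residue",
            )
        )

    def _terminal(members: Tuple[str, ...]) -> None:
        comp = REST
        for nt in members:
            comp = comp + _nmp(nt)
        prefix = "".join(members)
        category = "terminal" if not members else "composite_terminal"
        name = f"{prefix}_plus_rest" if members else "rest"
        defs.append(
            AdductDefinition(name, category, members, comp, "on_terminus")
        )
        if include_cyclic:
            cname = f"{prefix}_plus_cyclic_rest" if members else "cyclic_rest"
            defs.append(
                AdductDefinition(
                    cname, category, members, comp - _H2O, "on_terminus", cyclic=True
                )
            )

    _terminal(())
    if max_nt >= 2:
        for nt in NUCLEOBASE_COMPOSITIONS:
            _terminal((nt,))
    if max_nt == 3:
        for pair in combinations_with_replacement(sorted(NUCLEOBASE_COMPOSITIONS), 2):
            _terminal(pair)

    names = [d.name for d in defs]
    assert len(names) == len(set(names)), "duplicate adduct names"
    return defs


@dataclass
class PtmAssignment:
    """RNA-PTMs assigned to one peptide by a search or annotation step.

    ``residue_adducts`` maps 1-based positions to nucleobase definitions;
    ``terminal_adducts`` maps 'N'/'C' to terminal definitions (at most one
    each).  The site may be unknown (position ``None`` key not allowed; use
    :attr:`site_ambiguous` instead) when the producing search localised the
    base only to the peptide.
    """

    sequence: str
    residue_adducts: Dict[int, AdductDefinition] = field(default_factory=dict)
    terminal_adducts: Dict[str, AdductDefinition] = field(default_factory=dict)
    site_ambiguous: bool = False
    provenance: str = ""

    def adducts(self) -> List[AdductDefinition]:
        return list(self.residue_adducts.values()) + list(self.terminal_adducts.values())

    def total_adduct_mass(self) -> float:
        return sum(a.mass for a in self.adducts())

    def normalized(self) -> "PtmAssignment":
        """Move any terminal adduct to the N-terminus (terminus choice carries
        no mass information)."""
        if "C" in self.terminal_adducts and "N" not in self.terminal_adducts:
            term = {"N": self.terminal_adducts["C"]}
            return replace(
                self,
                residue_adducts=dict(self.residue_adducts),
                terminal_adducts=term,
            )
        return self


@dataclass(frozen=True)
class ValidationResult:
    valid: bool
    reason: Optional[str] = None  # machine-readable reason code when invalid

    def __bool__(self) -> bool:
        return self.valid


#: Reason codes emitted by :func:`validate_combination`.
REASONS = (
    "no_base",
    "multiple_base",
    "multiple_terminal",
    "rna_too_long",
    "too_many_adducts",
    "bad_placement",
    "bad_position",
)


def validate_combination(
    assignment: PtmAssignment,
    catalog: Optional[Sequence[AdductDefinition]] = None,
    max_total_nt: int = 3,
    max_adducts: int = 3,
) -> ValidationResult:
    """Screen an RNA-PTM combination for biochemical plausibility.

    Valid combinations carry exactly one nucleobase adduct (the crosslink
    site), at most one terminal adduct, and imply a total RNA of 1 to
    ``max_total_nt`` nucleotides.  Base-only assignments (glycosidic bond
    cleaved during preparation or in-source) are valid.  Everything else --
    "rest" alone, two terminal adducts, two crosslink sites -- is rejected
    with a reason code.
    """
    if catalog is not None:
        known = {d.name for d in catalog}
        for a in assignment.adducts():
            if a.name not in known:
                raise ValueError(f"adduct {a.name!r} not in catalogue")

    n = len(assignment.sequence)
    for pos, a in assignment.residue_adducts.items():
        if not 1 <= pos <= n:
            return ValidationResult(False, "bad_position")
        if a.placement != "on_residue":
            return ValidationResult(False, "bad_placement")
    for term, a in assignment.terminal_adducts.items():
        if term not in ("N", "C"):
            return ValidationResult(False, "bad_placement")
        if a.placement != "on_terminus":
            return ValidationResult(False, "bad_placement")

    if len(assignment.adducts()) > max_adducts:
        return ValidationResult(False, "too_many_adducts")

    n_base = len(assignment.residue_adducts)
    n_term = len(assignment.terminal_adducts)
    if n_base == 0:
        return ValidationResult(False, "no_base")
    if n_base > 1:
        return ValidationResult(False, "multiple_base")
    if n_term > 1:
        return ValidationResult(False, "multiple_terminal")

    total_nt = 1 + sum(len(a.nt_multiset) for a in assignment.terminal_adducts.values())
    if total_nt > max_total_nt:
        return ValidationResult(False, "rna_too_long")
    return ValidationResult(True)


@dataclass(frozen=True)
class RnaSummary:
    """Crosslinked RNA inferred from a valid assignment."""

    base: str                      # crosslinked nucleobase
    nt_multiset: Tuple[str, ...]   # full adduct composition, sorted
    site: Optional[int]            # 1-based residue index, None if ambiguous


def infer_rna(assignment: PtmAssignment) -> RnaSummary:
    """Summarise the RNA implied by a (valid) assignment."""
    result = validate_combination(assignment)
    if not result:
        raise ValueError(f"invalid assignment: {result.reason}")
    ((site, base_def),) = assignment.residue_adducts.items()
    base = base_def.nt_multiset[0]
    members: List[str] = [base]
    for term in assignment.terminal_adducts.values():
        members.extend(term.nt_multiset)
    return RnaSummary(
        base=base,
        nt_multiset=tuple(sorted(members)),
        site=None if assignment.site_ambiguous else site,
    )


def catalog_to_tsv(catalog: Iterable[AdductDefinition], path) -> None:
    """Write the catalogue as an audit TSV (name, category, nt_multiset,
    formula, monoisotopic_mass to 6 dp)."""
    with open(path, "w") as fh:
        fh.write("name\tcategory\tnt_multiset\tformula\tmonoisotopic_mass\n")
        for d in catalog:
            fh.write(
                f"{d.name}\t{d.category}\t{''.join(d.nt_multiset)}\t"
                f"{d.composition.formula()}\t{d.mass:.6f}\n"
            )


def catalog_from_tsv(path) -> List[AdductDefinition]:
    """Read a catalogue TSV written by :func:`catalog_to_tsv`."""
    defs: List[AdductDefinition] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {col: i for i, col in enumerate(header)}
        for line in fh:
            row = line.rstrip("\n").split("\t")
            comp = ElementalComposition.from_formula(row[idx["formula"]])
            name = row[idx["name"]]
            category = row[idx["category"]]
            defs.append(
                AdductDefinition(
                    name=name,
                    category=category,
                    nt_multiset=tuple(row[idx["nt_multiset"]]),
                    composition=comp,
                    placement="on_residue" if category == "nucleobase" else "on_terminus",
                    cyclic="cyclic" in name,
                )
            )
    return defs
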