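"""Theoretical ions, spectrum annotation and filtering for XL-peptides.

An XL-peptide is a peptide carrying a covalent ribonucleotide adduct (a
peptide-RNA heteroconjugate).  Its HCD/CID spectrum shows three ion classes
on top of ordinary b/y fragments:

* **b/y series** with the nucleobase mass riding on every fragment that
  contains the crosslinked residue -- the ribose-phosphate part has already
  dissociated, so fragments never carry the terminal adduct;
* **precursor neutral losses**: a ladder from the intact heteroconjugate
  [M] through loss of HPO3, loss of the full ribose-phosphate ("rest"), and
  for di/tri adducts loss of whole mononucleotides, ending at the
  peptide+base conjugate;
* **marker ions** in the low m/z range: protonated nucleobases (A' 136,
  G' 152, C' 112, U' 113) and protonated (cyclic) mononucleotides
  (cAMP+H 330 with a second water loss at 312, cCMP+H 306, cUMP+H 307).
  Markers appear when a non-crosslinked nucleotide can leave the conjugate,
  i.e. for di/trinucleotide adducts, and are typically the base peak there.

Matching uses an absolute fragment tolerance (0.02 Da by default, the
instrument setting the method was developed for) with nearest-peak greedy
assignment, ties broken toward higher intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import chem
from .chem import HPO3, PROTON, WATER, mz, peptide_mono_mass, residue_masses
from .ptm_catalog import (
    NUCLEOBASE_COMPOSITIONS,
    REST,
    AdductDefinition,
    PtmAssignment,
    infer_rna,
    validate_combination,
)

__all__ = [
    "CrosslinkedPeptide",
    "TheoreticalIon",
    "AnnotationConfig",
    "IonMatch",
    "AnnotatedSpectrum",
    "theoretical_ions",
    "annotate",
    "filter_xl_candidates",
    "summarize_xl",
    "XlSummary",
    "read_mgf",
]

_REST_MASS = chem.composition_mass(REST)
_BASE_MASS = {nt: chem.composition_mass(c) for nt, c in NUCLEOBASE_COMPOSITIONS.items()}
_NMP_MASS = {nt: _BASE_MASS[nt] + _REST_MASS for nt in _BASE_MASS}


@dataclass
class CrosslinkedPeptide:
    """A candidate XL-peptide: sequence + validated RNA-PTM assignment."""

    sequence: str
    assignment: PtmAssignment
    charge: int = 2
    protein_id: str = ""
    start: int = 0   # 1-based position of the peptide in the protein
    end: int = 0
    spectrum_id: str = ""
    carbamidomethyl_cys: bool = True

    def __post_init__(self) -> None:
        if self.assignment.sequence != self.sequence:
            raise ValueError("assignment sequence does not match peptide sequence")

    @property
    def peptide_mass(self) -> float:
        return peptide_mono_mass(self.sequence, self.carbamidomethyl_cys)

    @property
    def precursor_neutral_mass(self) -> float:
        """Peptide + all adduct masses (the additive heteroconjugate model)."""
        return self.peptide_mass + self.assignment.total_adduct_mass()


@dataclass(frozen=True)
class TheoreticalIon:
    series: str          # "b" | "y" | "precursor_NL" | "marker"
    ordinal: int         # fragment index; 0 for precursor/marker ions
    charge: int
    mz: float
    label: str


@dataclass
class AnnotationConfig:
    precursor_tol_ppm: float = 10.0
    fragment_tol_da: float = 0.02
    min_fragment_fraction: float = 0.4
    #: require >=1 matched marker ion for di/trinucleotide adducts
    require_marker_for_multi: bool = True
    lowest_mz: float = 100.0

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_da <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class IonMatch:
    ion: TheoreticalIon
    peak_index: int
    observed_mz: float
    intensity: float
    error_da: float


@dataclass
class AnnotatedSpectrum:
    spectrum_id: str
    candidate: CrosslinkedPeptide
    peaks_mz: np.ndarray
    peaks_intensity: np.ndarray
    matches: List[IonMatch] = field(default_factory=list)
    fragment_fraction: float = 0.0       # matched fraction of the b/y series
    markers_found: List[str] = field(default_factory=list)
    neutral_losses_found: List[str] = field(default_factory=list)
    base_peak_is_marker: bool = False


def _fragment_contains_site(series: str, ordinal: int, length: int, site: int) -> bool:
    if series == "b":
        return ordinal >= site
    # y_j covers residues length-j+1 .. length
    return ordinal >= length - site + 1


def theoretical_ions(xl: CrosslinkedPeptide, cfg: Optional[AnnotationConfig] = None) -> List[TheoreticalIon]:
    """Enumerate b/y fragments, precursor neutral losses and marker ions.

    Fragments are emitted at charges 1..precursor charge - 1 (at least 1);
    neutral-loss ions at 1..precursor charge; markers singly charged.  Ions
    below ``cfg.lowest_mz`` (the fixed acquisition floor) are suppressed.
    """
    cfg = cfg or AnnotationConfig()
    result = validate_combination(xl.assignment)
    if not result:
        raise ValueError(f"invalid RNA-PTM assignment: {result.reason}")

    seq = xl.sequence
    n = len(seq)
    rna = infer_rna(xl.assignment)
    ((site, base_def),) = xl.assignment.residue_adducts.items()
    base_mass = base_def.mass
    terminal: Optional[AdductDefinition] = None
    for t in xl.assignment.terminal_adducts.values():
        terminal = t

    masses = residue_masses(xl.carbamidomethyl_cys)
    res = [masses[aa] for aa in seq]
    prefix = np.cumsum(res)

    ions: List[TheoreticalIon] = []
    frag_charges = range(1, max(2, xl.charge))
    for i in range(1, n):
        b_neutral = prefix[i - 1]
        y_neutral = prefix[-1] - prefix[i - 1] + WATER
        b_mod = b_neutral + (base_mass if _fragment_contains_site("b", i, n, site) else 0.0)
        y_ord = n - i
        y_mod = y_neutral + (base_mass if _fragment_contains_site("y", y_ord, n, site) else 0.0)
        for z in frag_charges:
            ions.append(TheoreticalIon("b", i, z, mz(b_mod, z), f"b{i}" + ("+RNA" if b_mod != b_neutral else "")))
            ions.append(TheoreticalIon("y", y_ord, z, mz(y_mod, z), f"y{y_ord}" + ("+RNA" if y_mod != y_neutral else "")))

    # Precursor neutral-loss ladder: sequential loss of phosphate, ribose
    # (completing "rest"), then whole mononucleotides down to peptide+base.
    M = xl.precursor_neutral_mass
    losses: List[Tuple[float, str]] = [(0.0, "[M]")]
    if terminal is not None:
        rest_part = terminal.mass - sum(_NMP_MASS[nt] for nt in terminal.nt_multiset)
        losses.append((HPO3, "[M-HPO3]"))
        losses.append((rest_part, "[M-rest]"))
        cumulative = rest_part
        for k, nt in enumerate(sorted(terminal.nt_multiset), start=1):
            cumulative += _NMP_MASS[nt]
            losses.append((cumulative, f"[M-rest-{k}nt]"))
    for z in range(1, xl.charge + 1):
        for loss, label in losses:
            m = mz(M - loss, z)
            if m >= cfg.lowest_mz:
                ions.append(TheoreticalIon("precursor_NL", 0, z, m, f"{label}{'+' * z}"))

    # Marker ions (singly protonated), from every base in the adduct multiset.
    seen: Dict[str, float] = {}
    for nt in rna.nt_multiset:
        seen[f"{nt}_base+"] = _BASE_MASS[nt] + PROTON
        cyclic = _NMP_MASS[nt] - WATER + PROTON
        seen[f"c{nt}MP+"] = cyclic
        seen[f"{nt}MP+"] = _NMP_MASS[nt] + PROTON
        if nt == "A":
            # second water loss from the cyclic AMP marker (330 -> 312)
            seen["cAMP+-H2O"] = cyclic - WATER
    for label, m in seen.items():
        if m >= cfg.lowest_mz:
            ions.append(TheoreticalIon("marker", 0, 1, m, label))

    return [ion for ion in ions if ion.mz >= cfg.lowest_mz]


def annotate(
    peaks: Sequence[Tuple[float, float]] | np.ndarray,
    candidates: CrosslinkedPeptide | Sequence[CrosslinkedPeptide],
    cfg: Optional[AnnotationConfig] = None,
    spectrum_id: str = "",
) -> AnnotatedSpectrum:
    """Annotate an observed peak list against one or more XL candidates.

    With several candidates the one with the highest matched b/y fraction
    wins.  Matching is greedy nearest-peak within the fragment tolerance;
    each peak is assigned to at most one theoretical ion.
    """
    cfg = cfg or AnnotationConfig()
    arr = np.asarray(peaks, dtype=float)
    if arr.size == 0:
        raise ValueError("empty spectrum")
    arr = arr.reshape(-1, 2)
    order = np.argsort(arr[:, 0])
    mz_sorted = arr[order, 0]
    int_sorted = arr[order, 1]

    if isinstance(candidates, CrosslinkedPeptide):
        candidates = [candidates]
    best: Optional[AnnotatedSpectrum] = None
    for cand in candidates:
        annotated = _annotate_one(mz_sorted, int_sorted, order, cand, cfg, spectrum_id)
        if best is None or annotated.fragment_fraction > best.fragment_fraction:
            best = annotated
    assert best is not None
    return best


def _annotate_one(
    mz_sorted: np.ndarray,
    int_sorted: np.ndarray,
    order: np.ndarray,
    cand: CrosslinkedPeptide,
    cfg: AnnotationConfig,
    spectrum_id: str,
) -> AnnotatedSpectrum:
    ions = theoretical_ions(cand, cfg)
    tol = cfg.fragment_tol_da

    proposals: List[Tuple[float, float, int, TheoreticalIon]] = []
    for ion in ions:
        lo = np.searchsorted(mz_sorted, ion.mz - tol, side="left")
        hi = np.searchsorted(mz_sorted, ion.mz + tol, side="right")
        best_j = -1
        best_err = np.inf
        best_int = -np.inf
        for j in range(lo, hi):
            err = abs(mz_sorted[j] - ion.mz)
            # nearest peak wins; ties broken toward higher intensity
            if err < best_err - 1e-12 or (abs(err - best_err) <= 1e-12 and int_sorted[j] > best_int):
                best_j, best_err, best_int = j, err, int_sorted[j]
        if best_j >= 0:
            proposals.append((best_err, -best_int, best_j, ion))

    proposals.sort(key=lambda t: (t[0], t[1], t[3].label))
    taken: Dict[int, bool] = {}
    matched: Dict[str, IonMatch] = {}
    for err, _neg_int, j, ion in proposals:
        key = (ion.series, ion.label, ion.charge)
        if j in taken or key in matched:
            continue
        taken[j] = True
        matched[key] = IonMatch(
            ion=ion,
            peak_index=int(order[j]),
            observed_mz=float(mz_sorted[j]),
            intensity=float(int_sorted[j]),
            error_da=float(mz_sorted[j] - ion.mz),
        )

    matches = list(matched.values())
    frag_keys = {(i.series, i.label, i.charge) for i in ions if i.series in ("b", "y")}
    frag_matched = sum(1 for m in matches if m.ion.series in ("b", "y"))
    fraction = frag_matched / len(frag_keys) if frag_keys else 0.0

    markers = sorted({m.ion.label for m in matches if m.ion.series == "marker"})
    losses = sorted({m.ion.label for m in matches if m.ion.series == "precursor_NL"})

    base_peak_idx = int(np.argmax(int_sorted))
    base_peak_is_marker = any(
        m.ion.series == "marker" and m.peak_index == int(order[base_peak_idx])
        for m in matches
    )

    return AnnotatedSpectrum(
        spectrum_id=spectrum_id or cand.spectrum_id,
        candidate=cand,
        peaks_mz=mz_sorted,
        peaks_intensity=int_sorted,
        matches=matches,
        fragment_fraction=fraction,
        markers_found=markers,
        neutral_losses_found=losses,
        base_peak_is_marker=base_peak_is_marker,
    )


def filter_xl_candidates(
    annotated: Iterable[AnnotatedSpectrum],
    cfg: Optional[AnnotationConfig] = None,
) -> Tuple[List[AnnotatedSpectrum], List[Tuple[AnnotatedSpectrum, str]]]:
    """Apply the spectrum-level screens: PTM-combination validity, minimum
    matched b/y fraction, and the marker-ion requirement for di/tri adducts.

    Returns ``(accepted, rejected)`` with machine-readable reasons.  These
    config thresholds stand in for the manual curation of low-quality
    spectra; they are deterministic given the config.
    """
    cfg = cfg or AnnotationConfig()
    accepted: List[AnnotatedSpectrum] = []
    rejected: List[Tuple[AnnotatedSpectrum, str]] = []
    for spec in annotated:
        result = validate_combination(spec.candidate.assignment)
        if not result:
            rejected.append((spec, result.reason or "invalid_combination"))
            continue
        if spec.fragment_fraction < cfg.min_fragment_fraction:
            rejected.append((spec, "low_coverage"))
            continue
        rna = infer_rna(spec.candidate.assignment)
        if cfg.require_marker_for_multi and len(rna.nt_multiset) >= 2 and not spec.markers_found:
            rejected.append((spec, "missing_marker"))
            continue
        accepted.append(spec)
    return accepted, rejected


@dataclass(frozen=True)
class XlSummary:
    crosslinks: int   # distinct (peptide, RNA multiset, crosslink site)
    peptides: int     # distinct peptide sequences
    proteins: int     # distinct protein ids


def summarize_xl(accepted: Iterable[AnnotatedSpectrum]) -> XlSummary:
    """De-duplicated heteroconjugate / peptide / protein counts."""
    crosslinks = set()
    peptides = set()
    proteins = set()
    for spec in accepted:
        cand = spec.candidate
        rna = infer_rna(cand.assignment)
        crosslinks.add((cand.sequence, rna.nt_multiset, rna.site))
        peptides.add(cand.sequence)
        if cand.protein_id:
            proteins.add(cand.protein_id)
    return XlSummary(len(crosslinks), len(peptides), len(proteins))


def read_mgf(path) -> List[dict]:
    """Read an MGF peak-list file into a list of spectrum dicts
    (``id``, ``pepmass``, ``charge``, ``peaks`` as an (n, 2) array)."""
    from pyteomics import mgf

    spectra = []
    with mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = params.get("charge")
            spectra.append(
                {
                    "id": params.get("title", ""),
                    "pepmass": params.get("pepmass", (None,))[0],
                    "charge": int(charge[0]) if charge else None,
                    "peaks": np.column_stack([entry["m/z array"], entry["intensity array"]]),
                }
            )
    return spectra
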