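"""Digestion, Lys-C extension and merging of adjacent peptides.

In the CAPRI workflow proteins are first digested on-bead with Lys-C; the
peptides still attached to RNA are then trypsinised, releasing "adjacent"
tryptic peptides next to the crosslink.  Each significant tryptic adjacent
peptide is therefore a fragment of a Lys-C unit that contained a crosslink,
and is extended in silico to the nearest lysine boundaries on both sides to
recover that unit (an ADJ-peptide).  Multiple tryptic peptides from the same
Lys-C unit merge into a single ADJ-peptide.

Coordinates are 1-based inclusive throughout (proteomics convention).
Trypsin is modelled as trypsin/P: cleavage C-terminal to K/R with no proline
suppression; Lys-C cleaves C-terminal to K, also ignoring proline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ProteinRecord",
    "PeptideInterval",
    "ExtendedPeptide",
    "digest",
    "extend_to_lysc",
    "merge_adjacent",
    "select_isoform",
    "coverage",
    "xl_adj_overlap",
    "read_fasta",
    "map_peptide",
]

_CLEAVE_AFTER = {"LysC": "K", "TrypsinP": "KR"}


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.protein_id!r}")
        if not self.sequence.isupper() or not self.sequence.isalpha():
            raise ValueError(f"sequence for {self.protein_id!r} must be uppercase letters")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideInterval:
    """1-based inclusive interval on a protein, carrying its sequence slice."""

    protein_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad interval {self.start}-{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length does not match interval")

    def overlaps(self, other: "PeptideInterval") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class ExtendedPeptide:
    """An ADJ-peptide: a tryptic interval widened to Lys-C boundaries."""

    interval: PeptideInterval
    members: List[PeptideInterval] = field(default_factory=list)
    q_value: Optional[float] = None
    fold_change: Optional[float] = None


def _check_mapping(peptide: PeptideInterval, protein: ProteinRecord) -> None:
    if peptide.protein_id != protein.protein_id:
        raise ValueError(
            f"peptide maps to {peptide.protein_id!r}, protein is {protein.protein_id!r}"
        )
    if peptide.end > len(protein):
        raise ValueError("peptide interval exceeds protein length")
    if protein.sequence[peptide.start - 1 : peptide.end] != peptide.sequence:
        raise ValueError("peptide sequence does not match protein subsequence")


def digest(protein: ProteinRecord, enzyme: str = "TrypsinP", max_missed: int = 0) -> List[PeptideInterval]:
    """In-silico digestion with 0..``max_missed`` missed cleavages.

    ``LysC`` cleaves C-terminal to K; ``TrypsinP`` C-terminal to K/R with
    cleavage enabled N-terminal to proline.  At 0 missed cleavages the
    products tile the protein.
    """
    if enzyme not in _CLEAVE_AFTER:
        raise ValueError(f"unknown enzyme {enzyme!r}; choose from {sorted(_CLEAVE_AFTER)}")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence
    residues = _CLEAVE_AFTER[enzyme]
    # cut points: index i means a boundary after residue i (1-based)
    cuts = [0] + [i + 1 for i, aa in enumerate(seq) if aa in residues and i + 1 < len(seq)] + [len(seq)]
    peptides: List[PeptideInterval] = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + max_missed, len(cuts))):
            start, end = cuts[a] + 1, cuts[b]
            peptides.append(PeptideInterval(protein.protein_id, start, end, seq[start - 1 : end]))
    return peptides


def extend_to_lysc(peptide: PeptideInterval, protein: ProteinRecord) -> PeptideInterval:
    """Widen a tryptic interval to the nearest theoretical Lys-C boundaries.

    New start = one past the nearest K strictly left of the peptide (or 1);
    new end = the nearest K at or right of the current end (or the protein
    end).  Protein termini count as cleavage boundaries.  Idempotent and
    monotone (output contains input).
    """
    _check_mapping(peptide, protein)
    seq = protein.sequence
    start = 1
    for i in range(peptide.start - 1, 0, -1):  # residues 1..start-1, right to left
        if seq[i - 1] == "K":
            start = i + 1
            break
    end = len(seq)
    for i in range(peptide.end, len(seq) + 1):
        if seq[i - 1] == "K":
            end = i
            break
    return PeptideInterval(protein.protein_id, start, end, seq[start - 1 : end])


def merge_adjacent(
    extended: Iterable[ExtendedPeptide],
) -> List[ExtendedPeptide]:
    """Collapse extended peptides sharing the same Lys-C unit.

    Peptides whose extended intervals are identical merge into one
    ADJ-peptide keeping the member list and the best (minimum) q-value;
    distinct units never merge.
    """
    groups: Dict[Tuple[str, int, int], ExtendedPeptide] = {}
    order: List[Tuple[str, int, int]] = []
    for ep in extended:
        key = (ep.interval.protein_id, ep.interval.start, ep.interval.end)
        if key not in groups:
            groups[key] = ExtendedPeptide(
                interval=ep.interval,
                members=list(ep.members),
                q_value=ep.q_value,
                fold_change=ep.fold_change,
            )
            order.append(key)
        else:
            g = groups[key]
            g.members.extend(ep.members)
            for attr in ("q_value",):
                a, b = getattr(g, attr), getattr(ep, attr)
                if b is not None and (a is None or b < a):
                    setattr(g, attr, b)
            if ep.fold_change is not None and (
                g.fold_change is None or ep.fold_change > g.fold_change
            ):
                g.fold_change = ep.fold_change
    return [groups[k] for k in order]


def select_isoform(
    isoforms: Mapping[str, ProteinRecord],
    peptide_counts: Mapping[str, int],
) -> ProteinRecord:
    """Representative isoform for one gene: most mapped ADJ-peptides, then
    longest, then lexicographically smallest id (determinism tie-break)."""
    candidates = [pid for pid in isoforms if peptide_counts.get(pid, 0) > 0]
    if not candidates:
        raise ValueError("no isoform with mapped peptides")
    best = sorted(
        candidates,
        key=lambda pid: (-peptide_counts.get(pid, 0), -len(isoforms[pid]), pid),
    )[0]
    return isoforms[best]


def coverage(peptides: Iterable[PeptideInterval], protein: ProteinRecord) -> np.ndarray:
    """Per-residue count of member tryptic peptides covering each position
    (index 0 of the track is residue 1)."""
    track = np.zeros(len(protein), dtype=int)
    for p in peptides:
        _check_mapping(p, protein)
        track[p.start - 1 : p.end] += 1
    return track


def xl_adj_overlap(
    xl_peptides: Sequence[PeptideInterval],
    adj_peptides: Sequence[PeptideInterval],
    extension: int = 30,
    protein_lengths: Optional[Mapping[str, int]] = None,
) -> List[str]:
    """Per-XL-peptide overlap with the ADJ set.

    Returns one of ``direct_overlap`` (>=1 shared residue),
    ``overlap_after_extension`` (shared residue after widening the XL
    interval by +-``extension`` residues, clipped to the protein), or
    ``none``.  At ``extension=0`` the extended test reduces to the direct
    one.
    """
    by_protein: Dict[str, List[PeptideInterval]] = {}
    for a in adj_peptides:
        by_protein.setdefault(a.protein_id, []).append(a)

    flags: List[str] = []
    for x in xl_peptides:
        adj = by_protein.get(x.protein_id, [])
        if any(x.overlaps(a) for a in adj):
            flags.append("direct_overlap")
            continue
        lo = max(1, x.start - extension)
        hi = x.end + extension
        if protein_lengths and x.protein_id in protein_lengths:
            hi = min(hi, protein_lengths[x.protein_id])
        if any(lo <= a.end and a.start <= hi for a in adj):
            flags.append("overlap_after_extension")
        else:
            flags.append("none")
    return flags


_UNIPROT_RE = re.compile(r"^(?:sp|tr)\|([^|]+)\|")


def read_fasta(path, id_regex: Optional[str] = None, gene_regex: str = r"GN=(\S+)") -> List[ProteinRecord]:
    """Read protein records from FASTA.

    ``id_regex`` (first group = id) defaults to UniProt ``sp|ACC|NAME``
    parsing with fallback to the first whitespace-delimited token.
    """
    from Bio import SeqIO

    id_re = re.compile(id_regex) if id_regex else _UNIPROT_RE
    gene_re = re.compile(gene_regex)
    records: List[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        m = id_re.search(rec.id)
        pid = m.group(1) if m else rec.id
        g = gene_re.search(header)
        records.append(ProteinRecord(pid, str(rec.seq).upper(), g.group(1) if g else ""))
    return records


def map_peptide(sequence: str, protein: ProteinRecord) -> Optional[PeptideInterval]:
    """Locate a peptide in a protein; returns None when absent or when it
    maps more than once to the same protein (such peptides are dropped)."""
    first = protein.sequence.find(sequence)
    if first < 0:
        return None
    if protein.sequence.find(sequence, first + 1) >= 0:
        return None  # multi-mapping within one protein: ambiguous, dropped
    return PeptideInterval(protein.protein_id, first + 1, first + len(sequence), sequence)
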