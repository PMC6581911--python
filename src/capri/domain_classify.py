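"""Peptide-to-domain classification, composition statistics and RNA layers.

CAPRI-peptides (XL- and ADJ-peptides) are classified against Pfam domain and
intrinsically-disordered-region (IDR) annotations: a peptide overlapping a
known RNA-binding Pfam domain recapitulates a known interface, while the
rest point at novel interfaces, sub-categorised into novel Pfam domains,
novel IDRs and unannotated ("novel structured") regions.  Overlap means at
least one shared residue; Pfam takes priority over IDR when both overlap.

The module also holds the whitelist builder for RNA-binding Pfam domains
(literature + "ribosom" keyword + GO "RNA binding" + manual additions),
Fisher-exact amino-acid composition tests, crosslink-site composition, the
crosslinked-base tally, and the RNA-proximity layer assignment used for
complex visualisation (not_detected < FA < UV < ADJ < XL).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .adjacency import PeptideInterval
from .enrichment import bh_adjust

__all__ = [
    "DomainAnnotation",
    "PEPTIDE_CLASSES",
    "build_rbd_list",
    "classify_peptide",
    "composition_fisher",
    "crosslink_site_composition",
    "adduct_base_distribution",
    "LAYER_ORDER",
    "proximity_layers",
    "write_sif",
    "annotations_from_tsv",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

PEPTIDE_CLASSES = ("RBD_Pfam", "novel_Pfam", "novel_IDR", "novel_structured")


@dataclass(frozen=True)
class DomainAnnotation:
    """1-based inclusive protein interval carrying a Pfam/IDR label."""

    protein_id: str
    start: int
    end: int
    domain_id: str       # Pfam accession, or an IDR tag
    source: str          # "Pfam" | "MobiDB-IDR"
    is_rbd: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad interval {self.start}-{self.end}")
        if self.source not in ("Pfam", "MobiDB-IDR"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "MobiDB-IDR" and self.domain_id.startswith("PF"):
            raise ValueError("IDR records must not carry a Pfam accession")


def build_rbd_list(
    pfam_names: Mapping[str, str],
    keywords: Iterable[str] = ("ribosom",),
    go_rna_binding: Iterable[str] = (),
    manual: Iterable[str] = (),
    literature: Iterable[str] = (),
) -> Set[str]:
    """Union of the four whitelist sources of RNA-binding Pfam domains.

    ``pfam_names`` maps accession -> domain name; keyword matching on names
    is case-insensitive substring.  GO/manual/literature inputs are id
    iterables (no live database access).
    """
    selected: Set[str] = set()
    lowered = [k.lower() for k in keywords]
    for acc, name in pfam_names.items():
        lname = (name or "").lower()
        if any(k in lname for k in lowered):
            selected.add(acc)
    selected.update(go_rna_binding)
    selected.update(manual)
    selected.update(literature)
    return selected


def classify_peptide(
    peptide: PeptideInterval,
    annotations: Sequence[DomainAnnotation],
    protein_length: Optional[int] = None,
) -> str:
    """Four-way classification of one peptide interval.

    Priority: overlaps an RNA-binding Pfam -> ``RBD_Pfam``; else any Pfam ->
    ``novel_Pfam``; else an IDR -> ``novel_IDR``; else
    ``novel_structured``.
    """
    if protein_length is not None and peptide.end > protein_length:
        raise ValueError(
            f"peptide {peptide.start}-{peptide.end} exceeds protein length {protein_length}"
        )
    overlapping = [
        a
        for a in annotations
        if a.protein_id == peptide.protein_id
        and a.start <= peptide.end
        and peptide.start <= a.end
    ]
    if any(a.source == "Pfam" and a.is_rbd for a in overlapping):
        return "RBD_Pfam"
    if any(a.source == "Pfam" for a in overlapping):
        return "novel_Pfam"
    if any(a.source == "MobiDB-IDR" for a in overlapping):
        return "novel_IDR"
    return "novel_structured"


def composition_fisher(
    group_sequences: Iterable[str],
    background_sequences: Iterable[str],
) -> pd.DataFrame:
    """Per-amino-acid enrichment of a sequence group against a background.

    For each of the 20 residues a 2x2 table (this residue vs all others,
    group vs background) is tested with a two-sided Fisher exact test; the
    20 p-values are BH-corrected.  Returns count, percentage, odds_ratio
    (inf flagged for degenerate tables), p and q per residue.
    """
    group = "".join(group_sequences)
    background = "".join(background_sequences)
    if not group or not background:
        raise ValueError("both sequence groups must be non-empty")
    g_counts = {aa: group.count(aa) for aa in AMINO_ACIDS}
    b_counts = {aa: background.count(aa) for aa in AMINO_ACIDS}
    g_total, b_total = sum(g_counts.values()), sum(b_counts.values())

    rows = []
    for aa in AMINO_ACIDS:
        a, c = g_counts[aa], b_counts[aa]
        table = [[a, g_total - a], [c, b_total - c]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "residue": aa,
                "count": a,
                "percentage": 100.0 * a / g_total,
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("residue")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def crosslink_site_composition(site_residues: Iterable[str]) -> pd.DataFrame:
    """Percentage composition of resolved crosslink-site residues."""
    sites = [r for r in site_residues]
    if not sites:
        raise ValueError("no resolved crosslink sites")
    counts = {aa: sites.count(aa) for aa in AMINO_ACIDS}
    total = len(sites)
    return pd.DataFrame(
        {
            "count": pd.Series(counts),
            "percentage": pd.Series({aa: 100.0 * c / total for aa, c in counts.items()}),
        }
    ).rename_axis("residue")


def adduct_base_distribution(rna_summaries) -> Tuple[Dict[str, int], Dict[str, int]]:
    """Counts of crosslinked-base identity and of the full adduct
    nucleotide multiset, from :class:`~capri.ptm_catalog.RnaSummary` items."""
    base_counts: Dict[str, int] = {nt: 0 for nt in "ACGU"}
    multiset_counts: Dict[str, int] = {nt: 0 for nt in "ACGU"}
    for rna in rna_summaries:
        base_counts[rna.base] += 1
        for nt in rna.nt_multiset:
            multiset_counts[nt] += 1
    return base_counts, multiset_counts


#: RNA-proximity layer scale, outermost to innermost.
LAYER_ORDER: Tuple[str, ...] = ("not_detected", "FA", "UV", "ADJ", "XL")


def proximity_layers(
    complex_members: Iterable[str],
    memberships: Mapping[str, Set[str] | Sequence[str]],
) -> Tuple[Dict[str, int], List[Tuple[str, str, str, int]]]:
    """Assign each complex member its RNA-proximity layer.

    ``memberships`` maps dataset name ('FA', 'UV', 'ADJ', 'XL') to the set
    of detected proteins.  Layer = max over the ordered scale
    not_detected(0) < FA(1) < UV(2) < ADJ(3) < XL(4).  Returns the layer
    per protein and SIF edges ``("RNA", "pp", protein, weight)`` for every
    detected member (weight = layer score); undetected members get no edge.
    """
    sets = {name: set(members) for name, members in memberships.items()}
    unknown = set(sets) - set(LAYER_ORDER[1:])
    if unknown:
        raise ValueError(f"unknown dataset names: {sorted(unknown)}")
    layers: Dict[str, int] = {}
    edges: List[Tuple[str, str, str, int]] = []
    for protein in complex_members:
        score = 0
        for rank, name in enumerate(LAYER_ORDER[1:], start=1):
            if protein in sets.get(name, ()):
                score = rank
        layers[protein] = score
        if score > 0:
            edges.append(("RNA", "pp", protein, score))
    return layers, edges


def write_sif(edges: Iterable[Tuple[str, str, str, int]], sif_path, attr_path=None) -> None:
    """Emit a SIF edge list, and optionally a companion edge-weight table."""
    edges = list(edges)
    with open(sif_path, "w") as fh:
        for src, kind, dst, _w in edges:
            fh.write(f"{src}\t{kind}\t{dst}\n")
    if attr_path is not None:
        with open(attr_path, "w") as fh:
            fh.write("source\tinteraction\ttarget\tweight\n")
            for src, kind, dst, w in edges:
                fh.write(f"{src}\t{kind}\t{dst}\t{w}\n")


def annotations_from_tsv(path) -> List[DomainAnnotation]:
    """Read an annotation TSV (protein_id, start, end, accession, name,
    source, is_rbd)."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "start", "end", "accession", "source"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation TSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            DomainAnnotation(
                protein_id=str(row.protein_id),
                start=int(row.start),
                end=int(row.end),
                domain_id=str(row.accession),
                source=str(row.source),
                is_rbd=bool(getattr(row, "is_rbd", False)),
                name=str(getattr(row, "name", "") or ""),
            )
        )
    return out
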