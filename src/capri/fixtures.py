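"""Synthetic fixtures: proteomes, intensity tables and XL spectra.

Every downstream module is testable without downloads: this module emits the
same FASTA/MGF/TSV dialects the real pipeline consumes, together with ground
truth sufficient to score recall/FDR and classification tallies.  All
generators are deterministic for a fixed seed; substreams are derived from
one root ``numpy`` SeedSequence so partial re-runs are stable.

Default study conditions mirror the experimental design the method was run
under: four crosslinked vs four control replicates, log-normal null
intensities, spiked features shifted by log2(16) with sigma = 0.3 on the
log2 scale, missingness preferentially hitting low intensities, and a
crosslinked-base law with P(U) = 0.7 reflecting the strong uridine bias of
UV crosslinking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .adjacency import PeptideInterval, ProteinRecord, digest, extend_to_lysc
from .domain_classify import DomainAnnotation
from .ptm_catalog import AdductDefinition, PtmAssignment, build_catalog
from .xl_annotate import CrosslinkedPeptide, theoretical_ions

__all__ = [
    "FixtureSpec",
    "SpectrumNoise",
    "synth_proteome",
    "synth_intensity_table",
    "synth_xl_spectrum",
    "synth_study",
    "write_fasta",
    "write_annotations",
    "write_mgf",
]

# Amino-acid frequencies (rounded UniProt averages); K/R kept realistic so
# tryptic peptides have sensible lengths.
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_P = np.array(
    [8.3, 1.4, 5.5, 6.8, 3.9, 7.1, 2.3, 6.0, 5.8, 9.7, 2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.3, 6.9, 1.1, 2.9]
)
_AA_P = _AA_P / _AA_P.sum()

_PFAM_POOL = [
    ("PF00076", "RRM_1", True),
    ("PF00013", "KH_1", True),
    ("PF00270", "DEAD", True),
    ("PF00069", "Pkinase", False),
    ("PF00400", "WD40", False),
    ("PF07690", "MFS_1", False),
]


@dataclass
class SpectrumNoise:
    """Peak-level noise model for synthetic XL spectra."""

    n_decoys: int = 20
    mz_jitter_sd: float = 0.0          # Da, applied to true peaks
    decoy_intensity: float = 5.0
    marker_boost: float = 10.0         # markers dominate for di/tri adducts


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study; the seed is mandatory."""

    seed: int
    n_proteins: int = 24
    length_range: Tuple[int, int] = (150, 500)
    p_domain: float = 0.7              # chance a protein carries a Pfam domain
    p_idr: float = 0.5
    # intensity spike design (crosslinked vs control label-free table)
    n_features: int = 500
    n_spiked: int = 50
    fold: float = 16.0
    sigma_log2: float = 0.3
    missing_rate: float = 0.1
    n_crosslinked: int = 4
    n_control: int = 4
    # crosslinked-base law: strong uridine preference of UV crosslinking
    base_probs: Dict[str, float] = field(
        default_factory=lambda: {"U": 0.7, "A": 0.12, "G": 0.09, "C": 0.09}
    )
    noise: SpectrumNoise = field(default_factory=SpectrumNoise)

    def __post_init__(self) -> None:
        for rate in (self.p_domain, self.p_idr, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if abs(sum(self.base_probs.values()) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic substream ``stream`` of the root seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])


def synth_proteome(spec: FixtureSpec) -> Tuple[List[ProteinRecord], List[DomainAnnotation]]:
    """Random proteome with planted Pfam/IDR intervals recorded as truth."""
    rng = spec.rng(0)
    proteins: List[ProteinRecord] = []
    annotations: List[DomainAnnotation] = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = "".join(rng.choice(_AA, size=length, p=_AA_P))
        pid = f"SYN{i:04d}"
        proteins.append(ProteinRecord(pid, seq, gene_id=f"gene{i:04d}"))
        if rng.random() < spec.p_domain:
            acc, name, is_rbd = _PFAM_POOL[int(rng.integers(len(_PFAM_POOL)))]
            dlen = int(rng.integers(40, 90))
            start = int(rng.integers(1, max(2, length - dlen)))
            annotations.append(
                DomainAnnotation(pid, start, min(length, start + dlen - 1), acc, "Pfam", is_rbd, name)
            )
        if rng.random() < spec.p_idr:
            ilen = int(rng.integers(20, 60))
            start = int(rng.integers(1, max(2, length - ilen)))
            annotations.append(
                DomainAnnotation(pid, start, min(length, start + ilen - 1), f"IDR_{pid}", "MobiDB-IDR")
            )
    return proteins, annotations


def synth_intensity_table(
    spec: FixtureSpec,
    feature_ids: Optional[Sequence[str]] = None,
    spiked_ids: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, Dict[str, str], List[str]]:
    """Raw-intensity table (features x samples) with a planted enrichment.

    Null features are log-normal around 2^20; spiked features are shifted by
    log2(fold) in the crosslinked group.  Missingness (zeros) is applied
    preferentially to the lowest intensities.  Returns ``(table, groups,
    spiked_ids)``; table cells are raw intensities with 0 = missing.
    """
    rng = spec.rng(1)
    if feature_ids is None:
        feature_ids = [f"feat{i:05d}" for i in range(spec.n_features)]
    feature_ids = list(feature_ids)
    if spiked_ids is None:
        spiked_ids = feature_ids[: spec.n_spiked]
    spiked = set(spiked_ids)

    samples = [f"xl{i+1}" for i in range(spec.n_crosslinked)] + [
        f"ctrl{i+1}" for i in range(spec.n_control)
    ]
    groups = {s: ("crosslinked" if s.startswith("xl") else "control") for s in samples}

    base = rng.normal(20.0, 1.5, size=len(feature_ids))
    log2 = base[:, None] + rng.normal(0.0, spec.sigma_log2, size=(len(feature_ids), len(samples)))
    shift = np.log2(spec.fold)
    for i, fid in enumerate(feature_ids):
        if fid in spiked:
            log2[i, : spec.n_crosslinked] += shift
    raw = np.exp2(log2)

    if spec.missing_rate > 0:
        flat = raw.ravel()
        order = np.argsort(flat)
        n_missing = int(round(spec.missing_rate * flat.size))
        # missingness preferentially at low intensity: sample the missing
        # cells from the lowest third with high probability
        pool = order[: max(n_missing, flat.size // 3)]
        chosen = rng.choice(pool, size=n_missing, replace=False)
        flat[chosen] = 0.0
        raw = flat.reshape(raw.shape)

    table = pd.DataFrame(raw, index=feature_ids, columns=samples)
    return table, groups, list(spiked_ids)


def synth_xl_spectrum(
    xl: CrosslinkedPeptide,
    noise: Optional[SpectrumNoise] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, List]:
    """Peak list for an XL candidate: theoretical ions +- jitter + decoys.

    Markers are given the largest intensities when the adduct carries more
    than one nucleotide, emulating the observed marker-dominated base peak of
    dinucleotide conjugates.  Returns ``(peaks, truth_ions)``.
    """
    noise = noise or SpectrumNoise()
    rng = rng or np.random.default_rng(0)
    ions = theoretical_ions(xl)
    multi = sum(len(a.nt_multiset) for a in xl.assignment.terminal_adducts.values()) >= 1

    peaks: List[Tuple[float, float]] = []
    for ion in ions:
        intensity = float(rng.uniform(50.0, 100.0))
        if ion.series == "marker" and multi:
            intensity *= noise.marker_boost
        elif ion.series == "precursor_NL":
            intensity *= 2.0
        m = ion.mz + (rng.normal(0.0, noise.mz_jitter_sd) if noise.mz_jitter_sd > 0 else 0.0)
        peaks.append((m, intensity))

    top = max(m for m, _ in peaks)
    for _ in range(noise.n_decoys):
        peaks.append((float(rng.uniform(100.0, top + 50.0)), noise.decoy_intensity))

    arr = np.array(peaks, dtype=float)
    return arr[np.argsort(arr[:, 0])], ions


def write_fasta(proteins: Sequence[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">sp|{p.protein_id}|{p.protein_id}_SYN GN={p.gene_id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


def write_annotations(annotations: Sequence[DomainAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\taccession\tname\tsource\tis_rbd\n")
        for a in annotations:
            fh.write(
                f"{a.protein_id}\t{a.start}\t{a.end}\t{a.domain_id}\t{a.name}\t"
                f"{a.source}\t{a.is_rbd}\n"
            )


def write_mgf(records: Sequence[dict], path) -> None:
    """Write spectra dicts (id, pepmass, charge, peaks) as MGF."""
    from pyteomics import mgf

    out = []
    for rec in records:
        out.append(
            {
                "m/z array": rec["peaks"][:, 0],
                "intensity array": rec["peaks"][:, 1],
                "params": {
                    "title": rec["id"],
                    "pepmass": rec["pepmass"],
                    "charge": [rec["charge"]],
                },
            }
        )
    mgf.write(out, str(path), file_mode="w")


def _class_of(peptide: PeptideInterval, annotations: Sequence[DomainAnnotation]) -> str:
    """Generator-side class bookkeeping for the truth file (simple loop,
    intentionally independent of domain_classify internals)."""
    rbd = pfam = idr = False
    for a in annotations:
        if a.protein_id != peptide.protein_id:
            continue
        if min(a.end, peptide.end) - max(a.start, peptide.start) >= 0:
            if a.source == "Pfam" and a.is_rbd:
                rbd = True
            elif a.source == "Pfam":
                pfam = True
            else:
                idr = True
    if rbd:
        return "RBD_Pfam"
    if pfam:
        return "novel_Pfam"
    if idr:
        return "novel_IDR"
    return "novel_structured"


def synth_study(spec: FixtureSpec, outdir) -> Dict[str, object]:
    """Emit a complete synthetic study for the end-to-end pipeline.

    Writes proteome FASTA, domain annotation TSV, a MaxQuant-style peptide
    intensity table whose spiked features are real tryptic peptides next to
    the planted domains, an XL-peptide table, a complex membership table and
    a ground-truth JSON.  Returns the path dict plus the truth dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteins, annotations = synth_proteome(spec)
    rng = spec.rng(2)
    catalog = {d.name: d for d in build_catalog()}

    # candidate tryptic peptides (0 missed cleavages, length >= 6)
    candidates: List[PeptideInterval] = []
    by_protein = {p.protein_id: p for p in proteins}
    for p in proteins:
        for pep in digest(p, "TrypsinP", 0):
            if len(pep.sequence) >= 6 and pep.sequence.count(pep.sequence[:3]) == 1:
                candidates.append(pep)
    # drop duplicated sequences so peptide -> protein mapping is unique
    seq_counts: Dict[str, int] = {}
    for pep in candidates:
        seq_counts[pep.sequence] = seq_counts.get(pep.sequence, 0) + 1
    candidates = [p for p in candidates if seq_counts[p.sequence] == 1]

    rbd_annos = [a for a in annotations if a.source == "Pfam"]
    near_domain = [
        pep
        for pep in candidates
        if any(
            a.protein_id == pep.protein_id and a.start <= pep.end and pep.start <= a.end
            for a in rbd_annos
        )
    ]
    n_spiked = min(spec.n_spiked, len(near_domain))
    order = rng.permutation(len(near_domain))
    spiked_peps = [near_domain[i] for i in order[:n_spiked]]
    spiked_set = {p.sequence for p in spiked_peps}
    nulls = [p for p in candidates if p.sequence not in spiked_set]
    n_null = min(spec.n_features - n_spiked, len(nulls))
    order = rng.permutation(len(nulls))
    chosen = spiked_peps + [nulls[i] for i in order[:n_null]]

    feature_ids = [p.sequence for p in chosen]
    table, groups, spiked_ids = synth_intensity_table(
        spec, feature_ids=feature_ids, spiked_ids=[p.sequence for p in spiked_peps]
    )

    peptides_tsv = outdir / "peptides.tsv"
    mq = table.copy()
    mq.columns = [f"Intensity {c}" for c in mq.columns]
    mq.insert(0, "Sequence", table.index)
    mq.insert(
        1,
        "Proteins",
        [next(p.protein_id for p in chosen if p.sequence == s) for s in table.index],
    )
    mq["Potential contaminant"] = ""
    mq["Reverse"] = ""
    mq.to_csv(peptides_tsv, sep="\t", index=False, float_format="%.4f")

    # XL-peptides: crosslinks planted inside the Pfam intervals
    xl_rows = []
    bases = list(spec.base_probs)
    probs = [spec.base_probs[b] for b in bases]
    terminals = [None, "rest", "cyclic_rest", "A_plus_rest", "U_plus_rest", "AU_plus_rest"]
    for k, pep in enumerate(spiked_peps[: max(4, n_spiked // 3)]):
        base = rng.choice(bases, p=probs)
        site = int(rng.integers(1, len(pep.sequence) + 1))
        term = terminals[int(rng.integers(len(terminals)))]
        xl_rows.append(
            {
                "spectrum_id": f"xl_spec_{k:03d}",
                "protein_id": pep.protein_id,
                "peptide": pep.sequence,
                "start": pep.start,
                "end": pep.end,
                "site": site,
                "base": base,
                "terminal": term or "",
                "charge": 2,
            }
        )
    xl_tsv = outdir / "xl_peptides.tsv"
    pd.DataFrame(xl_rows).to_csv(xl_tsv, sep="\t", index=False)

    # complex membership and dataset memberships for the layer assignment
    adj_proteins = sorted({p.protein_id for p in spiked_peps})
    xl_proteins = sorted({r["protein_id"] for r in xl_rows})
    all_ids = [p.protein_id for p in proteins]
    fa = sorted(set(adj_proteins) | set(all_ids[: len(all_ids) // 2]))
    uv = sorted(set(adj_proteins) | set(all_ids[: len(all_ids) // 3]))
    complexes_tsv = outdir / "complexes.tsv"
    with open(complexes_tsv, "w") as fh:
        fh.write("complex_id\tprotein_id\n")
        for pid in all_ids:
            fh.write(f"toy_complex\t{pid}\n")
    memberships_tsv = outdir / "memberships.tsv"
    with open(memberships_tsv, "w") as fh:
        fh.write("dataset\tprotein_id\n")
        for name, members in (("FA", fa), ("UV", uv), ("ADJ", adj_proteins), ("XL", xl_proteins)):
            for pid in members:
                fh.write(f"{name}\t{pid}\n")

    fasta = outdir / "proteome.fasta"
    anno_tsv = outdir / "annotations.tsv"
    write_fasta(proteins, fasta)
    write_annotations(annotations, anno_tsv)

    # ground truth for scoring: ADJ-peptide classes from the planted layout
    truth_adj = {}
    for pep in spiked_peps:
        ext = extend_to_lysc(pep, by_protein[pep.protein_id])
        truth_adj[pep.sequence] = {
            "protein_id": pep.protein_id,
            "extended": [ext.start, ext.end],
            "class": _class_of(ext, annotations),
        }
    truth = {
        "seed": spec.seed,
        "spiked": [p.sequence for p in spiked_peps],
        "adj_truth": truth_adj,
        "xl_rows": xl_rows,
        "memberships": {"FA": fa, "UV": uv, "ADJ": adj_proteins, "XL": xl_proteins},
    }
    truth_json = outdir / "truth.json"
    with open(truth_json, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)

    return {
        "fasta": fasta,
        "annotations": anno_tsv,
        "peptides": peptides_tsv,
        "xl_peptides": xl_tsv,
        "complexes": complexes_tsv,
        "memberships": memberships_tsv,
        "truth": truth,
        "truth_json": truth_json,
        "groups": groups,
    }
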