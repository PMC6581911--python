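"""End-to-end orchestration: enrich -> extend/merge -> classify -> layers.

The pipeline ties the library modules into the dataflow of the method: the
label-free peptide table is tested for crosslink enrichment, surviving
tryptic peptides are mapped to the proteome, extended to Lys-C units and
merged into ADJ-peptides; ADJ- and XL-peptides are classified against the
domain/IDR annotation, their overlap is computed, and complex members are
assigned RNA-proximity layers.  Every run writes a machine-readable summary
and a provenance record (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import pandas as pd

from . import __version__
from .adjacency import (
    ExtendedPeptide,
    PeptideInterval,
    extend_to_lysc,
    map_peptide,
    merge_adjacent,
    read_fasta,
    xl_adj_overlap,
)
from .domain_classify import (
    annotations_from_tsv,
    classify_peptide,
    proximity_layers,
    write_sif,
)
from .enrichment import read_maxquant_table, run_contrast

__all__ = ["run_pipeline", "infer_groups"]


def infer_groups(path) -> Dict[str, str]:
    """Derive the sample design from ``Intensity <sample>`` column names:
    samples beginning with ``xl``/``uv``/``fa`` are crosslinked, the rest
    control."""
    header = pd.read_csv(path, sep="\t", nrows=0).columns
    groups: Dict[str, str] = {}
    for col in header:
        if col.startswith("Intensity "):
            sample = col[len("Intensity "):]
            crosslinked = sample.lower().startswith(("xl", "uv", "fa"))
            groups[sample] = "crosslinked" if crosslinked else "control"
    if not groups:
        raise ValueError(f"no 'Intensity <sample>' columns in {path}")
    return groups


def _read_memberships(path) -> Dict[str, List[str]]:
    df = pd.read_csv(path, sep="\t")
    out: Dict[str, List[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.dataset), []).append(str(row.protein_id))
    return out


def run_pipeline(
    fasta,
    peptides_tsv,
    annotations_tsv,
    outdir,
    xl_tsv=None,
    memberships_tsv=None,
    complexes_tsv=None,
    preset: str = "ADJ",
    groups: Optional[Mapping[str, str]] = None,
    seed: Optional[int] = None,
    xl_extension: int = 30,
) -> dict:
    """Run the full analysis and write results under ``outdir``.

    Returns the summary dict (also written as ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    proteins = {p.protein_id: p for p in read_fasta(fasta)}
    annotations = annotations_from_tsv(annotations_tsv)
    if groups is None:
        groups = infer_groups(peptides_tsv)
    matrix = read_maxquant_table(peptides_tsv, groups)

    stats = run_contrast(matrix, preset)
    selected = stats.index[stats["selected"]].tolist()

    # map, extend, merge
    extended: List[ExtendedPeptide] = []
    unmapped = 0
    for seq in selected:
        hits = [map_peptide(seq, p) for p in proteins.values()]
        hits = [h for h in hits if h is not None]
        if len(hits) != 1:
            unmapped += 1
            continue
        pep = hits[0]
        ext = extend_to_lysc(pep, proteins[pep.protein_id])
        extended.append(
            ExtendedPeptide(
                interval=ext,
                members=[pep],
                q_value=float(stats.loc[seq, "q"]),
                fold_change=float(stats.loc[seq, "ratio"]),
            )
        )
    adj = merge_adjacent(extended)

    adj_rows = []
    for ep in adj:
        adj_rows.append(
            {
                "protein_id": ep.interval.protein_id,
                "start": ep.interval.start,
                "end": ep.interval.end,
                "sequence": ep.interval.sequence,
                "members": ";".join(m.sequence for m in ep.members),
                "q_value": ep.q_value,
                "fold_change": ep.fold_change,
                "class": classify_peptide(ep.interval, annotations),
            }
        )
    adj_df = pd.DataFrame(adj_rows)
    adj_df.to_csv(outdir / "adj_peptides.tsv", sep="\t", index=False)

    summary: dict = {
        "n_peptides_tested": int(len(stats)),
        "n_peptides_selected": int(len(selected)),
        "n_unmapped": unmapped,
        "n_adj_peptides": int(len(adj)),
        "n_adj_proteins": int(adj_df["protein_id"].nunique()) if len(adj_df) else 0,
        "adj_class_tally": (
            adj_df["class"].value_counts().to_dict() if len(adj_df) else {}
        ),
    }

    if xl_tsv is not None:
        xl_df = pd.read_csv(xl_tsv, sep="\t")
        xl_intervals = [
            PeptideInterval(str(r.protein_id), int(r.start), int(r.end), str(r.peptide))
            for r in xl_df.itertuples(index=False)
        ]
        xl_classes = [classify_peptide(p, annotations) for p in xl_intervals]
        lengths = {pid: len(p) for pid, p in proteins.items()}
        flags = xl_adj_overlap(
            xl_intervals, [ep.interval for ep in adj], extension=xl_extension, protein_lengths=lengths
        )
        xl_df["class"] = xl_classes
        xl_df["adj_overlap"] = flags
        xl_df.to_csv(outdir / "xl_classified.tsv", sep="\t", index=False)
        tal: Dict[str, int] = {}
        for c in xl_classes:
            tal[c] = tal.get(c, 0) + 1
        summary["n_xl_peptides"] = int(len(xl_df))
        summary["xl_class_tally"] = tal
        summary["xl_adj_overlap"] = {
            flag: flags.count(flag) for flag in ("direct_overlap", "overlap_after_extension", "none")
        }

    if memberships_tsv is not None:
        memberships = {k: set(v) for k, v in _read_memberships(memberships_tsv).items()}
        if complexes_tsv is not None:
            cx = pd.read_csv(complexes_tsv, sep="\t")
            members = [str(r.protein_id) for r in cx.itertuples(index=False)]
        else:
            members = sorted(proteins)
        layers, edges = proximity_layers(members, memberships)
        write_sif(edges, outdir / "complex.sif", outdir / "complex_edges.tsv")
        summary["layers"] = layers
        summary["n_sif_edges"] = len(edges)

    provenance = {
        "version": __version__,
        "seed": seed,
        "preset": preset,
        "inputs": {
            "fasta": str(fasta),
            "peptides": str(peptides_tsv),
            "annotations": str(annotations_tsv),
            "xl": str(xl_tsv) if xl_tsv else None,
        },
    }
    provenance["config_hash"] = hashlib.sha256(
        json.dumps(provenance, sort_keys=True).encode()
    ).hexdigest()[:16]
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
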