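# capri

Mapping RNA-binding regions of proteins from UV-crosslinking mass
spectrometry: an implementation of the CAPRI analysis (Crosslinked and
Adjacent Peptides-based RNA-binding domain Identification).

After in-vivo UV crosslinking and polyA+ interactome capture, two kinds of
peptides report where a protein touches RNA:

* **XL-peptides** — peptides still carrying a covalent ribonucleotide adduct
  (1–3 nt after exhaustive nuclease trimming), identified from their MS/MS
  spectra; they localise the contact down to a single amino acid.
* **ADJ-peptides** — ordinary tryptic peptides released *next to* the
  crosslinked residue during the two-protease (Lys-C then trypsin) workflow;
  they are abundant, quantifiable by standard label-free proteomics, and are
  extended in silico back to their Lys-C unit to cover the neighbouring
  crosslink site.

This package implements the computational side of that workflow for
proteomics bioinformaticians: the RNA-adduct PTM catalogue, heteroconjugate
spectrum annotation and filtering, the enrichment statistics, the interval
algebra for extension/merging/overlap, and the peptide-to-domain
classification. All standard formats (FASTA, MGF, MaxQuant-style TSV, SIF)
are read and written; a synthetic-data module makes the whole pipeline
testable without any downloads.

## The model in brief

**RNA adducts as split PTMs.** In HCD/CID the glycosidic and phosphodiester
bonds of the adduct cleave preferentially while the base–side-chain bond
survives, so each crosslinked ribonucleotide is modelled as two
modifications: the nucleobase (A′, G′, C′, U′, mass of the free base) fixed
on the crosslinked residue, and the "rest" (ribose + PO₄, 212.008589 Da;
"cyclic-rest" = rest − H₂O for the 2′,3′-cyclic phosphate) annotated at a
peptide terminus. Non-crosslinked nucleotides of di/trinucleotide adducts
fold into the terminal modification as whole mononucleotides. Enumerating
all adduct compositions of up to 3 nt needs only **34 RNA-PTM definitions**
(4 bases + 2 rests + 4×2 mononucleotide + 10×2 unordered dinucleotide
composites). Combinations that are biochemically impossible ("rest" without
a base, two terminal adducts, …) are rejected with machine-readable reasons.

**Spectrum annotation.** Theoretical ions for an XL candidate comprise the
b/y series (base mass riding on fragments containing the crosslink site),
the precursor neutral-loss ladder (−HPO₃, −rest, −whole mononucleotides,
down to the bare peptide+base conjugate) and the low-m/z marker ions:
protonated bases at nominal m/z 136 (A′), 152 (G′), 112 (C′), 113 (U′) and
protonated cyclic mononucleotides at 330/312 (A), 306 (C), 307 (U). Peaks
match greedily within 0.02 Da.

**Enrichment.** Crosslinked vs control intensities are compared with an
empirical-Bayes moderated t-test (variance shrinkage s̃²g = (d₀s₀² + dg s²g)
/(d₀+dg), prior fitted by method of moments), Benjamini–Hochberg correction,
and a strict >8-fold raw mean-intensity filter. Presets: protein-level
RBPome (FDR 1%, >2 unique peptides), peptide-level ADJ (FDR 5%) and FA-dom
(FDR 15%, detected in ≥2 crosslinked replicates).

**Classification.** CAPRI-peptides are classified against Pfam/IDR
annotations into `RBD_Pfam`, `novel_Pfam`, `novel_IDR` and
`novel_structured` (≥1 shared residue; Pfam before IDR), and complex members
get RNA-proximity layers (not-detected < FA < UV < ADJ < XL) emitted as a
Cytoscape-ready SIF network.

## Worked example

Simulate a small study and run the full pipeline:

```sh
capri simulate --seed 7 --outdir demo
capri pipeline --fasta demo/proteome.fasta --peptides demo/peptides.tsv \
    --annotations demo/annotations.tsv --xl demo/xl_peptides.tsv \
    --memberships demo/memberships.tsv --complex-members demo/complexes.tsv \
    --seed 7 --outdir demo/out
```

which prints (layer map omitted):

```json
{
 "adj_class_tally": {"RBD_Pfam": 15, "novel_Pfam": 28},
 "n_adj_peptides": 43,
 "n_adj_proteins": 15,
 "n_peptides_selected": 50,
 "n_peptides_tested": 446,
 "n_sif_edges": 20,
 "n_unmapped": 0,
 "n_xl_peptides": 16,
 "xl_adj_overlap": {"direct_overlap": 16, "none": 0, "overlap_after_extension": 0},
 "xl_class_tally": {"RBD_Pfam": 7, "novel_Pfam": 9}
}
```

Reading: of 446 tryptic peptides tested, the 50 planted enriched peptides
were selected at FDR 5% + eightfold, merged into 43 Lys-C-extended
ADJ-peptides on 15 proteins; 15 ADJ-peptides overlap the whitelisted
RNA-binding Pfam domains and 28 identify other Pfam domains as candidate
novel interfaces; all 16 planted XL-peptides overlap an ADJ-peptide
directly. `demo/out/` also contains `adj_peptides.tsv`,
`xl_classified.tsv`, the `complex.sif` network and a provenance record.

The catalogue itself:

```sh
capri catalog --out demo/catalog.tsv   # -> "wrote 34 RNA-PTM definitions"
```

## Layout

| module | contents |
| --- | --- |
| `capri.chem` | atomic/residue mass table, compositions, m/z arithmetic |
| `capri.ptm_catalog` | the 34 RNA-PTM definitions, combination validation, RNA inference |
| `capri.xl_annotate` | theoretical ions, spectrum annotation, XL filters, MGF I/O |
| `capri.adjacency` | digestion, Lys-C extension, merging, isoforms, coverage, XL–ADJ overlap |
| `capri.enrichment` | moderated t-test, BH, fold filter, dataset presets |
| `capri.domain_classify` | RBD whitelist, peptide classes, composition stats, proximity layers |
| `capri.fixtures` | seeded synthetic proteomes, intensity tables, spectra, full studies |
| `capri.pipeline` / `capri.cli` | orchestration and the `capri` command |

Coordinates are 1-based inclusive throughout. See `docs/methods.md` for the
statistical model, parameter defaults and known limitations.
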