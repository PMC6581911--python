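# Methods

This note documents the models and numerical choices behind the package, in
the order data flows through the pipeline.

## RNA-adduct mass model

All masses derive from one table of monoisotopic atomic masses
(`capri.chem.ATOMIC_MASSES`, IUPAC/CODATA values to ≥6 decimals, exportable
to TSV for audit). Peptide mass = Σ residue masses + H₂O; cysteine
carbamidomethylation (+57.021464 Da) is a per-run switch, on by default to
match iodoacetamide alkylation.

A crosslinked ribonucleotide is treated additively: the heteroconjugate
neutral mass is the peptide mass plus the adduct masses, with no mass delta
at the covalent bond. Each nucleotide splits into the nucleobase (on the
crosslinked residue) and the ribose-phosphate "rest" (C₅H₉O₇P,
212.008589 Da, annotated at a terminus because it dissociates during
HCD/CID). The cyclic variant subtracts one water (2′,3′-cyclic phosphate
left by RNases). A terminal adduct carrying k non-crosslinked nucleotides
has composition Σ mononucleotide compositions + rest, i.e. each extra
nucleotide contributes a full NMP (base + rest); condensation water is not
subtracted, consistent with the additive bookkeeping of search-engine PTMs.
The terminus choice (N vs C) carries no mass information and is normalised
to N on output.

The catalogue for adducts of ≤3 nt therefore contains 34 definitions:
4 bases + {rest, cyclic-rest} + 4 mononucleotide composites ×2 + 10
unordered dinucleotide composites ×2. Dinucleotide compositions are
unordered multisets because a mass modification cannot encode sequence
order. Cyclic variants of the di-composites are included; disabling them
(`include_cyclic=False`) yields 19 definitions.

A valid PTM combination on one peptide has exactly one nucleobase adduct
(the crosslink site — multi-site peptides are rejected with their own
reason code so the policy can be relaxed), at most one terminal adduct, at
most 3 adducts total, and an implied RNA of 1–3 nt. Base-only peptides are
valid: the glycosidic bond can cleave during preparation or in-source.

## Spectrum annotation

Theoretical ions for an XL candidate:

* b/y fragments at charges 1..(precursor charge − 1), with the base mass on
  every fragment containing the crosslink residue and the terminal adduct on
  none of them. a-ions, non-marker immonium ions and internal fragments are
  not generated; annotated spectra of this ion chemistry use b/y + markers +
  precursor-loss ions.
* A precursor neutral-loss ladder at charges up to the precursor charge:
  [M], [M−HPO₃], [M−rest], then loss of whole mononucleotides down to the
  peptide+base conjugate. Successive rungs differ by HPO₃ (79.966331 Da),
  anhydro-ribose (132.042259 Da) or an NMP.
* Singly charged marker ions for every base in the adduct: protonated base,
  protonated cyclic mononucleotide, protonated mononucleotide; the second
  water loss from protonated cyclic AMP (330 → 312) is emitted for
  adenosine only.

Ions below the acquisition floor (default m/z 100, the fixed lowest recorded
MS2 mass) are suppressed. Matching is nearest-peak within an absolute
0.02 Da fragment tolerance (the instrument setting the method was tuned
for); ties break toward higher intensity, and each peak is assigned to at
most one theoretical ion. Annotation is invariant to peak order and
intensity rescaling.

The spectrum-level filters stand in for manual curation and are plain
config values, not fitted: minimum combined b/y coverage 0.4, and ≥1
matched marker ion required for di/trinucleotide adducts (none for
base-only/mononucleotide candidates, whose bases stay bound and produce no
markers). Heteroconjugate identity for the de-duplicated summary counts is
(peptide sequence, RNA multiset, crosslink site).

## Adjacency interval algebra

Coordinates are 1-based inclusive. Lys-C cleaves C-terminal to K; trypsin
is modelled as trypsin/P (cleaves C-terminal to K/R, including before
proline) to match the stated search-engine settings; protein termini count
as boundaries. Digestion emits all products with 0..m missed cleavages; at
0 the products tile the protein.

Extension to the Lys-C unit takes the nearest K strictly left of the
peptide (start = that position + 1, else 1) and the nearest K at/after its
end (else the protein end); it is idempotent and monotone. Peptides are
merged only when their extended intervals are identical — overlapping but
distinct Lys-C units (possible with missed cleavages) stay separate; the
merged record keeps the member list and the best (minimum) q-value.
Peptides mapping more than once to the same protein are dropped. Isoform
selection per gene orders by (mapped peptide count desc, length desc,
lexicographic id) — the id tie-break is ours, for determinism. The XL–ADJ
overlap flag widens the XL interval by ±30 residues (the mid-range tryptic
peptide length), clipped to the protein.

## Enrichment statistics

Features are peptides or protein groups; samples carry a two-group design
(crosslinked vs control, ≥2 replicates each). Contaminant and reverse-hit
rows are dropped. Missing values (intensity 0) are imputed with the global
minimum observed intensity — a per-feature variant exists behind config but
the global minimum is the default. Testing is on log2 intensities; the
fold filter uses raw group means (ratio strictly > 8); a geometric-mean
variant is available (`on_log_means=True`) since either reading of an
"average intensity cutoff" is defensible — the arithmetic-mean raw ratio is
the default and the choice is logged in the result metadata.

The moderated t-test shrinks per-feature pooled variances s²g (dg = n₁+n₂−2
df) toward a prior s₀² with d₀ df: s̃²g = (d₀s₀² + dg s²g)/(d₀+dg),
t̃g = Δmean/(s̃g·√(1/n₁+1/n₂)), two-sided p from t with d₀+dg df. The prior
is fitted by method of moments on log sample variances (Smyth 2004 closed
forms; trigamma inversion by Newton iteration). When the spread of log
variances does not exceed the chi-square sampling expectation the moment
equation has no finite solution; d₀ = ∞ is used with a warning, s̃ = s₀ and
a normal reference distribution. This is the correct limit for
homoskedastic data, and our homoskedastic simulations do reach it. The
implementation agrees with Bioconductor limma (eBayes) to ~1e-11 on a
frozen reference fixture; no intensity-trend on the prior is modelled.
BH correction is the standard step-up (via statsmodels), validated against
a brute-force oracle.

Dataset presets: RBPome (FDR < 0.01, > 2 unique peptides per protein
group), ADJ (FDR < 0.05), FAdom (FDR < 0.15, detected — nonzero raw
intensity, evaluated **before** imputation — in ≥2 crosslinked replicates).
All three end with the strict eightfold filter. Selection is monotone in
both thresholds.

## Classification and layers

Peptide–annotation overlap means ≥1 shared residue; no minimum-overlap
fraction is applied (a fractional option exists, default off). Priority is
RNA-binding Pfam > any Pfam > IDR > unannotated, reflecting that domain
assignment is more informative than disorder when both cover the peptide.
XL- and ADJ-peptides are classified by identical rules and kept as separate
tracks, appended without merging. The RBD whitelist is the union of a
literature list, case-insensitive keyword matches ("ribosom") on domain
names, GO "RNA binding" accessions and a manual list — all consumed as
input tables, never fetched live.

Amino-acid composition contrasts use two-sided Fisher exact tests on 2×2
tables (residue vs not, group vs background) with BH over the 20 residues;
degenerate tables report infinite odds ratios explicitly. Crosslink-site
composition is a plain percentage table over resolved sites.

Proximity layers score each protein by the most RNA-proximal dataset it
appears in: not-detected (0) < FA (1) < UV (2) < ADJ (3) < XL (4). The SIF
output adds an "RNA" node with an edge to every detected member, weighted
by the layer rank — the rank-as-weight semantics is our choice, recorded in
the companion edge-attribute table.

## Synthetic data

The generators emulate the study conditions the statistics were designed
for: 4+4 replicate label-free tables with log-normal nulls (log2 base
N(20, 1.5), replicate noise σ = 0.3), spiked features shifted by log2(16),
and ~10% missingness targeted at the lowest intensities; proteomes with
UniProt-like average amino-acid frequencies and planted Pfam/IDR intervals;
XL spectra built from the theoretical ions with optional m/z jitter and
decoy peaks, markers boosted to dominate di/trinucleotide spectra; and a
crosslinked-base law with P(U) = 0.7 matching the uridine bias of UV
crosslinking. Everything is driven by one seed through named SeedSequence
substreams, so reruns are byte-identical and partial reruns are stable.

What the fixtures do **not** model: retention-time/ionisation effects,
intensity-dependent variance trends, correlated missingness across
replicates, shared peptides between proteins, isotope envelopes and
chimeric spectra. Passing tests therefore demonstrate correctness of the
algebra and calibration of the statistics under idealised noise, not
instrument-level performance on real data.

## Problem sizes and tolerances

Simulation-based checks use 5000 features for null calibration (type-I
error at p<0.05 within ±0.02, Kolmogorov–Smirnov uniformity at α = 0.01),
500 features with 50 spiked 16-fold for recovery (recall ≥ 0.9, realised
FDR ≤ 0.1), and 2000 features for variance-prior recovery (within 20%) —
sizes chosen to keep Monte-Carlo error well inside those margins while the
whole suite runs in seconds. Mass assertions use 1e-6 Da; exact-identity
float comparisons (e.g. fragment complementarity) use 1e-9 Da. Headline
dataset sizes of real studies (hundreds of XL-peptides, thousands of
ADJ-peptides) depend on raw instrument data and external search engines and
are out of scope; the package consumes such search-engine outputs.

## Known limitations

* De novo sequencing and whole-proteome peptide-spectrum search are out of
  scope — the annotator scores given candidate peptides.
* Only the additive adduct model is implemented; crosslink-chemistry mass
  deltas (e.g. −H₂O at the covalent bond) are not.
* Non-canonical nucleosides (thio-U, m6A), DNA adducts and adducts >3 nt
  are not modelled.
* The protein-level contrast takes protein groups as given rows; no
  protein inference or razor-peptide logic.
* ETD/EThcD fragmentation and isotope-pattern modelling are not supported.
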