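# Methods

## Problem setting

A 5′-truncated isoform shows up in three largely independent data layers:
the exon-level RNA-seq profile (silent 5′ exons, expressed 3′ block), the
chromatin landscape (an internal active-promoter signature with a
Polycomb-repressed 5′ gene body), and the proteome (peptides confined to
the shared C-terminal region, at treatment-dependent abundance). The
package treats each layer as a separate, individually testable stage and
combines them into one report; no stage's verdict is fed back to modify
another's input.

## Coordinate conventions

All internal coordinates are 0-based half-open; GTF/GFF3 input (1-based
inclusive) is converted at the parsing boundary and nowhere else. Exon
indices are 1-based in transcript 5′→3′ order regardless of strand, so
"exon 23" means the same thing for plus- and minus-strand genes.
Transcript coordinates are nucleotide offsets along the spliced mRNA;
protein coordinates are 1-based residues on the canonical protein.

## Breakpoint model

The expression phenomenon is a single step: a 5′-silent block followed by
a 3′-active block. The caller therefore fits exactly one changepoint *k*,
scoring each candidate split by the difference of block means of
log₂(RPKM+1) and searching k = 2…E exhaustively (exact for transcript-scale
E; ties go to the smallest k, i.e. the longest short isoform consistent
with the data). The pseudocount of 1 RPKM makes the transform zero-safe.
Classification applies three conventions, all configurable: a block is
"off" below τ_off = 0.1 RPKM, "on" above τ_on = 1 RPKM, and a short call
additionally needs a block contrast of δ = 1 log₂ unit. The breakpoint is
a point estimate; no significance is attached to it. Per-group consensus
is a strict majority on the class (ambiguous on ties) with the lower
median of per-sample breakpoints, which keeps the consensus an integer
exon index deterministically.

## Promoter evidence

Chromatin support is expressed as fold enrichment over the mean signal of
the whole displayed locus rather than through a peak caller: ratios to a
track's own locus mean are invariant to per-track scaling (sequencing
depth, normalization), which is the property needed to compare marks and
conditions without replicate-level modeling. Active evidence is the mean,
over the available active marks (H3K27ac required; H3K4me3 and Pol II used
when present), of the enrichment in a ±W window (default W = 2 kb)
anchored at the 5′ genomic end of exon *k*; the same score at the
canonical TSS must stay below threshold for the internal window to count
as specifically active. Repression is the H3K27me3 enrichment over the
genomic span of exons 1…k−1. Both thresholds default to 3-fold
(ρ_act = ρ_rep = 3); these are conventions, chosen to separate a flat
track (enrichment ≈ 1) from a planted ~5-fold signal, not published
cutoffs. Because the locus mean includes the enriched windows themselves,
the background is meaningful only when the track covers the locus with
generous flanks, as a genome-browser window would; the synthetic generator
writes 40 kb flanks on each side for this reason. A missing H3K27me3
track makes the repression test pass vacuously and is flagged in the
output rather than silently ignored.

## ORF scan

Candidate starts are restricted to ATG codons in frame with the canonical
stop and with no intervening in-frame stop, so every candidate protein
terminates at the canonical stop codon and is a C-terminal suffix of the
canonical protein (the suffix relation is verified explicitly when both
sequences are available). Near-cognate starts (CTG/GTG) are deliberately
excluded; they would inflate the candidate list without support from the
data types consumed here. Masses are average (not monoisotopic) masses
via pyteomics, the correct scale for comparison with SDS-PAGE band sizes;
kDa values are reported to one decimal and gel comparisons are read to the
nearest integer. Domain status against the N-terminal offset
δ = canonical length − candidate length: lost if the domain ends at or
before δ, retained if it starts after δ, truncated otherwise — a strict
partition.

## Peptide evidence

Digestion cleaves C-terminal to K/R except before P (no further
exceptions), with configurable missed cleavages and length bounds.
Mapping is exact string matching at every occurrence (optionally with
I = L, since the residues are isobaric); coverage is the union of matched
spans. Because the short protein is a suffix of the canonical one, only
N-terminal evidence discriminates the isoforms: a peptide containing any
residue at or before δ (including peptides straddling the offset) implies
the full-length protein, and the short isoform is supported only by the
joint absence of such peptides and the presence of at least m_min = 2
shared peptides. Quantification sums fragment-ion XIC areas per peptide
and sample, averages over the isoform-unique peptide set per sample
(peptides missing from a sample are excluded from that sample's mean and
flagged), and tests the two conditions with a Welch unpaired two-sided
t-test on log₂ sample averages — intensities are multiplicative, so the
log scale is the natural one. Groups with fewer than two samples, or
zero sample averages, skip the test with a warning but still report the
fold change.

## Synthetic data: what it emulates

The generator's defaults encode the emulated study design: E = 28 exons of
150 bp, breakpoint k = 23, a canonical ORF of 1347 aa (~151 kDa, the size
range of a full-length guidance receptor) and a planted in-frame ATG at
the start of exon 23 giving a 250 aa short ORF. Codon-random coding
sequence averages 111.9 Da per residue, so 250 residues weigh ~28 kDa —
the gel-band size the short product is expected to show. The
transmembrane domain is placed at the exon-17-equivalent protein position,
entirely inside the N-terminal region absent from the short ORF. Six
signature tryptic peptides are selected by deterministic subset-sum to a
combined footprint of 40% of the short protein, emulating a curated
signature-peptide panel with its reported coverage.

Counts are negative binomial with mean `depth` = 100 reads per expressed
exon, an on/off ratio of 50, and Var = μ(1+φ) with φ = 0.2 — i.e. the
dispersion is the fractional variance excess over Poisson (an 11%
replicate CV at depth 100); φ → 0 recovers the Poisson limit. Library
sizes are the locus counts plus a transcriptome background of 2×10⁸
mapped reads, a deep bulk library under which the off-level exons sit at
~0.07 RPKM — "absent" on the τ_off = 0.1 convention — while expressed
exons reach ~3 RPKM. Chromatin tracks are 50-bp bins of background
1 + N(0, 0.2) with a 5-fold active-mark gain in ±2 kb of the exon-k
boundary and a 5-fold H3K27me3 gain over the 5′ body. Peptide
intensities are lognormal (CV 20%) around per-peptide lognormal base
responses, with a 2-fold treatment effect and 90% per-sample detection
probability. One global seed fans out to fixed per-generator substreams,
so adding a generator never perturbs the draws of another.

What the generator does **not** emulate: positional read biases,
junction/split reads, multi-isoform mixtures, fragment-length effects,
replicate-level ChIP variability, retention-time or identification errors
in the peptide evidence. Passing the recovery tests therefore shows that
the estimators are correct and well calibrated under the assumed noise
families at realistic effect sizes — not that they are robust to every
artefact of real data.

## Calibration checks and problem sizes

The test suite and `scripts/acceptance.py` verify: exact equivalence of
the breakpoint caller and the ORF start finder with independently coded
brute-force oracles (1,000 random instances each); breakpoint k = 23 and
class recovery in ≥95% of 500 single-sample simulations at the default
effect size, with a ≤5% false short-call rate on full-length simulations;
the alternative-promoter verdict in ≥95% of 200 track simulations; and
the 2-fold peptide induction recovered within [1.6, 2.4] in ≥90% of 200
simulated tables. These sizes keep the whole suite under a minute on one
CPU while leaving Monte-Carlo error well below the margins being tested.

## Known limitations

* One breakpoint only; genes with multiple alternative starts need a
  segmentation method.
* Promoter thresholds are conventions; the classifier grades evidence, it
  does not call peaks, and replicate-aware ChIP statistics are out of
  scope.
* "Unique" peptides default to the supplied set; proteome-wide uniqueness
  is only enforced when a background proteome FASTA is provided.
* The RPKM stage assumes upstream alignment and (if desired)
  unique-mapping filters have been applied; it quantifies whatever reads
  it is given.
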