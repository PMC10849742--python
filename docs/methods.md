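# Methods

This note documents the models and conventions behind `nnmine`, the
defaults it pins, what the synthetic-data generators do and do not
emulate, and the numerical choices that had to be made where more than one
sensible convention exists.

## Pairwise alignment and e-value statistics

Global (Needleman–Wunsch) and local (Smith–Waterman) alignment use the
three-state affine-gap recursion (match state M, gap-in-subject Ix,
gap-in-query Iy) over an integer substitution matrix, default BLOSUM62
loaded from the NCBI text format via Biopython. A gap of length *L* costs
`gap_open + L·gap_extend` (the NCBI-BLAST parameterisation; defaults
11/1). Traceback ties are broken deterministically — diagonal over up
over left — so alignments are identical across platforms and runs.

Edge significance uses the Karlin–Altschul form

    E = K · m · n · exp(−λ·S)

with the standard gapped BLOSUM62/11,1 constants λ = 0.267 nats per score
unit and K = 0.041 as configuration defaults. This is a deliberate
approximation of BLAST-style statistics: no finite-size edge correction
and no composition adjustment are applied, which keeps the statistic a
closed form of (score, query length, subject length) and removes any
database dependency. Near-identical long proteins produce e-values far
below the double-precision underflow limit, so all threshold comparisons
happen on the log e-value; `evalue()` itself is floored at the smallest
positive double to stay strictly positive.

Percent identity ("aa ID") is method-dependent, so both conventions are
pinned and exposed: global mode divides identical columns by **all**
aligned columns, gap columns included (terminal gap columns are *not*
excluded); local mode divides by residue–residue columns of the local
alignment only. Reported identities always state the mode.

Correctness of both aligners is checked two independent ways: exact
agreement with an oracle that exhaustively enumerates every gapped
alignment (sequences up to length 6), and score agreement with
`Bio.Align.PairwiseAligner` configured with the same gap model on longer
sequences.

## Sequence similarity network

The SSN is built from exact all-vs-all local alignments — no k-mer
prefilter — which is adequate at desk scale (hundreds of sequences). An
optional length-ratio prefilter (skip pairs whose lengths differ by more
than 5×) exists but is off by default. Exact duplicate sequences are
collapsed first (first id kept, membership recorded); no identity-level
deduplication is attempted because a published criterion for it does not
exist in the workflow this mirrors.

Clusters are connected components at the chosen e-value threshold, the
reading conventionally applied to SSN visualizations; no community
detection. Component numbering is deterministic (decreasing size, then
lexicographically smallest member), so cluster indices are stable.
`threshold_sweep` computes the alignments once and reports (edges,
clusters, largest cluster) per threshold; edge count is monotone
nondecreasing in the threshold by construction.

The default edge threshold of `1e-110` is the stringency used in the
mining campaign this package generalises. The synthetic recovery study
(five families of twenty members, 300-residue references, background
mutation rate 0.2) produces within-family e-values around 1e-160…1e-84
and between-family e-values near 1e-5, so any threshold between those
bands reproduces the planted families exactly; the sweep locates one
automatically rather than assuming the default fits every data scale.

## Active-site fingerprints

A fingerprint definition is a reference protein plus 1-based positions
grouped by domain, each with a set of accepted residues (default: exactly
the reference residue; optional conservative widening, e.g. D↔E).
Queries are mapped by **pairwise global alignment to the reference**, not
a progressive MSA: pairwise mapping is deterministic, needs no external
aligner, and recovers site positions exactly under the substitution-only
variation the generators produce. A star-MSA (pairwise alignments stacked
on reference coordinates, query insertions dropped) is available for
conservation displays.

A site aligned to a gap counts as a mismatch — a missing ligand cannot
bind metal. A domain is *active* iff its matched-site fraction is ≥ the
cutoff (inclusive). Defaults: cupin 3/3 (the N–N-bond-forming triad must
be complete) and HDO 5/7 (partial loss of the diiron ligands tolerated).
No published numeric rule exists for the HDO call — the source analyses
describe it qualitatively — so the cutoffs are configuration values
reported in every output rather than constants hidden in code.

The shipped definition file format stores the reference FASTA path and
the site list as JSON. No default SznF positions are shipped: the
residue numbers must come from the primary literature on the reference
enzyme, and inventing them here would be worse than requiring them.

## Genomic neighborhoods

Distance is measured in genes (window default ±10), not base pairs; this
matches how conserved gene content is described ("*n* consecutive
genes") and makes results robust to intergenic-length variation. A bp
window is available as an alternative. Neighborhoods are reported
5′→3′ of the anchor's strand so reverse-strand anchors compare cleanly.
Gene homology is family-label equality; labels come from the input
annotation or from the SSN/fingerprint stages — no protein search happens
inside this module.

Co-occurrence counts are per anchor-family gene: an anchor with two
nearby partner genes counts once, so the count is not symmetric under
argument swap. The count is invariant to genome order and coordinate
translation.

BGC classes: each neighborhood becomes a binary family-presence vector
over a fixed universe (unknown families bucket to "other"); classes are
connected components of the ≥-cut Jaccard-similarity graph
(single-linkage, default cut 0.5). The simple rule is fully
deterministic; a dendrogram-cutting variant was deliberately not used.
Per class, the consensus family set holds families present in at least
half the members, and organisms are counted as distinct source genomes.

Conserved blocks: the longest run of consecutive genes in genome A whose
family labels occur, in order, as consecutive genes in genome B, testing
both orientations of every B contig (whole-run inversion allowed). Ties
break to the leftmost start in A, preferring forward orientation. The
implementation is the classic longest-common-substring dynamic program
per contig pair and is property-tested against an all-substrings oracle.

## Isotope enrichment

Percent enrichment is pinned as the labeled-fraction difference

    enrichment% = 100 · ( f_label(sample) − f_label(control) )

where `f_label` sums intensities at the label shifts over total intensity.
This is the simplest convention that is exactly 0 for an unlabeled sample
and 100 for a fully labeled one; the unlabeled control subtracts the
natural-abundance contribution. Values can go slightly negative under
noise and are clipped only in the report file, never in the arithmetic.
The default shift set for an *n*-heavy-atom substrate is all shifts ≥ *n*
(capturing the entire shifted envelope); partial-incorporation shifts
1…*n−1* can be included on request. Replicate summaries use the sample
SD (n−1).

Limitation: when the label shift is smaller than the natural-abundance
envelope width (e.g. a single ¹⁵N), the labeled and unlabeled envelopes
overlap and the difference definition biases low; full isotope-pattern
deconvolution would be required and is out of scope. The recovery study
therefore uses a shift of 10 (the ¹⁵N₄,¹³C₆ case), where the envelopes
separate cleanly.

## Synthetic data and what passing tests mean

Generators are pure functions of (specification, seed) and emit truth
records alongside the data; tests compare pipeline output to planted
truth, never to re-runs of the pipeline.

* **Protein families**: members differ from an i.i.d.-uniform reference
  by i.i.d. substitutions (uniform over the 19 alternatives) at a
  configurable rate (default 0.2), with designated sites either frozen or
  forced away from the reference. No indels, no rate heterogeneity, no
  matrix-biased substitution, no phylogenetic correlation — so these
  tests demonstrate correct *bookkeeping and thresholding*, not
  robustness to realistic evolutionary divergence (where alignment-based
  site mapping can genuinely err).
* **Genomes**: ordered gene tables with planted features and uniform
  filler families; no operon structure, no gene-length or GC realism.
  The planted studies mirror the *structure* of a real campaign's
  headline numbers on synthetic data — 107 co-localized gene pairs
  across 250 genomes, one 17-gene conserved block (inverted in the
  second genome), 4 neighborhood classes over 97 organisms — the point
  being exact recovery of planted truth, not reproduction of any real
  database result.
* **Spectra**: natural-abundance envelope (default a 4-peak, ~C30-like
  envelope) mixed with a label-shifted copy at fraction *f*, with
  per-peak multiplicative lognormal noise (default CV 5%, unit mean).

Problem sizes in the test battery and the acceptance script — 100
sequences for the SSN study, 200 homologs per conservation pattern, 250
genomes, 100 simulations per planted enrichment — were chosen as the
smallest scales at which the planted statistics are unambiguous while the
whole battery stays interactive on a laptop.

## Degenerate inputs and other conventions

Coordinates are 1-based inclusive everywhere (GFF3 convention), and the
TSV gene-table dialect declares this in its header comment. Sequences
accept the 20 amino acids plus X; a trailing `*` is stripped; anything
else is an input error naming the record. Empty local alignments (all
substitution scores negative) return score 0 with empty aligned strings.
Percent identity of a zero-column alignment, empty fingerprint clusters,
empty threshold lists, zero-total spectra and mismatched spectrum index
ranges are errors, not silent defaults. Classification at exactly the
cutoff is *active* (≥ is inclusive). Cluster, class and block orderings
are all deterministic; every generator takes an explicit seed.
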