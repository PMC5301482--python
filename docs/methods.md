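# Methods

## Overview

The pipeline detects per-strand RNA-editing sites from strand-specific
RNA-Seq over a small organellar reference, then layers four analyses on the
calls: symmetrical-editing pairing, SNP exclusion, codon-level annotation,
mismatch-budget calibration, and cross-species conservation. All stages are
exercised against a synthetic-data generator whose planted events serve as
exact ground truth; this note records the model, the parameter choices, and
what the synthetic results do and do not establish about real data.

## Coordinate and strand conventions

Every file and every in-memory coordinate is 1-based inclusive. Alignments
are ungapped; the SAM dialect is restricted to flags {0, 4, 16} with
all-match CIGAR, and gapped records are rejected rather than skipped, since
silent skipping would bias pileup depths. A read whose transcript
orientation maps to the reverse strand carries flag 16 and belongs to strand
group R; its sequence is stored genome-forward. Calls are reported in RNA
space: for group F the genome-space bases with T→U, for group R their
complements with T→U. Under this convention a genomic C→T column is "C to U"
in group F and "G to A" in group R — the latter is exactly the antisense
signature of a symmetrical editing event. Site names for CDS sites follow
the gene-offset convention (`gene3-544` = spliced-CDS base 544).

## Read mapping with a mismatch budget

Reads are placed by minimal Hamming distance over all offsets and both
orientations, accepted only when the minimum is unique and ≤ k. Ambiguous
best placements are dropped, never assigned randomly: random placement would
fabricate editing signal at paralogous loci. N matches nothing. Two engines
return identical results (tested property): a full scan, and the default
pigeonhole seed-and-verify index — any placement with ≤ k mismatches
contains one of k+1 exact read segments, so exact k-mer lookup enumerates a
complete candidate set which is then verified by direct Hamming count. The
index exists purely for speed on the calibration grid; when the segment
length would drop below 4 bases the implementation falls back to the full
scan. There is no quality-aware weighting: the method under study tunes a
single mismatch count, and keeping the budget a pure Hamming cap keeps the
calibration interpretable.

## The editing caller

Per (position, strand group) column with depth ≥ c_min (default 5), each
non-reference base is tested against three gates:

* frequency `alt/depth ≥ f_min` (default 0.1; compared with a 1e-9 epsilon
  so a frequency exactly at the cutoff passes despite binary-float
  representation),
* at least `min_alt` supporting reads (default 3),
* one-sided exact binomial tail `P(X ≥ alt | n = depth, p = error/3) ≤
  p_max` (defaults error 0.01, p_max 0.05), the uniform-miscall model: a
  sequencing error hits a specific wrong base with a third of the per-base
  error rate.

If two or more alternates pass at one column, the column is discarded
entirely (multi-type exclusion), applied per strand group: a clean call on
one strand survives a multi-type column on the other, because the strands
are called separately. Reads contributing N at a column contribute nothing.

The supporting-reads floor deserves a note. With only the coverage,
frequency and P gates, a *single* error read in any column of depth 5–10
passes everything (at depth 5, frequency 0.2 and tail probability ≈ 0.017),
and coverage ramps at transcript boundaries guarantee thousands of such
columns; the variant-reads floor of 3 — the convention of REDItools-style
editing callers — removes that artifact class while leaving every
bona-fide call (which at the default depths has far more than 3 supporting
reads) untouched. It is configurable (`min_alt`).

The frequency denominator is the full column depth (all bases), not
ref+alt only; this is a documented choice, not an inferred fact about any
particular external caller.

No multiple-testing correction is applied by default; the binomial tail is
used as a per-column filter exactly as the cutoffs are stated. The p-values
are checked against an exact rational-summation oracle to 1e-12 in the test
suite.

## Consensus caller (assembly-method stand-in)

At desk scale, strand-specific assembly followed by transcript-to-genome
comparison reduces to dominant-allele consensus: per strand-group column
with depth ≥ 5, the strict-majority base (> 50% of depth; exact ties yield
nothing) is compared with the reference. This reproduces the assembly
method's defining limitation — it sees only the dominant allele and misses
low-frequency editing — which is precisely what makes the two-method
comparison meaningful for calibration.

## SNP calling and exclusion

Genomic-DNA reads are strand-agnostic; the pooled pileup yields substitution
SNPs, flagged high-quality at coverage ≥ 10 and frequency ≥ 0.1. The
ungapped mapper cannot produce indel evidence, so indels enter only via the
minimal-VCF route. An editing site is excluded iff its position equals a
high-quality SNP position or lies inside an indel's reference span. In the
simulator, RNA reads carry planted SNP alleles at their allele frequency —
genomic polymorphism is transcribed — so SNP positions genuinely produce
editing-caller hits and the exclusion step is observable, not vacuous.

## Symmetrical editing

A pair is emitted when a position carries exactly one surviving call in each
strand group and (by default) the substitutions are RNA-space complements
(C→U/G→A and the other eleven mirror combinations; the strict rule admits
exactly 12 of the 144 type combinations, verified by enumeration). The loose
any-co-edited-position reading is available behind `require_mirror=False`
and reported separately, because the phenomenon's definition ("both strands
edited at one site") is weaker than its validated instances (all mirrors).
Counting is per genomic position. Absent sites in a given sample are
classified `no_coverage` (depth 0), `covered_but_failed`, or `passed`, with
the caller's own gates.

## Annotation

Region assignment uses containment with precedence CDS > intron > tRNA/rRNA
> intergenic; genes may not overlap at a site (error — precedence among
overlapping genes is undefined). Sense means the strand group matches the
gene's coding strand; intergenic sites are labelled forward/reverse by
strand group alone. Codon consequences apply to CDS sense sites: the spliced
CDS is translated under the standard genetic code (table 1, appropriate for
land-plant mitochondrial CDS; the table id is configurable) before and after
substituting the alternate base. Effects: silent, start_gain (codon 1
becomes AUG — the ACG→AUG case that creates a translation start), stop_gain,
stop_loss, else missense; codon_effect is verified against a whole-CDS
mutate-translate-diff oracle over all codons containing a C. The
hydrophobicity summary uses the set {A, V, L, I, P, F, M, W, G, C}, kept as
a module constant because "hydrophobic" has no single canonical definition;
stops are excluded from the respective denominators. Upstream windows span
−25..0 in transcript orientation (26 bases including the edited site;
a 25-base variant without the site is available), reverse-complemented for
reverse-group sites, dropped with a warning at genome ends.

## Mismatch-budget calibration

Method 1 (map → split → pileup → call) is re-run per k; method 2 is the
consensus caller applied once to the most-permissive-k mapping (re-mapping
per k applies to method 1 only, since the assembly stand-in is meant to be
mapping-independent). Sensitivity and specificity are exact set-intersection
ratios over (position, strand group, ref, alt) keys; empty sets make the
corresponding ratio undefined and the row degenerate rather than zero. "Best
combination" is operationalized as the maximal harmonic mean with ties
toward smaller k — the combining formula is a package choice; the full grid
table is always emitted so any other criterion can be applied.

## Conservation on consensus coordinates

Homolog groups are an input manifest (gene-name matching); orthology
inference is out of scope. Each group is aligned with a deterministic
center-star MSA: the center is the member with the maximal summed pairwise
Needleman–Wunsch score (match +1, mismatch −1, gap −2; ties to the first
listed), every other member is aligned to it globally (first optimal
alignment; member insertions placed flush left inside their gap block), and
rows are merged on the center's coordinates. Sites from different species
cluster when they share group, consensus column, RNA-space substitution and
orientation class; orientation is normalized to transcript orientation
before comparison, so species whose homolog sits on the opposite genomic
strand still compare correctly. SRE conservation clusters the pair's sense
substitution the same way. The paralog cross-check translates copy
coordinates through a pairwise global alignment and flags a copy site only
where the aligned bases are identical and an identical site exists on the
source; sites at gaps or diverged bases are logged and skipped.

## The synthetic-data generator

The generator emulates the study system, and its defaults are the reference
conditions used throughout the tests:

* **Genome**: 30 kb single contig (realistic small-mitogenome scale for a
  desk run), 8 protein-coding genes of 600–1500 bp placed on both strands,
  a quarter of them with one intron, plus tRNA/rRNA features; intergenic
  gaps ≥ 2 read lengths; features ≥ 1 read length from the origin, so the
  circular topology can be treated as linear for read placement — no read
  wraps, and no wrap-around mapping logic is needed.
* **Events**: 200 edited genomic positions, 80% of them C→U at sense-strand
  CDS positions biased 90/10 toward codon positions 1–2 (the empirical
  pattern for plant mitochondria); 40% of positions carry an exact mirrored
  pair. Editing frequencies are drawn from a mixture with half the mass
  uniform on 0.91–1.0 and half on 0.30–0.90 — the real per-site frequency
  distribution per tissue is unknown, so this is a modeling choice that
  matches the qualitative shape (mode in the top bin) rather than an
  inferred fact. 10 substitution SNPs (allele frequency 0.5 or 1.0) and 2
  codon-scale deletions are planted inside gene spans.
* **Reads**: single-end, 100 bp, FR protocol, uniform per-base substitution
  error 0.005. 90% of reads come from gene spans (pre-mRNA, unspliced —
  introns get coverage), 10% uniform background on both strands. Half the
  transcript reads are drawn antisense (`antisense_fraction = 0.5`):
  pervasive antisense transcription is the phenomenon that makes
  symmetrical editing observable at all, and without it the reverse-group
  members of SRE pairs would have no coverage. Single-end suffices because
  the strand logic needs only the orientation bit.
* **Scale**: calibration fixtures use a 12 kb genome at 30× with ten seeds,
  and conservation fixtures use 4–5 homolog groups of ~160 codons across
  three species at 2% divergence with occasional whole-codon indels; these
  sizes keep the full suite and the acceptance script fast while leaving
  every measured property far from its decision boundary.

Conserved-edit planting is restricted to positions whose ±9 bp context is
colinear (no indel) in every species: a position adjacent to an indel has no
unique homolog — optimal gap placement is not unique there — so "planted at
homologous positions" is only well defined in locally colinear context.

What the generator does **not** model: base-quality error profiles, indel
sequencing errors, PCR duplicates, splicing isoforms, circular-origin
coverage, NUMT-style cross-mapping from a nuclear background, and
tissue-specific editing differences (samples differ only by seed). Passing
tests therefore demonstrate the correctness of the pipeline's logic under
its stated error model, not calling accuracy on real libraries with
structured errors.

## Numerical choices and degenerate inputs

Frequency and SNP-frequency cutoffs use a 1e-9 epsilon so exact boundary
values pass. Binomial tails come from `scipy.stats.binom.sf` and are
oracle-checked to 1e-12 up to depth 500. Consensus ties (exactly 50/50)
yield no site. Reference-N columns are skipped with a warning. Empty
method-1/method-2 sets make sensitivity/specificity undefined (degenerate
calibration rows; selecting k over only degenerate rows is an error).
Duplicate calls at one (position, strand group) are an error in SRE pairing
(impossible after multi-type exclusion). Mapping ties are unmapped. All
randomness flows through numpy Generators seeded explicitly; identical
configs produce byte-identical outputs (tested).

## Known limitations

* The ungapped mapper cannot discover indel variation; indel exclusion
  depends on externally supplied variant tables.
* The binomial error model is uniform across bases and positions; real
  miscalls are context- and quality-dependent.
* Center-star MSA is not codon-aware; a codon-aware mode would improve
  column homology for diverged groups.
* The consensus caller stands in for a full assembler; it shares the
  assembly method's blindness to minor alleles by construction, which is
  the point, but it also cannot model assembly artifacts (chimeras,
  fragmented transcripts).
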