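# mito-sre

Strand-specific discovery of RNA-editing sites — including **symmetrical RNA
editing (SRE)** — in plant mitochondrial genomes, as a desk-scale, fully
testable pipeline driven by a synthetic-data generator with exact ground
truth.

## The problem

Plant mitochondrial mRNAs are heavily edited, predominantly cytidine→uridine
("C to U"). With *strand-specific* RNA-Seq the two strands' transcripts can
be analyzed separately: reads are partitioned by the SAM orientation bit
(flag 16) into forward (F) and reverse (R) strand groups, and editing sites
are called per `(position, strand group)` column of the pileup. Reporting is
in **RNA space**: reverse-group mismatches are complemented and T is written
U, so a genomic C→T column seen in the reverse group is the antisense
"G to A" event. A position where *both* strand groups are edited with
complementary substitutions — sense C→U together with antisense G→A — is a
symmetrical RNA-editing (SRE) pair.

Three method-level questions make this more than a pileup exercise, and each
is a module here:

* **Mismatch budget (k).** Editing sites cluster densely (several edits
  within one read length), so a small Hamming budget unmaps exactly the
  edited reads and silently underestimates editing. `calibrate` grids the
  mapper over k and scores each run against a consensus-based caller
  (the assembly-method stand-in) with
  `sensitivity = |M1∩M2|/|M2|`, `specificity = |M1∩M2|/|M1|`.
* **Genomic polymorphism.** A DNA SNP looks like editing in RNA. `calling`
  calls SNPs from genomic reads (coverage ≥ 10, frequency ≥ 0.1) and excludes
  editing sites at SNP positions or inside indel spans.
* **Conservation.** Sites from several species are compared on *consensus
  coordinates*: homologous CDS are aligned (deterministic center-star MSA)
  and sites cluster when they share the consensus column, the editing type
  and the orientation class. The same machinery cross-checks paralogous
  copies (e.g. nuclear copies of mitochondrial DNA).

The editing caller uses the cutoffs coverage ≥ 5, frequency ≥ 0.1, ≥ 3
variant-supporting reads, and a one-sided exact binomial tail
`P(X ≥ alt | n = depth, p = error/3) ≤ 0.05`; columns where two alternate
bases pass are discarded (multi-type exclusion).

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data; every number below is computed at run time and scored against the
planted ground truth.

```
$ python analysis/01_simulate.py
leaf: 15000 strand-specific reads
...
planted: 200 edited positions (80 symmetrical pairs, 280 strand-level events), 10 SNPs, 2 indels

$ python analysis/03_call_editing_sites.py
leaf: 14995 mapped (7569 F / 7426 R), 5 unmapped
...
pooled: 300 raw sites, 20 excluded at SNP/indel positions, 280 kept
strand split: 117 forward-group / 163 reverse-group sites
vs ground truth: recall 1.000, precision 1.000

$ python analysis/04_sre_and_annotation.py
symmetrical editing: 80 strict mirror pairs (80 under the loose co-edited rule); recall vs planted 1.000
164 C→U CDS sense sites; codon positions 1/2/3: 49.4% / 43.3% / 7.3%
hydrophobic fraction of affected residues: 49.4% before editing -> 69.0% after
codon effects of C→U CDS edits: {'missense': 132, 'silent': 26, 'stop_gain': 6}
```

Reading this: all 280 planted strand-level events (200 positions, 80 of them
mirrored SRE pairs) were recovered with no false calls after SNP exclusion;
C→U edits concentrate at codon positions 1 and 2 and shift the affected
residues toward hydrophobic amino acids, the classic signature of plant
mitochondrial editing. `analysis/02_calibrate_mismatch_budget.py` shows the
mismatch-budget effect: with 5-edit clusters planted inside one read length,
sensitivity at k = 2 is ~0.71–0.93 and reaches 1.0 by k = 5, with the
harmonic-mean pick landing at k = 3–5 across ten seeds.
`analysis/05_cross_species_conservation.py` recovers all 40 planted
conserved sites across three simulated species and flags exactly the
identical-copy sites in the paralog cross-check.

The same stages are available as a CLI:

```
mito-sre simulate --out data/
mito-sre map --ref data/genome.fasta --reads data/reads.fastq --max-mismatch 7 --out aln.sam
mito-sre call-editing --ref data/genome.fasta --sam aln.sam --out sites.tsv
mito-sre sre --forward sites_F.tsv --reverse sites_R.tsv --out sre.tsv
```

## Layout

```
src/mito_sre/        io_formats, simulate, mapping, calling, sre,
                     annotate, calibrate, conserve, pipeline, cli
analysis/            numbered drivers (simulate → calibrate → call →
                     SRE/annotate → conserve), writing results/
tests/               unit, property and end-to-end acceptance tests
docs/methods.md      model, assumptions, parameter choices, limitations
```
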