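"""Map, call and SNP-filter editing sites on the synthetic dataset.

Per-tissue and pooled calling at mismatch budget k = 7 with the caller
cutoffs (coverage >= 5, frequency >= 0.1, >= 3 supporting reads, binomial
P <= 0.05), strand-separated via the orientation bit; DNA SNPs called from
the genomic reads (coverage >= 10, frequency >= 0.1) plus the planted indels
are excluded from the editing-site set.  Writes per-strand site tables, the
per-tissue Venn partition, the absence classification, and a ground-truth
scorecard.
"""

import json
from pathlib import Path

import pandas as pd

from mito_sre import calling, io_formats, mapping, pipeline, simulate, sre

DATA = Path("results/dataset")
OUT = Path("results")
K = 7
SAMPLES = ["leaf", "flower", "root"]


def main():
    genome = mapping.Genome(*io_formats.read_fasta(DATA / "genome.fasta")[0])
    truth = simulate.GroundTruth.from_json(DATA / "truth.json")

    per_sample_aln = {}
    per_sample_pile = {}
    per_sample_sites = {}
    for name in SAMPLES:
        reads = io_formats.read_fastq(DATA / f"{name}.fastq")
        alns, unmapped = mapping.map_reads(reads, genome, K, sample=name)
        fwd, rev = mapping.split_by_strand(alns)
        print(f"{name}: {len(alns)} mapped ({len(fwd)} F / {len(rev)} R), "
              f"{unmapped} unmapped")
        per_sample_aln[name] = alns
        pile = calling.build_pileup(alns, genome)
        per_sample_pile[name] = pile
        per_sample_sites[name] = calling.call_editing_sites(pile, genome, sample=name)
        print(f"{name}: {len(per_sample_sites[name])} sites")

    pooled = calling.pool_samples(per_sample_aln)
    pooled_pile = calling.build_pileup(pooled, genome)
    raw = calling.call_editing_sites(pooled_pile, genome, sample="pooled")

    dna_reads = io_formats.read_fastq(DATA / "dna.fastq")
    dna_aln, _ = mapping.map_reads(dna_reads, genome, 3)
    snps = calling.call_snps(calling.build_pileup(dna_aln, genome).pooled(), genome)
    indels = [
        calling.SnpSite(s.position, s.ref, s.alt, None, s.allele_frequency,
                        is_indel=True)
        for s in truth.snps if s.is_indel
    ]
    kept, excluded = calling.exclude_snp_overlaps(raw, snps + indels)
    print(f"pooled: {len(raw)} raw sites, {len(excluded)} excluded at "
          f"SNP/indel positions, {len(kept)} kept")

    fwd = [s for s in kept if s.strand_group == "F"]
    rev = [s for s in kept if s.strand_group == "R"]
    io_formats.write_site_table(fwd, OUT / "sites_F.tsv")
    io_formats.write_site_table(rev, OUT / "sites_R.tsv")
    io_formats.write_site_table(excluded, OUT / "sites_excluded.tsv")
    print(f"strand split: {len(fwd)} forward-group / {len(rev)} reverse-group sites")

    venn = sre.venn_partition(
        {n: {s.key for s in ss} for n, ss in per_sample_sites.items()}
    )
    pd.DataFrame(
        [{"samples": "&".join(sorted(k)), "count": v} for k, v in sorted(venn.items())]
    ).to_csv(OUT / "venn.tsv", sep="\t", index=False)

    absence = []
    for s in kept:
        for name in SAMPLES:
            cls = sre.classify_absence(s.position, s.strand_group,
                                       per_sample_pile[name], genome)
            absence.append({"position": s.position, "strand_group": s.strand_group,
                            "sample": name, "class": cls})
    adf = pd.DataFrame(absence)
    adf.to_csv(OUT / "absence.tsv", sep="\t", index=False)
    print("absence classes across tissues:",
          adf["class"].value_counts().to_dict())

    scores = pipeline.score_against_truth(kept, truth)
    with open(OUT / "calling_scorecard.json", "w") as fh:
        json.dump(scores, fh, indent=1)
    print(f"vs ground truth: recall {scores['recall']:.3f}, "
          f"precision {scores['precision']:.3f}")


if __name__ == "__main__":
    main()
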