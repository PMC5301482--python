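"""Generate the synthetic study dataset.

Builds a 30 kb mitogenome-like reference with 8 protein-coding genes on both
strands (plus tRNA/rRNA features), plants 200 edited positions (40% of them
symmetrical pairs, frequencies >= 0.3 with the mode above 0.9), 10 genomic
SNPs and 2 indels, and draws strand-specific RNA reads for three "tissue"
samples at 50x plus one genomic-DNA read set at 40x.  Everything lands in
results/dataset/ together with the ground truth.
"""

import json
from pathlib import Path

from mito_sre import io_formats, simulate

OUT = Path("results/dataset")
SEED = 20260901

CONFIG = dict(
    genome_length=30000, n_genes=8, n_edits=200, sre_fraction=0.4,
    n_snps=10, n_indels=2, depth=50.0, read_length=100, seq_error_rate=0.005,
    n_samples=3, seed=SEED,
)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    genome, models = simulate.generate_genome(
        CONFIG["genome_length"], CONFIG["n_genes"], seed=SEED,
        read_length=CONFIG["read_length"],
    )
    truth = simulate.plant_events(
        genome, models, n_edits=CONFIG["n_edits"], sre_fraction=CONFIG["sre_fraction"],
        n_snps=CONFIG["n_snps"], n_indels=CONFIG["n_indels"], seed=SEED + 1,
    )
    io_formats.write_fasta([("mito", genome)], OUT / "genome.fasta")
    io_formats.write_gff(models, OUT / "genes.gff3", {"mito": len(genome)})
    truth.to_json(OUT / "truth.json")

    for i, name in enumerate(["leaf", "flower", "root"][: CONFIG["n_samples"]]):
        reads, truth_sam = simulate.simulate_reads(
            genome, models, truth, depth=CONFIG["depth"],
            read_length=CONFIG["read_length"], error_rate=CONFIG["seq_error_rate"],
            seed=SEED + 10 + i,
        )
        io_formats.write_fastq(reads, OUT / f"{name}.fastq")
        io_formats.write_sam(truth_sam, OUT / f"{name}.truth.sam", {"mito": len(genome)})
        print(f"{name}: {len(reads)} strand-specific reads")

    dna_reads, _ = simulate.simulate_dna_reads(
        genome, truth, depth=40.0, read_length=CONFIG["read_length"], seed=SEED + 99
    )
    io_formats.write_fastq(dna_reads, OUT / "dna.fastq")
    print(f"genomic DNA: {len(dna_reads)} reads")

    with open(OUT / "params.json", "w") as fh:
        json.dump(CONFIG, fh, indent=1)
    n_sre = len(truth.sre_positions)
    print(
        f"planted: {CONFIG['n_edits']} edited positions ({n_sre} symmetrical pairs, "
        f"{len(truth.edits)} strand-level events), {CONFIG['n_snps']} SNPs, "
        f"{CONFIG['n_indels']} indels"
    )


if __name__ == "__main__":
    main()
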