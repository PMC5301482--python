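"""End-to-end orchestration: simulate → map → call → exclude → SRE → annotate.

Everything is reproducible from a ``RunConfig`` and its seed; each run writes
its config next to its outputs.  Reports are TSV tables carrying the same
numbers the study presents as figures (substitution-type spectrum, frequency
histogram, region distribution, per-sample Venn regions, absence classes),
plus a ground-truth scorecard on synthetic data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate as annotate_mod
from . import calibrate as calibrate_mod
from . import calling, mapping, simulate, sre
from .io_formats import write_fasta, write_fastq, write_gff, write_sam, write_site_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # synthetic genome / events
    genome_length: int = 30000
    n_genes: int = 8
    n_edits: int = 200
    sre_fraction: float = 0.4
    n_snps: int = 10
    n_indels: int = 2
    cluster: tuple[int, int] | None = None  # (k edits, window bp)
    # sequencing
    n_samples: int = 1
    depth: float = 50.0
    read_length: int = 100
    seq_error_rate: float = 0.005
    transcript_fraction: float = 0.9
    antisense_fraction: float = 0.5
    # mapping / calling
    k: int = 7
    c_min: int = 5
    f_min: float = 0.1
    p_max: float = 0.05
    min_alt: int = 3
    caller_error_rate: float = 0.01
    snp_c_min: int = 10
    snp_f_min: float = 0.1
    # annotation
    window_span: int = 25
    # calibration
    run_calibration: bool = False
    k_values: tuple = tuple(range(2, 11))
    seed: int = 1

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)

    def validate(self) -> None:
        if self.genome_length < 5000:
            raise ValueError("genome_length must be >= 5000")
        if not 0 <= self.sre_fraction <= 1:
            raise ValueError("sre_fraction must be in [0, 1]")
        if self.k < 0 or self.c_min < 1:
            raise ValueError("invalid mapping/calling thresholds")


@dataclass
class RunResult:
    config: RunConfig
    genome: mapping.Genome
    models: list
    truth: simulate.GroundTruth
    per_sample_sites: dict[str, list]
    kept_sites: list
    excluded_sites: list
    snps: list
    sre_pairs: list
    annotated: list
    calibration: list | None = None
    evaluation: dict = field(default_factory=dict)


def score_against_truth(sites, truth: simulate.GroundTruth) -> dict:
    """Site-level recall/precision of calls vs the planted ground truth."""
    pred = {s.key for s in sites}
    true = truth.edit_keys()
    tp = len(pred & true)
    return {
        "n_true": len(true),
        "n_called": len(pred),
        "n_true_positive": tp,
        "recall": tp / len(true) if true else float("nan"),
        "precision": tp / len(pred) if pred else float("nan"),
    }


def score_sre(pairs, truth: simulate.GroundTruth) -> dict:
    pred = {p.position for p in pairs}
    true = truth.sre_positions
    tp = len(pred & true)
    return {
        "n_true_sre": len(true),
        "n_paired": len(pred),
        "sre_recall": tp / len(true) if true else float("nan"),
        "sre_precision": tp / len(pred) if pred else float("nan"),
    }


def run_pipeline(config: RunConfig, outdir=None) -> RunResult:
    """Simulate, map, call, exclude, pair, annotate; optionally calibrate."""
    config.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_json(out / "config.json")

    logger.info("stage simulate: genome %d bp, %d genes", config.genome_length, config.n_genes)
    genome_seq, models = simulate.generate_genome(
        config.genome_length,
        config.n_genes,
        both_strands=True,
        seed=config.seed,
        read_length=config.read_length,
    )
    genome = mapping.Genome("mito", genome_seq)
    truth = simulate.plant_events(
        genome_seq,
        models,
        n_edits=config.n_edits,
        sre_fraction=config.sre_fraction,
        cluster_spec=config.cluster,
        n_snps=config.n_snps,
        n_indels=config.n_indels,
        seed=config.seed + 1,
    )
    if out is not None:
        write_fasta([("mito", genome_seq)], out / "genome.fasta")
        write_gff(models, out / "genes.gff3", {"mito": len(genome_seq)})
        truth.to_json(out / "truth.json")

    sample_names = [f"sample{i+1}" for i in range(config.n_samples)]
    per_sample_aln: dict[str, list] = {}
    per_sample_reads = {}
    for i, name in enumerate(sample_names):
        reads, truth_sam = simulate.simulate_reads(
            genome_seq,
            models,
            truth,
            depth=config.depth,
            read_length=config.read_length,
            error_rate=config.seq_error_rate,
            seed=config.seed + 10 + i,
            transcript_fraction=config.transcript_fraction,
            antisense_fraction=config.antisense_fraction,
        )
        per_sample_reads[name] = reads
        alns, n_unmapped = mapping.map_reads(reads, genome, config.k, sample=name)
        fwd, rev = mapping.split_by_strand(alns)
        logger.info(
            "stage map [%s]: %d reads, %d mapped (%d F / %d R), %d unmapped",
            name, len(reads), len(alns), len(fwd), len(rev), n_unmapped,
        )
        per_sample_aln[name] = alns
        if out is not None:
            write_fastq(reads, out / f"{name}.fastq")
            write_sam(truth_sam, out / f"{name}.truth.sam", {"mito": len(genome_seq)})

    pooled = calling.pool_samples(per_sample_aln)
    pile = calling.build_pileup(pooled, genome)
    caller_kw = dict(
        c_min=config.c_min,
        f_min=config.f_min,
        p_max=config.p_max,
        error_rate=config.caller_error_rate,
        min_alt=config.min_alt,
    )
    raw_sites = calling.call_editing_sites(pile, genome, sample="pooled", **caller_kw)
    logger.info("stage call: %d sites from pooled pileup", len(raw_sites))

    per_sample_sites = {}
    per_sample_piles = {}
    for name in sample_names:
        p = calling.build_pileup(per_sample_aln[name], genome)
        per_sample_piles[name] = p
        per_sample_sites[name] = calling.call_editing_sites(p, genome, sample=name, **caller_kw)

    # DNA SNP calling and exclusion
    dna_reads, _ = simulate.simulate_dna_reads(
        genome_seq, truth, depth=40.0, read_length=config.read_length,
        seed=config.seed + 99,
    )
    dna_aln, _ = mapping.map_reads(dna_reads, genome, 3)
    dna_pile = calling.build_pileup(dna_aln, genome).pooled()
    snps = calling.call_snps(dna_pile, genome, c_min=config.snp_c_min, f_min=config.snp_f_min)
    indel_snps = [
        calling.SnpSite(
            position=s.position, ref=s.ref, alt=s.alt, depth=None,
            allele_frequency=s.allele_frequency, is_indel=True, high_quality=True,
        )
        for s in truth.snps
        if s.is_indel
    ]
    kept, excluded = calling.exclude_snp_overlaps(raw_sites, snps + indel_snps)
    logger.info(
        "stage exclude: %d raw -> %d kept, %d excluded at SNP/indel positions",
        len(raw_sites), len(kept), len(excluded),
    )

    fwd_sites = [s for s in kept if s.strand_group == "F"]
    rev_sites = [s for s in kept if s.strand_group == "R"]
    pairs = sre.pair_sre(fwd_sites, rev_sites, require_mirror=True)
    logger.info("stage sre: %d mirrored pairs", len(pairs))

    annotated = annotate_mod.annotate_sites(kept, genome, models)

    calibration = None
    if config.run_calibration:
        calibration = calibrate_mod.run_grid(
            per_sample_reads[sample_names[0]], genome,
            k_values=config.k_values, caller_params=caller_kw,
        )

    evaluation = {}
    evaluation.update(score_against_truth(kept, truth))
    evaluation.update(score_sre(pairs, truth))

    result = RunResult(
        config=config,
        genome=genome,
        models=models,
        truth=truth,
        per_sample_sites=per_sample_sites,
        kept_sites=kept,
        excluded_sites=excluded,
        snps=snps + indel_snps,
        sre_pairs=pairs,
        annotated=annotated,
        calibration=calibration,
        evaluation=evaluation,
    )

    if out is not None:
        write_site_table(fwd_sites, out / "sites_F.tsv")
        write_site_table(rev_sites, out / "sites_R.tsv")
        write_site_table(excluded, out / "sites_excluded.tsv")
        sre_table(pairs).to_csv(out / "sre.tsv", sep="\t", index=False)
        annotated_table(annotated).to_csv(out / "annotated.tsv", sep="\t", index=False)
        for name, df in summarize(kept, annotated).items():
            df.to_csv(out / f"summary_{name}.tsv", sep="\t")
        if config.n_samples > 1:
            venn = sre.venn_partition(
                {n: {s.key for s in sites} for n, sites in per_sample_sites.items()}
            )
            pd.DataFrame(
                [{"samples": "&".join(sorted(k)), "count": v} for k, v in venn.items()]
            ).to_csv(out / "venn.tsv", sep="\t", index=False)
            absence_rows = []
            for s in kept:
                for name in sample_names:
                    cls = sre.classify_absence(
                        s.position, s.strand_group, per_sample_piles[name], genome,
                        c_min=config.c_min, f_min=config.f_min,
                        p_max=config.p_max, error_rate=config.caller_error_rate,
                        min_alt=config.min_alt,
                    )
                    absence_rows.append(
                        {"position": s.position, "strand_group": s.strand_group,
                         "sample": name, "class": cls}
                    )
            pd.DataFrame(absence_rows).to_csv(out / "absence.tsv", sep="\t", index=False)
        if calibration is not None:
            calibrate_mod.grid_table(calibration).to_csv(
                out / "calibration.tsv", sep="\t", index=False
            )
        windows = annotate_mod.extract_upstream_windows(
            [a for a in annotated if a.effect not in ("noncoding",)],
            genome, span=config.window_span,
        )
        write_fasta(windows, out / "windows.fasta") if windows else None
        with open(out / "evaluation.json", "w") as fh:
            json.dump(evaluation, fh, indent=1)
    return result


def sre_table(pairs) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "position": p.position,
                "F_substitution": p.forward_site.substitution,
                "F_frequency": p.forward_site.frequency,
                "R_substitution": p.reverse_site.substitution,
                "R_frequency": p.reverse_site.frequency,
            }
            for p in pairs
        ],
        columns=["position", "F_substitution", "F_frequency", "R_substitution", "R_frequency"],
    )


def annotated_table(annotated) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_name": a.site_name,
                "position": a.site.position,
                "strand_group": a.site.strand_group,
                "substitution": a.site.substitution,
                "frequency": a.site.frequency,
                "region": a.region,
                "gene_id": a.gene_id or "",
                "orientation": a.orientation or "",
                "cds_offset": a.cds_offset or "",
                "codon_index": a.codon_index or "",
                "codon_position": a.codon_position or "",
                "ref_codon": a.ref_codon or "",
                "alt_codon": a.alt_codon or "",
                "ref_aa": a.ref_aa or "",
                "alt_aa": a.alt_aa or "",
                "effect": a.effect,
            }
            for a in annotated
        ]
    )


def summarize(sites, annotated) -> dict[str, pd.DataFrame]:
    """Figure-style tables: type spectrum, frequency bins, region distribution."""
    type_counts, freq_hist = annotate_mod.type_frequency_summary(sites)
    type_pct = 100.0 * type_counts / max(len(sites), 1)
    regions = pd.Series([a.region for a in annotated]).value_counts().to_frame("count")
    regions["percent"] = 100.0 * regions["count"] / max(len(annotated), 1)
    effects = (
        pd.Series([a.effect for a in annotated]).value_counts().to_frame("count")
    )
    return {
        "type_counts": type_counts,
        "type_percent": type_pct,
        "frequency_bins": freq_hist.to_frame("count"),
        "regions": regions,
        "effects": effects,
    }
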