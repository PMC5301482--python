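"""Synthetic mitogenome, planted editing/SNP events, and strand-specific reads.

The generator emulates the study system: a small circular plant-type
mitogenome (treated as linear — features are kept away from the origin so no
read wraps), protein-coding genes on both strands, C→U editing concentrated
at codon positions 1 and 2 of sense-strand CDS, a configurable fraction of
symmetrical-editing positions (mirrored C→U / G→A events on the two strands'
transcripts), genomic SNPs that leak into the RNA reads at their allele
frequency, dense editing clusters that stress the mapper's mismatch budget,
and an FR strand-specific protocol with uniform per-base substitution error.

Everything is deterministic under the seed and the planted events are written
out as a ground truth so each downstream stage can be scored exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from Bio.Seq import Seq

from .io_formats import GeneModel, SamRecord

DNA = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def rna_complement(base: str) -> str:
    """Complement in the RNA alphabet (A<->U, C<->G)."""
    return {"A": "U", "U": "A", "C": "G", "G": "C"}[base]


def genome_to_rna(base: str, strand_group: str) -> str:
    """Genome-space (forward) base -> RNA-space base for a strand group."""
    if strand_group == "R":
        base = base.translate(_COMP)
    return base.replace("T", "U")


def rna_to_genome(base: str, strand_group: str) -> str:
    """RNA-space base for a strand group -> genome-space (forward) base."""
    base = base.replace("U", "T")
    if strand_group == "R":
        base = base.translate(_COMP)
    return base


# ---------------------------------------------------------------------------
# Ground truth containers


@dataclass(frozen=True)
class PlantedEdit:
    position: int  # 1-based genomic
    strand_group: str  # F or R (transcript orientation of the edited strand)
    rna_ref: str  # RNA space (U not T)
    rna_alt: str
    editing_frequency: float
    is_sre: bool = False

    @property
    def key(self) -> tuple:
        return (self.position, self.strand_group, self.rna_ref, self.rna_alt)


@dataclass(frozen=True)
class PlantedSnp:
    position: int
    ref: str  # genome space, may be multi-base for indels
    alt: str
    allele_frequency: float
    is_indel: bool = False


@dataclass
class GroundTruth:
    edits: list[PlantedEdit]
    snps: list[PlantedSnp]
    params: dict = field(default_factory=dict)

    @property
    def sre_positions(self) -> set[int]:
        return {e.position for e in self.edits if e.is_sre}

    def edit_keys(self) -> set[tuple]:
        return {e.key for e in self.edits}

    def to_json(self, path) -> None:
        payload = {
            "edits": [asdict(e) for e in self.edits],
            "snps": [asdict(s) for s in self.snps],
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            edits=[PlantedEdit(**e) for e in payload["edits"]],
            snps=[PlantedSnp(**s) for s in payload["snps"]],
            params=payload["params"],
        )


# ---------------------------------------------------------------------------
# Genome generation


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + one stop codon."""
    body = []
    for _ in range(n_codons - 2):
        while True:
            codon = "".join(DNA[i] for i in rng.integers(0, 4, size=3))
            if codon not in STOP_CODONS:
                break
        body.append(codon)
    stop = STOP_CODONS[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def generate_genome(
    length: int,
    n_genes: int,
    both_strands: bool = True,
    seed: int = 0,
    read_length: int = 100,
    gene_length_range: tuple[int, int] = (600, 1500),
    intron_prob: float = 0.25,
    intron_length_range: tuple[int, int] = (60, 150),
    n_trna: int = 2,
    n_rrna: int = 1,
    contig_name: str = "mito",
) -> tuple[str, list[GeneModel]]:
    """Build a random mitogenome-like contig plus its gene models.

    Genes are non-overlapping, separated by at least ``2 * read_length`` of
    intergenic sequence and kept at least ``read_length`` from the circular
    origin; roughly half go on the minus strand when ``both_strands``.
    Protein-coding genes may carry one intron inserted at a codon boundary.
    """
    if length < 5000:
        raise ValueError("genome length must be >= 5000")
    rng = np.random.default_rng(seed)

    specs = []  # (kind, transcript_parts) where parts mark cds/intron lengths
    for i in range(n_genes):
        lo, hi = gene_length_range
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        cds = _random_cds(rng, n_codons)
        intron_len = 0
        if rng.random() < intron_prob and n_codons > 20:
            ilen = int(rng.integers(*intron_length_range))
            intron_len = ilen
        specs.append(("protein_coding", cds, intron_len))
    for _ in range(n_trna):
        specs.append(("tRNA", "".join(DNA[i] for i in rng.integers(0, 4, size=75)), 0))
    for _ in range(n_rrna):
        specs.append(("rRNA", "".join(DNA[i] for i in rng.integers(0, 4, size=160)), 0))

    spans = [len(s[1]) + s[2] for s in specs]
    margin = read_length
    gap_min = 2 * read_length
    needed = 2 * margin + sum(spans) + gap_min * (len(specs) - 1)
    if needed > length:
        raise ValueError(
            f"cannot fit {len(specs)} features ({needed} bp needed) in {length} bp"
        )

    # distribute the slack randomly over the gaps
    slack = length - needed
    cuts = np.sort(rng.integers(0, slack + 1, size=len(specs)))
    extra = np.diff(np.concatenate([[0], cuts]))

    background = rng.integers(0, 4, size=length)
    genome = [DNA[i] for i in background]
    models: list[GeneModel] = []
    cursor = margin  # 0-based insertion point
    order = rng.permutation(len(specs))
    for slot, idx in enumerate(order):
        kind, transcript, intron_len = specs[idx]
        cursor += int(extra[slot])
        start0 = cursor
        if kind == "protein_coding":
            if intron_len:
                n_codons = len(transcript) // 3
                cut_codon = int(rng.integers(4, n_codons - 4))
                intron = "".join(DNA[i] for i in rng.integers(0, 4, size=intron_len))
                # avoid GT..AG mimicry concerns: content irrelevant to pipeline
                pre = transcript[: 3 * cut_codon] + intron + transcript[3 * cut_codon :]
            else:
                pre = transcript
            strand = "-" if (both_strands and rng.random() < 0.5) else "+"
            region = pre if strand == "+" else revcomp(pre)
            end0 = start0 + len(region)
            genome[start0:end0] = list(region)
            gstart, gend = start0 + 1, end0  # 1-based inclusive
            if intron_len:
                # transcript coords of the intron within the pre-mRNA
                t_i0, t_i1 = 3 * cut_codon, 3 * cut_codon + intron_len  # 0-based half-open
                if strand == "+":
                    cds_segs = [(gstart, gstart + t_i0 - 1), (gstart + t_i1, gend)]
                    intr = [(gstart + t_i0, gstart + t_i1 - 1)]
                else:
                    cds_segs = [(gend - t_i0 + 1, gend), (gstart, gend - t_i1)]
                    intr = [(gend - t_i1 + 1, gend - t_i0)]
            else:
                cds_segs = [(gstart, gend)]
                intr = []
            models.append(
                GeneModel(
                    gene_id=f"gene{len([m for m in models if m.kind == 'protein_coding']) + 1}",
                    contig=contig_name,
                    strand=strand,
                    start=gstart,
                    end=gend,
                    cds=sorted(cds_segs, reverse=(strand == "-")),
                    introns=intr,
                )
            )
        else:
            strand = "-" if (both_strands and rng.random() < 0.5) else "+"
            region = transcript if strand == "+" else revcomp(transcript)
            end0 = start0 + len(region)
            genome[start0:end0] = list(region)
            tag = "trn" if kind == "tRNA" else "rrn"
            n_prior = len([m for m in models if m.kind == kind])
            models.append(
                GeneModel(
                    gene_id=f"{tag}{n_prior + 1}",
                    contig=contig_name,
                    strand=strand,
                    start=start0 + 1,
                    end=end0,
                    kind=kind,
                )
            )
        cursor = end0 + gap_min

    seq = "".join(genome)
    assert len(seq) == length
    models.sort(key=lambda m: m.start)
    return seq, models


# ---------------------------------------------------------------------------
# Event planting


def default_frequency_dist(rng: np.random.Generator) -> float:
    """Editing-frequency mixture with its mode in the 0.91-1.00 bin.

    Half the sites are near-fully edited (uniform 0.91-1.0); the rest spread
    over 0.30-0.90.  Real per-site frequencies per tissue are unknown; this
    is a modeling choice, not an inferred fact.
    """
    if rng.random() < 0.5:
        return float(rng.uniform(0.91, 1.0))
    return float(rng.uniform(0.30, 0.90))


def _sense_strand_group(strand: str) -> str:
    return "F" if strand == "+" else "R"


def plant_events(
    genome: str,
    models: Sequence[GeneModel],
    n_edits: int,
    sre_fraction: float = 0.0,
    cluster_spec: tuple[int, int] | None = None,
    freq_dist: Callable[[np.random.Generator], float] | None = None,
    n_snps: int = 0,
    seed: int = 0,
    cds_c2u_fraction: float = 0.8,
    codon12_bias: float = 0.9,
    n_indels: int = 0,
    n_overlap_snps: int = 0,
    cluster_frequency: float = 1.0,
) -> GroundTruth:
    """Plant editing events, SRE pairs, clusters and genomic SNPs.

    ``n_edits`` counts edited genomic positions; ``round(sre_fraction *
    n_edits)`` of them carry an exact mirrored pair (F x→y and R
    comp(x)→comp(y) at the same position).  A ``cluster_spec`` of
    ``(k, window)`` additionally packs k edits into one window of that many
    bases inside a single CDS, at ``cluster_frequency`` — the fixture that
    makes the mismatch-budget calibration meaningful.  SNP positions are
    disjoint from edit positions unless ``n_overlap_snps`` requests overlaps
    to exercise the exclusion step.
    """
    if not 0.0 <= sre_fraction <= 1.0:
        raise ValueError("sre_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    freq_dist = freq_dist or default_frequency_dist
    coding = [m for m in models if m.kind == "protein_coding"]

    # eligible sense-strand CDS positions whose transcript base is C,
    # bucketed by codon position
    c2u_pool: dict[int, list[tuple[int, GeneModel]]] = {1: [], 2: [], 3: []}
    for m in coding:
        spliced = m.spliced_cds(genome)
        for off in range(1, len(spliced) + 1):
            if spliced[off - 1] == "C":
                cp = (off - 1) % 3 + 1
                c2u_pool[cp].append((m.genomic_position_of(off), m))
    gene_positions = [
        (pos, m)
        for m in models
        for pos in range(m.start, m.end + 1)
    ]

    used: set[int] = set()
    edits: list[PlantedEdit] = []

    def _plant_at(pos: int, strand_group: str, rna_ref: str, rna_alt: str,
                  freq: float, is_sre: bool) -> None:
        edits.append(PlantedEdit(pos, strand_group, rna_ref, rna_alt, freq, is_sre))
        if is_sre:
            edits.append(
                PlantedEdit(
                    pos,
                    "R" if strand_group == "F" else "F",
                    rna_complement(rna_ref),
                    rna_complement(rna_alt),
                    freq,
                    True,
                )
            )
        used.add(pos)

    n_sre = round(sre_fraction * n_edits)
    n_c2u = round(cds_c2u_fraction * n_edits)

    def _draw_c2u() -> tuple[int, GeneModel]:
        for _ in range(10000):
            if rng.random() < codon12_bias:
                cp = int(rng.integers(1, 3))
            else:
                cp = 3
            pool = c2u_pool[cp]
            if not pool:
                continue
            pos, m = pool[rng.integers(0, len(pool))]
            if pos not in used:
                return pos, m
        raise ValueError("more events requested than eligible positions")

    planted = 0
    # C->U sites on the sense strand first (SRE flags assigned among them)
    while planted < n_c2u and planted < n_edits:
        pos, m = _draw_c2u()
        freq = freq_dist(rng)
        _plant_at(pos, _sense_strand_group(m.strand), "C", "U", freq, planted < n_sre)
        planted += 1
    # remaining sites: any gene position, any of the 12 substitution types
    attempts = 0
    while planted < n_edits:
        attempts += 1
        if attempts > 100000:
            raise ValueError("more events requested than eligible positions")
        pos, m = gene_positions[rng.integers(0, len(gene_positions))]
        if pos in used:
            continue
        group = _sense_strand_group(m.strand)
        ref = genome_to_rna(genome[pos - 1], group)
        alt = rng.choice([b for b in "ACGU" if b != ref])
        _plant_at(pos, group, ref, str(alt), freq_dist(rng), planted < n_sre)
        planted += 1

    # dense cluster inside one CDS, sense strand
    if cluster_spec is not None:
        k, window = cluster_spec
        host = max(coding, key=lambda m: m.cds_length)
        group = _sense_strand_group(host.strand)
        for _ in range(10000):
            w0 = int(rng.integers(host.start, host.end - window + 2))
            cand = [p for p in range(w0, w0 + window) if p not in used]
            if len(cand) >= k:
                chosen = rng.choice(len(cand), size=k, replace=False)
                for ci in sorted(chosen):
                    pos = cand[ci]
                    ref = genome_to_rna(genome[pos - 1], group)
                    alt = "U" if ref == "C" else rna_complement(ref)
                    _plant_at(pos, group, ref, alt, cluster_frequency, False)
                break
        else:
            raise ValueError("could not place requested edit cluster")

    # genomic SNPs (inside gene spans so RNA evidence exists)
    snps: list[PlantedSnp] = []
    placed = 0
    attempts = 0
    while placed < n_snps:
        attempts += 1
        if attempts > 100000:
            raise ValueError("more SNPs requested than eligible positions")
        pos, m = gene_positions[rng.integers(0, len(gene_positions))]
        want_overlap = placed < n_overlap_snps
        if want_overlap:
            edited = sorted(used - {s.position for s in snps})
            if not edited:
                continue
            pos = edited[rng.integers(0, len(edited))]
        elif pos in used or any(s.position == pos for s in snps):
            continue
        ref = genome[pos - 1]
        alt = str(rng.choice([b for b in DNA if b != ref]))
        af = float(rng.choice([0.5, 1.0]))
        snps.append(PlantedSnp(pos, ref, alt, af, False))
        placed += 1
    for _ in range(n_indels):
        for _ in range(10000):
            pos, m = gene_positions[rng.integers(0, len(gene_positions))]
            span = set(range(pos, pos + 3))
            if span & used or any(s.position in span for s in snps):
                continue
            ref = genome[pos - 1 : pos + 2]  # 3-base REF, 1-base ALT: deletion
            snps.append(PlantedSnp(pos, ref, ref[0], 1.0, True))
            break

    return GroundTruth(
        edits=edits,
        snps=snps,
        params={
            "n_edits": n_edits,
            "sre_fraction": sre_fraction,
            "n_snps": n_snps,
            "seed": seed,
            "genome_length": len(genome),
        },
    )


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(
    genome: str,
    models: Sequence[GeneModel],
    truth: GroundTruth,
    depth: float = 50.0,
    read_length: int = 100,
    error_rate: float = 0.005,
    protocol: str = "FR",
    seed: int = 0,
    transcript_fraction: float = 0.9,
    antisense_fraction: float = 0.5,
    contig_name: str = "mito",
) -> tuple[list[tuple[str, str]], list[SamRecord]]:
    """Draw strand-specific RNA reads and their true-placement SAM records.

    Reads come from gene regions (on the gene's strand, or the antisense
    strand for ``antisense_fraction`` of them — the antisense transcription
    that makes symmetrical editing observable) and from intergenic background
    on both strands.  A read overlapping a planted edit on its own strand
    group carries the alt base with probability equal to the editing
    frequency; substitution SNPs appear at their allele frequency on every
    read regardless of strand.  FASTQ sequences are transcript-oriented;
    the truth SAM stores genome-forward sequence with flag 16 for the
    reverse strand group.
    """
    if protocol != "FR":
        raise ValueError("only the FR strand protocol is supported")
    if read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    glen = len(genome)
    n_reads = math.ceil(depth * glen / read_length)

    gene_list = list(models)
    weights = np.array([m.end - m.start + 1 for m in gene_list], dtype=float)
    weights /= weights.sum()

    # per-strand lookup of events by position
    edits_by_group: dict[str, dict[int, PlantedEdit]] = {"F": {}, "R": {}}
    for e in truth.edits:
        edits_by_group[e.strand_group][e.position] = e
    sub_snps = {s.position: s for s in truth.snps if not s.is_indel}

    reads: list[tuple[str, str]] = []
    sam: list[SamRecord] = []
    for i in range(n_reads):
        if rng.random() < transcript_fraction and gene_list:
            g = gene_list[rng.choice(len(gene_list), p=weights)]
            span = g.end - g.start + 1
            if span >= read_length:
                start = int(rng.integers(g.start, g.end - read_length + 2))
            else:
                lo = max(1, g.end - read_length + 1)
                hi = min(g.start, glen - read_length + 1)
                start = int(rng.integers(lo, hi + 1)) if lo <= hi else 1
            sense = _sense_strand_group(g.strand)
            if rng.random() < antisense_fraction:
                group = "R" if sense == "F" else "F"
            else:
                group = sense
        else:
            start = int(rng.integers(1, glen - read_length + 2))
            group = "F" if rng.random() < 0.5 else "R"

        window = list(genome[start - 1 : start + read_length - 1])
        for off in range(read_length):
            pos = start + off
            snp = sub_snps.get(pos)
            if snp is not None and rng.random() < snp.allele_frequency:
                window[off] = snp.alt
            edit = edits_by_group[group].get(pos)
            if edit is not None and rng.random() < edit.editing_frequency:
                window[off] = rna_to_genome(edit.rna_alt, group)
        if error_rate > 0:
            err = rng.random(read_length) < error_rate
            for off in np.nonzero(err)[0]:
                window[off] = str(rng.choice([b for b in DNA if b != window[off]]))
        gseq = "".join(window)
        read_id = f"r{i:06d}"
        reads.append((read_id, gseq if group == "F" else revcomp(gseq)))
        sam.append(
            SamRecord(
                read_id=read_id,
                flag=0 if group == "F" else 16,
                contig=contig_name,
                position=start,
                seq=gseq,
            )
        )
    return reads, sam


def simulate_dna_reads(
    genome: str,
    truth: GroundTruth,
    depth: float = 40.0,
    read_length: int = 100,
    error_rate: float = 0.002,
    seed: int = 0,
    contig_name: str = "mito",
) -> tuple[list[tuple[str, str]], list[SamRecord]]:
    """Whole-genomic-DNA reads: uniform coverage, SNP alleles, no editing."""
    rng = np.random.default_rng(seed)
    glen = len(genome)
    n_reads = math.ceil(depth * glen / read_length)
    sub_snps = {s.position: s for s in truth.snps if not s.is_indel}
    reads, sam = [], []
    for i in range(n_reads):
        start = int(rng.integers(1, glen - read_length + 2))
        group = "F" if rng.random() < 0.5 else "R"
        window = list(genome[start - 1 : start + read_length - 1])
        for off in range(read_length):
            snp = sub_snps.get(start + off)
            if snp is not None and rng.random() < snp.allele_frequency:
                window[off] = snp.alt
        if error_rate > 0:
            err = rng.random(read_length) < error_rate
            for off in np.nonzero(err)[0]:
                window[off] = str(rng.choice([b for b in DNA if b != window[off]]))
        gseq = "".join(window)
        read_id = f"d{i:06d}"
        reads.append((read_id, gseq if group == "F" else revcomp(gseq)))
        sam.append(
            SamRecord(
                read_id=read_id,
                flag=0 if group == "F" else 16,
                contig=contig_name,
                position=start,
                seq=gseq,
            )
        )
    return reads, sam


# ---------------------------------------------------------------------------
# Homolog evolution (conservation fixtures)


@dataclass
class EvolvedGene:
    species_id: str
    gene_id: str
    sequence: str
    # ancestor CDS offset (1-based) -> species CDS offset (1-based) or None
    offset_map: dict[int, int | None] = field(default_factory=dict)


def evolve_homolog(
    ancestor_cds: str,
    gene_id: str,
    species_ids: Sequence[str],
    sub_rate: float = 0.02,
    codon_indel_rate: float = 0.005,
    seed: int = 0,
) -> list[EvolvedGene]:
    """Derive one homolog per species from an ancestral CDS.

    Per species: whole-codon deletions/insertions at ``codon_indel_rate`` per
    codon and point substitutions at ``sub_rate`` per base, with the
    ancestor-offset -> species-offset map tracked exactly (None = deleted).
    """
    rng = np.random.default_rng(seed)
    out = []
    n_codons = len(ancestor_cds) // 3
    for sp in species_ids:
        seq_parts: list[str] = []
        offset_map: dict[int, int | None] = {}
        cursor = 0  # species offset so far (0-based count of emitted bases)
        for c in range(n_codons):
            codon = ancestor_cds[3 * c : 3 * c + 3]
            roll = rng.random()
            if 0 < c < n_codons - 1 and roll < codon_indel_rate:
                for j in range(3):  # codon deleted
                    offset_map[3 * c + j + 1] = None
                continue
            if 0 < c < n_codons - 1 and roll < 2 * codon_indel_rate:
                ins = "".join(DNA[i] for i in rng.integers(0, 4, size=3))
                seq_parts.append(ins)
                cursor += 3
            new = []
            for j, base in enumerate(codon):
                if rng.random() < sub_rate:
                    base = str(rng.choice([b for b in DNA if b != base]))
                new.append(base)
                offset_map[3 * c + j + 1] = cursor + j + 1
            seq_parts.append("".join(new))
            cursor += 3
        out.append(EvolvedGene(sp, gene_id, "".join(seq_parts), offset_map))
    return out


def plant_conserved_edits(
    evolved: Sequence[EvolvedGene],
    n_shared: int,
    seed: int = 0,
    indel_buffer: int = 9,
) -> list[dict]:
    """Pick ancestor C positions preserved in every species and mark C→U edits.

    Returns one record per (species, site): dicts with species_id, gene_id,
    cds_offset, rna_ref, rna_alt, orientation — the shape ``conserve``
    consumes.  Eligible positions must keep the C in every species and sit
    at least ``indel_buffer`` bases away from any indel in every species:
    a position right next to an indel has no unambiguous homolog (optimal
    gap placement is not unique there), so "planted at homologous positions"
    is only well defined in locally colinear context.
    """
    rng = np.random.default_rng(seed)
    by_gene: dict[str, list[EvolvedGene]] = {}
    for g in evolved:
        by_gene.setdefault(g.gene_id, []).append(g)
    eligible: list[tuple[str, int]] = []
    for gene_id, members in by_gene.items():
        n_anc = max(max(m.offset_map) for m in members)
        for off in range(1, n_anc + 1):
            ok = True
            for m in members:
                sp_off = m.offset_map.get(off)
                if sp_off is None or m.sequence[sp_off - 1] != "C":
                    ok = False
                    break
                # locally colinear: neighbouring offsets shift uniformly
                for d in range(-indel_buffer, indel_buffer + 1):
                    o = off + d
                    if o < 1 or o > n_anc:
                        continue
                    if m.offset_map.get(o) != sp_off + d:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                eligible.append((gene_id, off))
    if n_shared > len(eligible):
        raise ValueError(f"only {len(eligible)} conserved C positions available")
    chosen = [eligible[i] for i in rng.choice(len(eligible), size=n_shared, replace=False)]
    records = []
    for gene_id, off in sorted(chosen):
        for m in by_gene[gene_id]:
            records.append(
                {
                    "species_id": m.species_id,
                    "gene_id": gene_id,
                    "cds_offset": m.offset_map[off],
                    "rna_ref": "C",
                    "rna_alt": "U",
                    "orientation": "sense",
                }
            )
    return records
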