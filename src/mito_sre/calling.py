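"""Strand-partitioned pileups and site calling.

Two callers are implemented:

* the mapping-based caller (``call_editing_sites``): per (position, strand
  group) column, a non-reference base is called an editing site when
  coverage >= 5, frequency >= 0.1, at least ``min_alt`` (default 3) reads
  support the variant, and the one-sided exact binomial tail
  P(X >= alt_count | n=depth, p=error_rate/3) <= 0.05; a column where two
  or more distinct alternates pass is discarded entirely (multi-type
  exclusion).  The supporting-reads floor mirrors the minimum-variant-reads
  default of REDItools-style callers; without it a single sequencing error
  in a depth-5..10 column satisfies all three ratio cutoffs;
* the consensus caller (``consensus_sites``): the assembly-method stand-in —
  at sufficient depth the strict-majority base, when it differs from the
  reference, is a site.  It sees only the dominant allele, so it misses
  low-frequency editing, exactly the limitation that motivates comparing
  the two methods.

Calls are reported in RNA space: reverse-strand-group mismatches are
complemented and T is written U, so a genomic C→T column on the reverse
group becomes the antisense "G to A" event.

DNA SNPs are called from a strand-pooled pileup (coverage >= 10, frequency
>= 0.1 for the high-quality flag); editing sites overlapping high-quality
SNPs or indel reference spans are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import VariantRow
from .mapping import Genome, StrandedAlignment
from .simulate import genome_to_rna

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_FREQ_EPS = 1e-9  # absorbs binary-float error so frequency == f_min passes


@dataclass
class PileupColumn:
    position: int
    strand_group: str
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


class Pileup:
    """Per-strand-group base counts over a reference contig."""

    def __init__(self, genome_length: int, groups: tuple[str, ...] = ("F", "R")):
        self.genome_length = genome_length
        # row 0 unused: 1-based positions index directly
        self.counts = {g: np.zeros((genome_length + 1, 4), dtype=np.int32) for g in groups}

    def column(self, position: int, strand_group: str) -> PileupColumn:
        row = self.counts[strand_group][position]
        return PileupColumn(
            position=position,
            strand_group=strand_group,
            counts={b: int(row[i]) for i, b in enumerate(_BASES) if row[i]},
        )

    def depth(self, position: int, strand_group: str) -> int:
        return int(self.counts[strand_group][position].sum())

    def covered_positions(self, strand_group: str) -> np.ndarray:
        return np.nonzero(self.counts[strand_group].sum(axis=1))[0]

    def pooled(self) -> "Pileup":
        """Strand-agnostic view (DNA pileups): counts summed over groups."""
        p = Pileup(self.genome_length, groups=("*",))
        p.counts["*"] = sum(self.counts.values())
        return p


def build_pileup(
    alignments: list[StrandedAlignment], genome: Genome, groups=("F", "R")
) -> Pileup:
    """Tally genome-space bases of every alignment per (position, strand group)."""
    pile = Pileup(len(genome), groups=groups)
    code = {b: i for i, b in enumerate(_BASES)}
    for a in alignments:
        L = len(a.genome_space_seq)
        if a.position < 1 or a.position + L - 1 > len(genome):
            raise ValueError(
                f"alignment {a.read_id} at {a.position} (+{L}) exceeds genome bounds"
            )
        g = a.strand_group if a.strand_group in pile.counts else "*"
        arr = pile.counts[g]
        for off, base in enumerate(a.genome_space_seq):
            idx = code.get(base)
            if idx is not None:  # N contributes nothing
                arr[a.position + off, idx] += 1
    return pile


@dataclass(frozen=True)
class EditingSite:
    contig: str
    position: int
    strand_group: str
    rna_ref: str
    rna_alt: str
    depth: int
    alt_count: int
    frequency: float
    p_value: float
    sample: str = ""

    @property
    def key(self) -> tuple:
        return (self.position, self.strand_group, self.rna_ref, self.rna_alt)

    @property
    def substitution(self) -> str:
        return f"{self.rna_ref}>{self.rna_alt}"


def binomial_p(alt_count: int, depth: int, per_alt_error: float) -> float:
    """One-sided tail P(X >= alt_count) for X ~ Binomial(depth, per_alt_error)."""
    return float(stats.binom.sf(alt_count - 1, depth, per_alt_error))


def call_editing_sites(
    pileup: Pileup,
    genome: Genome,
    c_min: int = 5,
    f_min: float = 0.1,
    p_max: float = 0.05,
    error_rate: float = 0.01,
    min_alt: int = 3,
    sample: str = "",
    groups=("F", "R"),
) -> list[EditingSite]:
    """Call per-strand editing sites with the coverage/frequency/P cutoffs."""
    sites: list[EditingSite] = []
    per_alt = error_rate / 3.0
    for g in groups:
        arr = pileup.counts[g]
        depths = arr.sum(axis=1)
        for pos in np.nonzero(depths >= c_min)[0]:
            ref = genome.seq[pos - 1]
            if ref not in _BASES:
                logger.warning("reference base N at %d: column skipped", pos)
                continue
            depth = int(depths[pos])
            passing = []
            for i, base in enumerate(_BASES):
                if base == ref or arr[pos, i] == 0:
                    continue
                alt_count = int(arr[pos, i])
                if alt_count < min_alt or alt_count < f_min * depth - _FREQ_EPS:
                    continue
                p = binomial_p(alt_count, depth, per_alt)
                if p > p_max:
                    continue
                passing.append((base, alt_count, p))
            if len(passing) != 1:
                continue  # nothing passed, or multi-type column discarded
            base, alt_count, p = passing[0]
            sites.append(
                EditingSite(
                    contig=genome.name,
                    position=int(pos),
                    strand_group=g,
                    rna_ref=genome_to_rna(ref, g),
                    rna_alt=genome_to_rna(base, g),
                    depth=depth,
                    alt_count=alt_count,
                    frequency=alt_count / depth,
                    p_value=p,
                    sample=sample,
                )
            )
    sites.sort(key=lambda s: (s.position, s.strand_group))
    return sites


def consensus_sites(
    pileup: Pileup,
    genome: Genome,
    c_min: int = 5,
    sample: str = "",
    groups=("F", "R"),
) -> list[EditingSite]:
    """Assembly-method stand-in: strict-majority consensus vs the reference."""
    sites: list[EditingSite] = []
    for g in groups:
        arr = pileup.counts[g]
        depths = arr.sum(axis=1)
        for pos in np.nonzero(depths >= c_min)[0]:
            ref = genome.seq[pos - 1]
            if ref not in _BASES:
                continue
            depth = int(depths[pos])
            top = int(arr[pos].argmax())
            top_count = int(arr[pos, top])
            if 2 * top_count <= depth:  # no strict majority (ties included)
                continue
            base = _BASES[top]
            if base == ref:
                continue
            sites.append(
                EditingSite(
                    contig=genome.name,
                    position=int(pos),
                    strand_group=g,
                    rna_ref=genome_to_rna(ref, g),
                    rna_alt=genome_to_rna(base, g),
                    depth=depth,
                    alt_count=top_count,
                    frequency=top_count / depth,
                    p_value=float("nan"),
                    sample=sample,
                )
            )
    sites.sort(key=lambda s: (s.position, s.strand_group))
    return sites


@dataclass(frozen=True)
class SnpSite:
    position: int
    ref: str  # genome space; multi-base REF for deletions
    alt: str
    depth: int | None
    allele_frequency: float | None
    is_indel: bool = False
    high_quality: bool = True

    @property
    def ref_span(self) -> tuple[int, int]:
        return self.position, self.position + len(self.ref) - 1


def call_snps(
    dna_pileup: Pileup,
    genome: Genome,
    c_min: int = 10,
    f_min: float = 0.1,
) -> list[SnpSite]:
    """Substitution SNPs from a strand-pooled DNA pileup.

    Every non-reference base at frequency >= f_min is reported; the
    high-quality flag additionally requires depth >= c_min.  Indels cannot
    arise here (the mapper is ungapped) — they enter via VCF input.
    """
    if "*" not in dna_pileup.counts:
        dna_pileup = dna_pileup.pooled()
    arr = dna_pileup.counts["*"]
    depths = arr.sum(axis=1)
    snps: list[SnpSite] = []
    for pos in np.nonzero(depths > 0)[0]:
        ref = genome.seq[pos - 1]
        if ref not in _BASES:
            continue
        depth = int(depths[pos])
        for i, base in enumerate(_BASES):
            if base == ref:
                continue
            alt_count = int(arr[pos, i])
            if alt_count == 0 or alt_count < f_min * depth - _FREQ_EPS:
                continue
            snps.append(
                SnpSite(
                    position=int(pos),
                    ref=ref,
                    alt=base,
                    depth=depth,
                    allele_frequency=alt_count / depth,
                    is_indel=False,
                    high_quality=depth >= c_min,
                )
            )
    return snps


def snps_from_vcf(rows: list[VariantRow], c_min: int = 10, f_min: float = 0.1) -> list[SnpSite]:
    """Adopt minimal-VCF variant rows (the indel route) as SNP sites."""
    out = []
    for r in rows:
        hq = True
        if r.depth is not None and r.depth < c_min:
            hq = False
        if r.frequency is not None and r.frequency < f_min - _FREQ_EPS:
            hq = False
        out.append(
            SnpSite(
                position=r.position,
                ref=r.ref,
                alt=r.alt,
                depth=r.depth,
                allele_frequency=r.frequency,
                is_indel=r.is_indel,
                high_quality=hq,
            )
        )
    return out


def exclude_snp_overlaps(
    editing_sites: list[EditingSite], snp_sites: list[SnpSite]
) -> tuple[list[EditingSite], list[EditingSite]]:
    """Drop editing sites at high-quality SNP positions or inside indel spans."""
    excluded_positions: set[int] = set()
    for s in snp_sites:
        if not s.high_quality:
            continue
        lo, hi = s.ref_span
        excluded_positions.update(range(lo, hi + 1))
    kept, excluded = [], []
    for site in editing_sites:
        (excluded if site.position in excluded_positions else kept).append(site)
    return kept, excluded


def pool_samples(per_sample: dict[str, list[StrandedAlignment]]) -> list[StrandedAlignment]:
    """Concatenate per-sample alignments, tagging provenance; one reference only."""
    contigs = {a.contig for alns in per_sample.values() for a in alns}
    if len(contigs) > 1:
        raise ValueError(f"alignments from different references: {sorted(contigs)}")
    pooled: list[StrandedAlignment] = []
    for sample, alns in per_sample.items():
        for a in alns:
            pooled.append(
                StrandedAlignment(
                    read_id=a.read_id,
                    position=a.position,
                    strand_group=a.strand_group,
                    genome_space_seq=a.genome_space_seq,
                    n_mismatch=a.n_mismatch,
                    contig=a.contig,
                    sample=sample or a.sample,
                )
            )
    return pooled
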