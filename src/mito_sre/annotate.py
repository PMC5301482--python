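"""Genomic context, codon consequences and summaries for editing sites.

CDS sense-strand sites get codon-level consequences under the standard
genetic code (table 1 — appropriate for land-plant mitochondrial CDS and
configurable), including the start-codon-creating ACG→AUG case.  Site names
follow the gene-offset convention ("cox2-544" = 544th spliced-CDS base of
cox2).  The hydrophobic amino-acid set used for the hydrophobicity-shift
summary is a module constant so the claim can be probed under alternative
definitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .calling import EditingSite
from .io_formats import GeneModel
from .mapping import Genome
from .simulate import revcomp

logger = logging.getLogger(__name__)

HYDROPHOBIC = frozenset("AVLIPFMWGC")

CDS, INTRON, TRNA, RRNA, INTERGENIC = "CDS", "intron", "tRNA", "rRNA", "intergenic"
SENSE, ANTISENSE = "sense", "antisense"
SUBSTITUTION_TYPES = [f"{a}>{b}" for a in "ACGU" for b in "ACGU" if a != b]

FREQ_BIN_LABELS = [
    "1-10%", "11-20%", "21-30%", "31-40%", "41-50%",
    "51-60%", "61-70%", "71-80%", "81-90%", "91-100%",
]


@dataclass
class AnnotatedSite:
    site: EditingSite
    region: str
    gene_id: str | None = None
    orientation: str | None = None  # sense/antisense; forward/reverse for intergenic
    cds_offset: int | None = None
    codon_index: int | None = None
    codon_position: int | None = None
    ref_codon: str | None = None  # RNA triplet
    alt_codon: str | None = None
    ref_aa: str | None = None  # single letter, '*' for stop
    alt_aa: str | None = None
    effect: str = "noncoding"
    site_name: str = ""


def locate_site(
    site: EditingSite, gene_models: list[GeneModel]
) -> tuple[str, GeneModel | None, str]:
    """Assign (region, gene, orientation) by coordinate containment.

    Precedence CDS > intron > tRNA/rRNA > intergenic; genes may not overlap
    at the site (the naming and orientation rules would be ambiguous).
    """
    pos = site.position
    hits = [g for g in gene_models if g.start <= pos <= g.end]
    if len(hits) > 1:
        raise ValueError(f"overlapping genes {[g.gene_id for g in hits]} at {pos}")
    if hits:
        g = hits[0]
        sense = (site.strand_group == "F") == (g.strand == "+")
        orientation = SENSE if sense else ANTISENSE
        if g.kind == "protein_coding":
            if any(s <= pos <= e for s, e in g.cds):
                return CDS, g, orientation
            if any(s <= pos <= e for s, e in g.introns):
                return INTRON, g, orientation
            return INTERGENIC, None, "forward" if site.strand_group == "F" else "reverse"
        return (TRNA if g.kind == "tRNA" else RRNA), g, orientation
    return INTERGENIC, None, "forward" if site.strand_group == "F" else "reverse"


def _translate(codon_rna: str, table: int = 1) -> str:
    return str(Seq(codon_rna.replace("U", "T")).translate(table=table))


def codon_effect(
    ann: AnnotatedSite, genome: Genome, gene: GeneModel, table: int = 1
) -> AnnotatedSite:
    """Fill codon fields and the effect class for a CDS sense site (in place).

    Effects: silent, start_gain (codon 1 becomes AUG), stop_gain, stop_loss,
    else missense.
    """
    if ann.region != CDS or ann.orientation != SENSE:
        raise ValueError("codon_effect applies to CDS sense sites only")
    spliced = gene.spliced_cds(genome.seq)
    if len(spliced) % 3 != 0:
        raise ValueError(f"CDS length of {gene.gene_id} not divisible by 3")
    off = gene.cds_offset_of(ann.site.position)
    if off is None:
        raise ValueError(f"position {ann.site.position} not in CDS of {gene.gene_id}")
    ann.cds_offset = off
    ann.codon_index = (off - 1) // 3 + 1
    ann.codon_position = (off - 1) % 3 + 1
    codon_dna = spliced[3 * (ann.codon_index - 1) : 3 * ann.codon_index]
    ref_codon = codon_dna.replace("T", "U")
    alt = ann.site.rna_alt
    alt_codon = (
        ref_codon[: ann.codon_position - 1] + alt + ref_codon[ann.codon_position :]
    )
    ann.ref_codon, ann.alt_codon = ref_codon, alt_codon
    ann.ref_aa = _translate(ref_codon, table)
    ann.alt_aa = _translate(alt_codon, table)
    if ann.ref_aa == ann.alt_aa:
        ann.effect = "silent"
    elif ann.codon_index == 1 and alt_codon == "AUG" and ref_codon != "AUG":
        ann.effect = "start_gain"
    elif ann.alt_aa == "*" and ann.ref_aa != "*":
        ann.effect = "stop_gain"
    elif ann.ref_aa == "*" and ann.alt_aa != "*":
        ann.effect = "stop_loss"
    else:
        ann.effect = "missense"
    return ann


def annotate_sites(
    sites: list[EditingSite],
    genome: Genome,
    gene_models: list[GeneModel],
    table: int = 1,
) -> list[AnnotatedSite]:
    """Locate every site; compute codon consequences for CDS sense sites."""
    out = []
    for site in sites:
        region, gene, orientation = locate_site(site, gene_models)
        ann = AnnotatedSite(
            site=site,
            region=region,
            gene_id=gene.gene_id if gene else None,
            orientation=orientation,
        )
        if region == CDS and gene is not None:
            ann.cds_offset = gene.cds_offset_of(site.position)
            if orientation == SENSE:
                codon_effect(ann, genome, gene, table=table)
        if ann.gene_id and ann.cds_offset:
            ann.site_name = f"{ann.gene_id}-{ann.cds_offset}"
        else:
            ann.site_name = f"{site.contig}:{site.position}:{site.strand_group}"
        out.append(ann)
    return out


def hydrophobicity_shift(
    annotated_sites: list[AnnotatedSite], hydrophobic: frozenset = HYDROPHOBIC
) -> tuple[float, float]:
    """Percent hydrophobic among affected residues before vs after editing.

    Stop codons are excluded from the respective denominator.
    """
    with_aa = [a for a in annotated_sites if a.ref_aa is not None]
    if not with_aa:
        raise ValueError("no sites with amino-acid consequences")
    before = [a.ref_aa for a in with_aa if a.ref_aa != "*"]
    after = [a.alt_aa for a in with_aa if a.alt_aa != "*"]
    pct_before = 100.0 * sum(aa in hydrophobic for aa in before) / len(before) if before else 0.0
    pct_after = 100.0 * sum(aa in hydrophobic for aa in after) / len(after) if after else 0.0
    return pct_before, pct_after


def type_frequency_summary(
    sites: list[EditingSite], bins: int = 10
) -> tuple[pd.DataFrame, pd.Series]:
    """Counts per 12 substitution types x strand group, and a frequency histogram.

    Frequency bins are (0.0,0.1], (0.1,0.2], ..., (0.9,1.0], labelled
    "1-10%" ... "91-100%".
    """
    type_counts = pd.DataFrame(0, index=SUBSTITUTION_TYPES, columns=["F", "R"])
    for s in sites:
        type_counts.loc[s.substitution, s.strand_group] += 1
    if bins != 10:
        edges = [i / bins for i in range(bins + 1)]
        labels = [f"{int(edges[i]*100)+1}-{int(edges[i+1]*100)}%" for i in range(bins)]
    else:
        edges = [i / 10 for i in range(11)]
        labels = FREQ_BIN_LABELS
    freqs = pd.Series([s.frequency for s in sites], dtype=float)
    hist = (
        pd.cut(freqs, bins=edges, labels=labels, right=True, include_lowest=False)
        .value_counts()
        .reindex(labels, fill_value=0)
    )
    return type_counts, hist


def extract_upstream_windows(
    annotated_sites: list[AnnotatedSite], genome: Genome, span: int = 25,
    include_site: bool = True,
) -> list[tuple[str, str]]:
    """Transcript-orientation windows from -span through the edited base.

    Forward-group sites yield genome[p-span..p]; reverse-group sites the
    reverse complement of genome[p..p+span].  With ``include_site=False``
    the edited base itself is omitted (a span-long window).  Windows running
    off the genome end are dropped with a warning.  DNA alphabet (motif-tool
    ready).
    """
    out = []
    glen = len(genome)
    for ann in annotated_sites:
        p = ann.site.position
        if ann.site.strand_group == "F":
            lo, hi = p - span, p if include_site else p - 1
            if lo < 1:
                logger.warning("window for %s truncated at genome start: dropped", ann.site_name)
                continue
            seq = genome.seq[lo - 1 : hi]
        else:
            lo, hi = p if include_site else p + 1, p + span
            if hi > glen:
                logger.warning("window for %s truncated at genome end: dropped", ann.site_name)
                continue
            seq = revcomp(genome.seq[lo - 1 : hi])
        out.append((ann.site_name, seq))
    return out
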