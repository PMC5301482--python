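"""Readers and writers for the formats the pipeline touches.

Every coordinate in every file is 1-based inclusive.  The SAM dialect is
deliberately narrow: this pipeline's mapper is ungapped, so only flags 0
(forward), 4 (unmapped) and 16 (reverse) and all-match CIGAR strings are
accepted; anything else is rejected loudly rather than silently skipped,
because a silently dropped gapped record would bias pileups.

RNA bases in site tables are written with U (never T); DNA contexts use T.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

SITE_TABLE_COLUMNS = [
    "contig",
    "position",
    "strand_group",
    "rna_ref",
    "rna_alt",
    "depth",
    "alt_count",
    "frequency",
    "p_value",
    "sample",
]

_RNA_BASES = {"A", "C", "G", "U"}


class FormatError(ValueError):
    """Raised for malformed or out-of-dialect input files."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` in file order.

    Sequences are uppercased; line wrapping is ignored.  Duplicate record
    ids and empty files are errors.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# FASTQ


def write_fastq(reads: Iterable[tuple[str, str]], path, quality_char: str = "I") -> None:
    """Write ``(read_id, sequence)`` pairs with a flat Phred+33 quality string."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# SAM (restricted dialect)


@dataclass
class SamRecord:
    """One alignment row in the pipeline dialect.

    ``seq`` is stored in genome-forward orientation; ``flag`` 16 marks a read
    whose transcript orientation maps to the reverse strand group.
    """

    read_id: str
    flag: int  # 0, 4 or 16
    contig: str
    position: int  # 1-based leftmost; 0 for unmapped
    seq: str
    mapq: int = 255

    ALLOWED_FLAGS = (0, 4, 16)

    def __post_init__(self):
        if self.flag not in self.ALLOWED_FLAGS:
            raise FormatError(f"flag {self.flag} outside dialect {self.ALLOWED_FLAGS}")

    @property
    def strand_group(self) -> str:
        return "R" if self.flag == 16 else "F"

    @property
    def cigar(self) -> str:
        return "*" if self.flag == 4 else f"{len(self.seq)}M"


def write_sam(records: Sequence[SamRecord], path, reference_lengths: dict[str, int]) -> None:
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": name, "LN": length} for name, length in reference_lengths.items()],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(header)
            a.query_name = rec.read_id
            a.query_sequence = rec.seq
            a.flag = rec.flag
            a.mapping_quality = rec.mapq
            if rec.flag == 4:
                a.reference_id = -1
                a.reference_start = -1
            else:
                a.reference_id = list(reference_lengths).index(rec.contig)
                a.reference_start = rec.position - 1
                a.cigarstring = f"{len(rec.seq)}M"
            out.write(a)


def read_sam(path) -> tuple[list[SamRecord], dict[str, int]]:
    """Read a SAM file, enforcing the dialect (flags 0/4/16, all-match CIGAR)."""
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        ref_lengths = dict(zip(fh.references, fh.lengths))
        for a in fh:
            if a.flag not in SamRecord.ALLOWED_FLAGS:
                raise FormatError(f"flag {a.flag} outside supported dialect")
            if a.flag != 4:
                for op, _ in a.cigartuples or []:
                    if op != 0:  # 0 == M
                        opname = "MIDNSHP=X"[op]
                        raise FormatError(f"unsupported CIGAR operator {opname!r}")
            records.append(
                SamRecord(
                    read_id=a.query_name,
                    flag=a.flag,
                    contig=a.reference_name if a.flag != 4 else "*",
                    position=(a.reference_start + 1) if a.flag != 4 else 0,
                    seq=a.query_sequence or "",
                    mapq=a.mapping_quality,
                )
            )
    return records, ref_lengths


# ---------------------------------------------------------------------------
# GFF3 (gene / CDS / tRNA / rRNA / intron subset)


@dataclass
class GeneModel:
    """One gene with transcript-ordered CDS segments.

    ``cds`` segments are 1-based inclusive ``(start, end)`` ordered 5'→3' in
    transcript orientation (descending genomic order for minus-strand genes).
    """

    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    start: int
    end: int
    kind: str = "protein_coding"  # protein_coding | tRNA | rRNA
    cds: list[tuple[int, int]] = field(default_factory=list)
    introns: list[tuple[int, int]] = field(default_factory=list)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def spliced_cds(self, genome_seq: str) -> str:
        """Spliced CDS in transcript orientation (DNA alphabet)."""
        if self.strand == "+":
            return "".join(genome_seq[s - 1 : e] for s, e in self.cds)
        parts = [str(Seq(genome_seq[s - 1 : e]).reverse_complement()) for s, e in self.cds]
        return "".join(parts)

    def cds_offset_of(self, position: int) -> int | None:
        """1-based offset of a genomic position within the spliced CDS, or None."""
        off = 0
        for s, e in self.cds:
            if s <= position <= e:
                return off + (position - s + 1 if self.strand == "+" else e - position + 1)
            off += e - s + 1
        return None

    def genomic_position_of(self, cds_offset: int) -> int:
        """Inverse of :meth:`cds_offset_of` (1-based both ways)."""
        off = cds_offset
        for s, e in self.cds:
            seg_len = e - s + 1
            if off <= seg_len:
                return s + off - 1 if self.strand == "+" else e - off + 1
            off -= seg_len
        raise ValueError(f"cds_offset {cds_offset} beyond CDS of {self.gene_id}")


def read_gff(path) -> list[GeneModel]:
    """Parse the GFF3 subset (gene/CDS/tRNA/rRNA/intron) into gene models."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: dict[str, GeneModel] = {}
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.start > feat.end:
            raise FormatError(f"start > end on line for {feat.id}: {feat.start}..{feat.end}")
        if feat.strand not in ("+", "-"):
            raise FormatError(f"unknown strand {feat.strand!r} for {feat.id}")
        if feat.featuretype == "gene":
            gid = feat.id
            models[gid] = GeneModel(
                gene_id=gid,
                contig=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
            )
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype in ("CDS", "intron"):
            parents = feat.attributes.get("Parent", [])
            if not parents or parents[0] not in models:
                raise FormatError(f"{feat.featuretype} without known Parent gene")
            gene = models[parents[0]]
            seg = (feat.start, feat.end)
            if feat.featuretype == "CDS":
                gene.cds.append(seg)
            else:
                gene.introns.append(seg)
        elif feat.featuretype in ("tRNA", "rRNA"):
            gid = feat.id
            models[gid] = GeneModel(
                gene_id=gid,
                contig=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
                kind=feat.featuretype,
            )
    for gene in models.values():
        gene.cds.sort(key=lambda se: se[0], reverse=(gene.strand == "-"))
        gene.introns.sort(key=lambda se: se[0], reverse=(gene.strand == "-"))
        ordered = sorted(gene.cds)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise FormatError(f"overlapping CDS segments in gene {gene.gene_id}")
    return list(models.values())


def write_gff(models: Sequence[GeneModel], path, contig_lengths: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in contig_lengths.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in models:
            if g.kind in ("tRNA", "rRNA"):
                fh.write(
                    f"{g.contig}\tmito_sre\t{g.kind}\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}\n"
                )
                continue
            fh.write(
                f"{g.contig}\tmito_sre\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for s, e in sorted(g.cds):
                fh.write(
                    f"{g.contig}\tmito_sre\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"Parent={g.gene_id}\n"
                )
            for s, e in sorted(g.introns):
                fh.write(
                    f"{g.contig}\tmito_sre\tintron\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Minimal VCF


@dataclass
class VariantRow:
    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    is_indel: bool
    depth: int | None = None
    frequency: float | None = None

    @property
    def ref_span(self) -> tuple[int, int]:
        """Reference positions covered by REF (1-based inclusive)."""
        return self.position, self.position + len(self.ref) - 1


def _ensure_vcf_contigs(path) -> str:
    """Minimal-dialect tolerance: declare contigs and DP/AF when absent."""
    text = Path(path).read_text()
    insert = []
    if "##contig=" not in text:
        chroms = []
        for ln in text.splitlines():
            if ln and not ln.startswith("#"):
                c = ln.split("\t", 1)[0]
                if c not in chroms:
                    chroms.append(c)
        insert += [f"##contig=<ID={c}>" for c in chroms]
    if "##INFO=<ID=DP" not in text:
        insert.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">')
    if "##INFO=<ID=AF" not in text:
        insert.append('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">')
    if not insert:
        return str(path)
    out = []
    for ln in text.splitlines():
        if ln.startswith("#CHROM"):
            out.extend(insert)
        out.append(ln)
    import tempfile

    tmp = tempfile.NamedTemporaryFile(
        "w", suffix=".vcf", delete=False, prefix="minvcf_"
    )
    tmp.write("\n".join(out) + "\n")
    tmp.close()
    return tmp.name


def read_vcf_min(path) -> list[VariantRow]:
    """Read a minimal VCF; multi-allelic rows are split, DP/AF taken from INFO."""
    rows = []
    with pysam.VariantFile(_ensure_vcf_contigs(path)) as vcf:
        for rec in vcf:
            if rec.pos <= 0:
                raise FormatError(f"non-positive POS {rec.pos}")
            dp = rec.info.get("DP", None)
            af = rec.info.get("AF", None)
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                freq = None
                if af is not None:
                    freq = float(af[i]) if isinstance(af, tuple) else float(af)
                rows.append(
                    VariantRow(
                        contig=rec.chrom,
                        position=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        is_indel=len(rec.ref) != len(alt),
                        depth=int(dp) if dp is not None else None,
                        frequency=freq,
                    )
                )
    return rows


def write_vcf_min(rows: Sequence[VariantRow], path, contig_lengths: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(rows, key=lambda r: (r.contig, r.position)):
            info = []
            if r.depth is not None:
                info.append(f"DP={r.depth}")
            if r.frequency is not None:
                info.append(f"AF={r.frequency:g}")
            fh.write(
                f"{r.contig}\t{r.position}\t.\t{r.ref}\t{r.alt}\t.\t.\t"
                f"{';'.join(info) or '.'}\n"
            )


# ---------------------------------------------------------------------------
# Site tables


def write_site_table(sites, path, comments: Sequence[str] = ()) -> None:
    """Write editing sites (any objects with SiteTableRow fields) as TSV."""
    df = pd.DataFrame(
        [
            {
                "contig": s.contig,
                "position": s.position,
                "strand_group": s.strand_group,
                "rna_ref": s.rna_ref,
                "rna_alt": s.rna_alt,
                "depth": s.depth,
                "alt_count": s.alt_count,
                "frequency": s.frequency,
                "p_value": s.p_value,
                "sample": s.sample,
            }
            for s in sites
        ],
        columns=SITE_TABLE_COLUMNS,
    )
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_site_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SITE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"site table missing columns: {sorted(missing)}")
    bad = df[(df.alt_count > df.depth) | (df.rna_ref == df.rna_alt)]
    if len(bad):
        raise FormatError(f"{len(bad)} invalid site rows (alt>depth or ref==alt)")
    for col in ("rna_ref", "rna_alt"):
        if not set(df[col]).issubset(_RNA_BASES):
            raise FormatError(f"{col} contains non-RNA bases")
    return df
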