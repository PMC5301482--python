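"""Cross-species conservation of editing sites via consensus coordinates.

Homologous CDS (grouped by shared gene name across species) are aligned with
a deterministic center-star multiple alignment (pairwise global
Needleman-Wunsch, match +1 / mismatch -1 / gap -2); sites from different
species are conserved when they fall in the same consensus column with the
same RNA-space substitution and the same orientation class.  The same column
map drives the paralog (e.g. NUMT) cross-check: a site on a copied sequence
is flagged when it translates through the pairwise alignment to an identical
site on the source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align

logger = logging.getLogger(__name__)


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


def pairwise_nw(a: str, b: str) -> tuple[str, str]:
    """Optimal global alignment of two sequences as gapped strings.

    The first optimal alignment reported is taken, which is deterministic
    for identical inputs.
    """
    aln = _aligner().align(a, b)[0]
    return str(aln[0]), str(aln[1])


@dataclass
class HomologGroup:
    group_id: str  # gene name shared across species, e.g. "cox3"
    members: list[tuple[str, str]]  # (species_id, cds_sequence)

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError(f"group {self.group_id} needs >= 2 members")
        for sp, seq in self.members:
            if not seq:
                raise ValueError(f"empty member {sp} in group {self.group_id}")


@dataclass
class ConsensusMap:
    group_id: str
    # per species: one entry per consensus column, a 1-based CDS offset or None
    columns: dict[str, list[int | None]] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.columns.values())))

    def column_of(self, species_id: str, cds_offset: int) -> int:
        """Consensus column index (0-based) of a member's CDS offset."""
        cols = self.columns[species_id]
        try:
            return cols.index(cds_offset)
        except ValueError:
            raise ValueError(
                f"cds_offset {cds_offset} of {species_id} outside map of {self.group_id}"
            ) from None


def align_group(group: HomologGroup) -> ConsensusMap:
    """Center-star MSA merged on the center member's coordinates.

    The center is the member with the maximal summed pairwise alignment score
    to all others (i.e. minimal summed distance), ties to the first listed.
    Member insertions relative to the center are placed flush left within
    their gap block.
    """
    aligner = _aligner()
    names = [sp for sp, _ in group.members]
    seqs = [seq for _, seq in group.members]
    n = len(seqs)
    if n == 2:
        center_idx = 0
    else:
        scores = [0.0] * n
        for i in range(n):
            for j in range(n):
                if i != j:
                    scores[i] += aligner.score(seqs[i], seqs[j])
        center_idx = max(range(n), key=lambda i: (scores[i], -i))
    center = seqs[center_idx]
    C = len(center)

    # pairwise alignments of each non-center member to the center
    pair: dict[int, tuple[str, str]] = {}
    # gaps_before[i]: gaps inserted before center char i (i == C -> trailing)
    master_gaps = [0] * (C + 1)
    for i in range(n):
        if i == center_idx:
            continue
        gc, gm = pairwise_nw(center, seqs[i])
        pair[i] = (gc, gm)
        ci = 0
        run = 0
        for ch in gc:
            if ch == "-":
                run += 1
            else:
                master_gaps[ci] = max(master_gaps[ci], run)
                run = 0
                ci += 1
        master_gaps[C] = max(master_gaps[C], run)

    def expand(gc: str, gm: str) -> list[int | None]:
        """Member offsets per master column given its pairwise alignment."""
        cols: list[int | None] = []
        off = 0  # member offset consumed (1-based output)
        ci = 0  # center chars consumed
        k = 0  # position in the pairwise alignment
        while ci <= C:
            # member chars aligned to gaps before center char ci
            block: list[int | None] = []
            while k < len(gc) and gc[k] == "-":
                off += 1
                block.append(off)
                k += 1
            block += [None] * (master_gaps[ci] - len(block))
            cols.extend(block)
            if ci < C:
                if gm[k] == "-":
                    cols.append(None)
                else:
                    off += 1
                    cols.append(off)
                k += 1
            ci += 1
        return cols

    columns: dict[str, list[int | None]] = {}
    # center row
    center_cols: list[int | None] = []
    for i in range(C + 1):
        center_cols.extend([None] * master_gaps[i])
        if i < C:
            center_cols.append(i + 1)
    columns[names[center_idx]] = center_cols
    for i in range(n):
        if i == center_idx:
            continue
        columns[names[i]] = expand(*pair[i])

    cmap = ConsensusMap(group_id=group.group_id, columns=columns)
    for (sp, seq), cols in zip(group.members, [columns[sp] for sp, _ in group.members]):
        assert sum(c is not None for c in cols) == len(seq)
    return cmap


@dataclass(frozen=True)
class ConservedCluster:
    group_id: str
    column: int  # 0-based consensus column
    rna_ref: str
    rna_alt: str
    orientation: str
    members: tuple[tuple[str, int], ...]  # (species_id, cds_offset), sorted

    @property
    def species(self) -> frozenset:
        return frozenset(sp for sp, _ in self.members)


def conserved_sites(
    per_species_sites: dict[str, list[dict]],
    consensus_maps: dict[str, ConsensusMap],
) -> list[ConservedCluster]:
    """Cluster CDS sites that share consensus column, editing type and orientation.

    Site records are dicts with species_id-independent fields: gene_id (the
    homolog group), cds_offset (1-based, spliced transcript), rna_ref,
    rna_alt, orientation ('sense'/'antisense').  Only groups present in
    ``consensus_maps`` participate; clusters require >= 2 species.
    """
    buckets: dict[tuple, list[tuple[str, int]]] = {}
    for species, sites in per_species_sites.items():
        for rec in sites:
            gid = rec["gene_id"]
            cmap = consensus_maps.get(gid)
            if cmap is None or species not in cmap.columns:
                continue
            col = cmap.column_of(species, rec["cds_offset"])
            key = (gid, col, rec["rna_ref"], rec["rna_alt"], rec["orientation"])
            buckets.setdefault(key, []).append((species, rec["cds_offset"]))
    clusters = []
    for (gid, col, ref, alt, orient), members in sorted(buckets.items()):
        if len({sp for sp, _ in members}) >= 2:
            clusters.append(
                ConservedCluster(gid, col, ref, alt, orient, tuple(sorted(members)))
            )
    return clusters


def conserved_sre(
    per_species_sre: dict[str, list[dict]],
    consensus_maps: dict[str, ConsensusMap],
) -> list[ConservedCluster]:
    """Conserved symmetrical-editing positions (keyed by the sense substitution)."""
    return conserved_sites(per_species_sre, consensus_maps)


def membership_counts(clusters: list[ConservedCluster]) -> dict[frozenset, int]:
    """How many clusters are shared by each species combination."""
    out: dict[frozenset, int] = {}
    for c in clusters:
        out[c.species] = out.get(c.species, 0) + 1
    return out


def crosscheck_paralog(
    sites_primary: list,
    sites_copy: list,
    primary_seq: str,
    copy_seq: str,
) -> list[tuple]:
    """Identical editing sites shared between a sequence and its paralogous copy.

    Sites are objects with position (1-based on their own sequence),
    strand_group, rna_ref and rna_alt.  A copy site is flagged iff the
    global alignment maps its position to a primary position with the
    identical base and an identical site exists there.  Sites aligned to a
    gap or at a diverged base are skipped (logged).
    """
    g_copy, g_prim = pairwise_nw(copy_seq, primary_seq)
    copy_to_primary: dict[int, int | None] = {}
    cpos = ppos = 0
    for a, b in zip(g_copy, g_prim):
        if a != "-":
            cpos += 1
        if b != "-":
            ppos += 1
        if a != "-":
            if b != "-" and a == b:
                copy_to_primary[cpos] = ppos
            else:
                copy_to_primary[cpos] = None  # gap or diverged base
    primary_index = {
        (s.position, s.strand_group, s.rna_ref, s.rna_alt): s for s in sites_primary
    }
    overlaps = []
    for s in sites_copy:
        mapped = copy_to_primary.get(s.position)
        if mapped is None:
            logger.warning(
                "copy site at %d not comparable (gap or diverged base): skipped",
                s.position,
            )
            continue
        hit = primary_index.get((mapped, s.strand_group, s.rna_ref, s.rna_alt))
        if hit is not None:
            overlaps.append((s, hit))
    return overlaps
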