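"""Symmetrical RNA editing: pairing per-strand calls and absence accounting.

A symmetrical RNA editing (SRE) event is a genomic position at which the
transcripts of BOTH strands are edited — canonically "C to U" on the sense
transcript seen together with "G to A" on the antisense transcript.  With
the strict mirror rule the reverse-group substitution must be the RNA-space
complement of the forward-group one; the looser reading (any co-edited
position) is kept behind ``require_mirror=False`` and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .calling import EditingSite, Pileup
from .mapping import Genome
from .simulate import rna_complement

PASSED = "passed"
COVERED_BUT_FAILED = "covered_but_failed"
NO_COVERAGE = "no_coverage"


@dataclass(frozen=True)
class SrePair:
    position: int
    forward_site: EditingSite
    reverse_site: EditingSite

    @property
    def is_mirror(self) -> bool:
        return (
            self.reverse_site.rna_ref == rna_complement(self.forward_site.rna_ref)
            and self.reverse_site.rna_alt == rna_complement(self.forward_site.rna_alt)
        )


def pair_sre(
    forward_sites: list[EditingSite],
    reverse_sites: list[EditingSite],
    require_mirror: bool = True,
) -> list[SrePair]:
    """Pair co-edited positions across the two strand groups.

    Duplicate calls at one (position, strand_group) are an error: the caller's
    multi-type filter guarantees at most one surviving call per column.
    """
    by_pos_f: dict[int, EditingSite] = {}
    for s in forward_sites:
        if s.position in by_pos_f:
            raise ValueError(f"duplicate forward call at position {s.position}")
        by_pos_f[s.position] = s
    by_pos_r: dict[int, EditingSite] = {}
    for s in reverse_sites:
        if s.position in by_pos_r:
            raise ValueError(f"duplicate reverse call at position {s.position}")
        by_pos_r[s.position] = s

    pairs = []
    for pos in sorted(set(by_pos_f) & set(by_pos_r)):
        pair = SrePair(pos, by_pos_f[pos], by_pos_r[pos])
        if not require_mirror or pair.is_mirror:
            pairs.append(pair)
    return pairs


def classify_absence(
    position: int,
    strand_group: str,
    sample_pileup: Pileup,
    genome: Genome,
    c_min: int = 5,
    f_min: float = 0.1,
    p_max: float = 0.05,
    error_rate: float = 0.01,
    min_alt: int = 3,
) -> str:
    """Why is a site (not) seen in a sample: passed / covered_but_failed / no_coverage."""
    from .calling import binomial_p, _BASES, _FREQ_EPS

    depth = sample_pileup.depth(position, strand_group)
    if depth == 0:
        return NO_COVERAGE
    ref = genome.seq[position - 1]
    if depth >= c_min and ref in _BASES:
        col = sample_pileup.counts[strand_group][position]
        for i, base in enumerate(_BASES):
            if base == ref or col[i] == 0:
                continue
            alt = int(col[i])
            if (
                alt >= min_alt
                and alt >= f_min * depth - _FREQ_EPS
                and binomial_p(alt, depth, error_rate / 3) <= p_max
            ):
                return PASSED
    return COVERED_BUT_FAILED


def venn_partition(site_sets_by_sample: dict[str, set]) -> dict[frozenset, int]:
    """Counts for every non-empty membership region of the sample Venn diagram."""
    regions: dict[frozenset, int] = {}
    samples = list(site_sets_by_sample)
    for r in range(1, len(samples) + 1):
        for combo in combinations(samples, r):
            regions[frozenset(combo)] = 0
    union = set().union(*site_sets_by_sample.values()) if site_sets_by_sample else set()
    for key in union:
        membership = frozenset(s for s, sites in site_sets_by_sample.items() if key in sites)
        regions[membership] += 1
    return regions
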