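from fractions import Fraction

import numpy as np
import pytest

from mito_sre import calling, mapping, simulate
from mito_sre.calling import (
    EditingSite,
    Pileup,
    SnpSite,
    build_pileup,
    call_editing_sites,
    call_snps,
    consensus_sites,
    exclude_snp_overlaps,
    pool_samples,
    snps_from_vcf,
)
from mito_sre.io_formats import VariantRow
from mito_sre.mapping import Genome, StrandedAlignment


def make_column_pileup(genome: Genome, position: int, strand_group: str,
                       counts: dict[str, int]) -> Pileup:
    """A pileup holding exactly one constructed column."""
    pile = Pileup(len(genome))
    for i, base in enumerate("ACGT"):
        pile.counts[strand_group][position, i] = counts.get(base, 0)
    return pile


def exact_binomial_tail(alt: int, depth: int, p: float) -> Fraction:
    """Independent oracle: exact summation of the binomial upper tail."""
    from math import comb

    pf = Fraction(p).limit_denominator(10**12)
    return sum(
        Fraction(comb(depth, j)) * pf**j * (1 - pf) ** (depth - j)
        for j in range(alt, depth + 1)
    )


@pytest.fixture(scope="module")
def flat_genome():
    return Genome("m", "ACGT" * 250)  # 1 kb, position p has base 'ACGT'[(p-1)%4]


def c_position(flat_genome):
    return 2  # 1-based position with reference C


class TestBuildPileup:
    def test_single_read_columns(self, flat_genome):
        aln = StrandedAlignment("r", 10, "F", "ACGT", 0)
        pile = build_pileup([aln], flat_genome)
        for off, base in enumerate("ACGT"):
            col = pile.column(10 + off, "F")
            assert col.depth == 1 and col.counts == {base: 1}
        assert pile.depth(14, "F") == 0 and pile.depth(10, "R") == 0

    def test_disagreeing_reads(self, flat_genome):
        a = StrandedAlignment("r1", 10, "F", "ACCT", 0)
        b = StrandedAlignment("r2", 10, "F", "ACTT", 0)
        pile = build_pileup([a, b], flat_genome)
        assert pile.column(12, "F").counts == {"C": 1, "T": 1}

    def test_n_contributes_nothing(self, flat_genome):
        pile = build_pileup([StrandedAlignment("r", 10, "F", "ANGT", 0)], flat_genome)
        assert pile.depth(11, "F") == 0

    def test_out_of_bounds_rejected(self, flat_genome):
        with pytest.raises(ValueError, match="bounds"):
            build_pileup([StrandedAlignment("r", 999, "F", "ACGT", 0)], flat_genome)

    def test_depths_match_interval_stabbing_oracle(self, small_genome):
        seq, models = small_genome
        truth = simulate.GroundTruth(edits=[], snps=[])
        _, sam = simulate.simulate_reads(seq, models, truth, depth=3, seed=9)
        genome = Genome("mito", seq)
        alns = mapping.alignments_from_sam(sam)
        pile = build_pileup(alns, genome)
        # oracle: count reads stabbing each probed position per strand
        rng = np.random.default_rng(0)
        for pos in rng.integers(1, len(seq) + 1, size=60):
            for g, flag in (("F", 0), ("R", 16)):
                expect = sum(
                    1 for r in sam
                    if r.flag == flag and r.position <= pos < r.position + len(r.seq)
                    and "N" not in r.seq[pos - r.position]
                )
                assert pile.depth(int(pos), g) == expect


class TestCallEditingSites:
    def test_high_frequency_c_to_u(self, flat_genome):
        pile = make_column_pileup(flat_genome, 2, "F", {"C": 10, "T": 90})
        (site,) = call_editing_sites(pile, flat_genome)
        assert (site.rna_ref, site.rna_alt) == ("C", "U")
        assert site.frequency == pytest.approx(0.90)
        # binomial tail vs exact-summation oracle
        oracle = float(exact_binomial_tail(90, 100, 0.01 / 3))
        assert site.p_value == pytest.approx(oracle, abs=1e-12)
        assert site.p_value <= 0.05

    def test_depth_below_coverage_cutoff(self, flat_genome):
        pile = make_column_pileup(flat_genome, 2, "F", {"T": 4})
        assert call_editing_sites(pile, flat_genome) == []

    def test_low_frequency_alts_rejected(self, flat_genome):
        pile = make_column_pileup(flat_genome, 2, "F", {"C": 18, "T": 1, "A": 1})
        assert call_editing_sites(pile, flat_genome) == []

    def test_multi_type_column_discarded(self, flat_genome):
        pile = make_column_pileup(flat_genome, 2, "F", {"C": 5, "T": 8, "A": 7})
        assert call_editing_sites(pile, flat_genome) == []

    def test_reverse_group_reported_in_rna_space(self, flat_genome):
        # genome-space C→T on the reverse group is the antisense G→A event
        pile = make_column_pileup(flat_genome, 2, "R", {"C": 2, "T": 18})
        (site,) = call_editing_sites(pile, flat_genome)
        assert (site.strand_group, site.rna_ref, site.rna_alt) == ("R", "G", "A")

    def test_multi_type_exclusion_is_per_strand(self, flat_genome):
        pile = make_column_pileup(flat_genome, 2, "F", {"C": 5, "T": 8, "A": 7})
        for i, base in enumerate("ACGT"):
            pile.counts["R"][2, i] = {"C": 2, "T": 18}.get(base, 0)
        sites = call_editing_sites(pile, flat_genome)
        assert [s.strand_group for s in sites] == ["R"]

    def test_depth_exactly_at_cutoff_called(self, flat_genome):
        pile = make_column_pileup(flat_genome, 2, "F", {"C": 2, "T": 3})
        (site,) = call_editing_sites(pile, flat_genome)
        assert site.depth == 5 and site.alt_count == 3

    def test_frequency_exactly_at_cutoff_called(self, flat_genome):
        # 3/30 = 0.1 exactly: accepted (>=); 3/31 rejected
        pile = make_column_pileup(flat_genome, 2, "F", {"C": 27, "T": 3})
        (site,) = call_editing_sites(pile, flat_genome)
        assert site.frequency == pytest.approx(0.1)
        pile = make_column_pileup(flat_genome, 2, "F", {"C": 28, "T": 3})
        assert call_editing_sites(pile, flat_genome) == []

    def test_min_supporting_reads(self, flat_genome):
        pile = make_column_pileup(flat_genome, 2, "F", {"C": 3, "T": 2})
        assert call_editing_sites(pile, flat_genome) == []
        assert len(call_editing_sites(pile, flat_genome, min_alt=2)) == 1

    def test_binomial_p_matches_exact_summation_grid(self):
        # dense small grid; the acceptance suite covers depths up to 500
        for depth in (5, 17, 60):
            for alt in (1, 2, depth // 3, depth):
                p = calling.binomial_p(alt, depth, 0.01 / 3)
                oracle = float(exact_binomial_tail(alt, depth, 0.01 / 3))
                assert p == pytest.approx(oracle, abs=1e-12)


class TestConsensusSites:
    def test_majority_alt(self, flat_genome):
        pile = make_column_pileup(flat_genome, 2, "F", {"C": 3, "T": 7})
        (site,) = consensus_sites(pile, flat_genome)
        assert (site.rna_ref, site.rna_alt) == ("C", "U")

    def test_tie_gives_no_site(self, flat_genome):
        pile = make_column_pileup(flat_genome, 2, "F", {"C": 5, "T": 5})
        assert consensus_sites(pile, flat_genome) == []

    def test_majority_reference_gives_no_site(self, flat_genome):
        pile = make_column_pileup(flat_genome, 2, "F", {"C": 8, "T": 2})
        assert consensus_sites(pile, flat_genome) == []

    def test_matches_planted_truth_at_high_frequency(self, small_genome):
        # with no errors and planted frequencies >= 0.8 the consensus set
        # equals the planted set restricted to covered columns
        seq, models = small_genome
        truth = simulate.plant_events(
            seq, models, n_edits=25, sre_fraction=0.4, seed=21,
            freq_dist=lambda rng: float(rng.uniform(0.8, 1.0)),
        )
        reads, _ = simulate.simulate_reads(seq, models, truth, depth=40,
                                           error_rate=0.0, seed=22)
        genome = Genome("mito", seq)
        alns, _ = mapping.map_reads(reads, genome, 7)
        pile = build_pileup(alns, genome)
        got = {s.key for s in consensus_sites(pile, genome, c_min=5)}
        want = {
            e.key for e in truth.edits
            if pile.depth(e.position, e.strand_group) >= 5
        }
        assert got == want


class TestSnps:
    def test_high_quality_snp(self, flat_genome):
        pile = make_column_pileup(flat_genome, 2, "F", {"C": 20, "T": 20}).pooled()
        (snp,) = call_snps(pile, flat_genome)
        assert snp.high_quality and snp.allele_frequency == pytest.approx(0.5)

    def test_depth_below_ten_not_high_quality(self, flat_genome):
        pile = make_column_pileup(flat_genome, 2, "F", {"T": 9}).pooled()
        (snp,) = call_snps(pile, flat_genome)
        assert not snp.high_quality

    def test_vcf_indel_adopted(self):
        (snp,) = snps_from_vcf([VariantRow("m", 5, "ATT", "A", True, 30, 0.9)])
        assert snp.is_indel and snp.ref_span == (5, 7) and snp.high_quality


class TestExcludeSnpOverlaps:
    def _site(self, pos):
        return EditingSite("m", pos, "F", "C", "U", 20, 10, 0.5, 1e-6)

    def test_exact_position_excluded(self):
        kept, excl = exclude_snp_overlaps(
            [self._site(120)], [SnpSite(120, "C", "T", 40, 0.5)]
        )
        assert kept == [] and len(excl) == 1

    def test_adjacent_position_kept(self):
        kept, excl = exclude_snp_overlaps(
            [self._site(121)], [SnpSite(120, "C", "T", 40, 0.5)]
        )
        assert len(kept) == 1 and excl == []

    def test_site_inside_deletion_span_excluded(self):
        # REF spans 5..7; site at 6 falls inside
        indel = SnpSite(5, "ATT", "A", None, None, is_indel=True)
        kept, excl = exclude_snp_overlaps([self._site(6), self._site(8)], [indel])
        assert [s.position for s in excl] == [6]
        assert [s.position for s in kept] == [8]

    def test_low_quality_snps_do_not_exclude(self):
        kept, excl = exclude_snp_overlaps(
            [self._site(120)],
            [SnpSite(120, "C", "T", 9, 0.5, high_quality=False)],
        )
        assert len(kept) == 1 and excl == []


class TestPoolSamples:
    def _aln(self, i, contig="mito"):
        return StrandedAlignment(f"r{i}", 1, "F", "A", 0, contig=contig)

    def test_sizes_add(self):
        pooled = pool_samples(
            {"a": [self._aln(i) for i in range(3)],
             "b": [self._aln(i) for i in range(4)],
             "c": [self._aln(i) for i in range(5)]}
        )
        assert len(pooled) == 12
        assert {a.sample for a in pooled} == {"a", "b", "c"}

    def test_empty_sample_is_noop(self):
        assert len(pool_samples({"a": [], "b": [self._aln(1)]})) == 1

    def test_reference_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different references"):
            pool_samples({"a": [self._aln(1, "x")], "b": [self._aln(2, "y")]})

    def test_pileup_order_independent(self, flat_genome):
        a = [StrandedAlignment("r1", 10, "F", "ACGT", 0, contig="m")]
        b = [StrandedAlignment("r2", 12, "F", "GTAC", 0, contig="m")]
        p1 = build_pileup(pool_samples({"a": a, "b": b}), flat_genome)
        p2 = build_pileup(pool_samples({"b": b, "a": a}), flat_genome)
        assert (p1.counts["F"] == p2.counts["F"]).all()


class TestStrandConventionLaw:
    def test_reverse_only_transcription_gives_only_reverse_group_calls(self, small_genome):
        # antisense transcripts over genomic C positions edited C→T in genome
        # space read out exclusively as G→A in group R, never in group F
        seq, models = small_genome
        gene = next(m for m in models if m.kind == "protein_coding" and m.strand == "+")
        positions = [p for p in range(gene.start + 5, gene.start + 400)
                     if seq[p - 1] == "C"][:10]
        truth = simulate.GroundTruth(
            edits=[simulate.PlantedEdit(p, "R", "G", "A", 0.9) for p in positions],
            snps=[],
        )
        reads, _ = simulate.simulate_reads(
            seq, models, truth, depth=40, error_rate=0.0, seed=31,
            antisense_fraction=1.0, transcript_fraction=1.0,
        )
        genome = Genome("mito", seq)
        alns, _ = mapping.map_reads(reads, genome, 7)
        sites = call_editing_sites(build_pileup(alns, genome), genome)
        assert sites
        assert all(s.strand_group == "R" for s in sites)
        assert {(s.rna_ref, s.rna_alt) for s in sites} == {("G", "A")}
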