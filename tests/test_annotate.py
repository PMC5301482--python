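import numpy as np
import pytest
from Bio.Seq import Seq

from mito_sre import annotate, simulate
from mito_sre.annotate import (
    AnnotatedSite,
    annotate_sites,
    codon_effect,
    extract_upstream_windows,
    hydrophobicity_shift,
    locate_site,
    type_frequency_summary,
)
from mito_sre.calling import EditingSite
from mito_sre.io_formats import GeneModel
from mito_sre.mapping import Genome
from mito_sre.simulate import revcomp


def site(pos, group="F", ref="C", alt="U", freq=0.5):
    depth = 20
    return EditingSite("m", pos, group, ref, alt, depth, int(freq * depth), freq, 1e-8)


def gene_with_cds(cds: str, start: int, strand: str = "+", gene_id: str = "g1",
                  glen: int = 2000, rng=None) -> tuple[Genome, GeneModel]:
    """Embed a CDS (transcript orientation) into a random genome background."""
    rng = rng or np.random.default_rng(0)
    background = "".join(np.random.default_rng(1).choice(list("ACGT"), size=glen))
    region = cds if strand == "+" else revcomp(cds)
    seq = background[: start - 1] + region + background[start - 1 + len(region):]
    end = start + len(region) - 1
    model = GeneModel(gene_id, "m", strand, start, end,
                      cds=[(start, end)] if strand == "+" else [(start, end)])
    return Genome("m", seq), model


class TestLocateSite:
    @pytest.fixture()
    def setup(self):
        genome, gene = gene_with_cds("ATG" + "GCT" * 50 + "TAA", 501)
        return genome, [gene]

    def test_sense_cds(self, setup):
        genome, models = setup
        region, gene, orient = locate_site(site(520, "F"), models)
        assert (region, orient) == ("CDS", "sense") and gene.gene_id == "g1"

    def test_antisense_cds(self, setup):
        genome, models = setup
        region, gene, orient = locate_site(site(520, "R"), models)
        assert (region, orient) == ("CDS", "antisense")

    def test_intergenic_orientation_is_strand_group(self, setup):
        genome, models = setup
        assert locate_site(site(10, "F"), models)[::2] == ("intergenic", "forward")
        assert locate_site(site(10, "R"), models)[::2] == ("intergenic", "reverse")

    def test_overlapping_genes_rejected(self, setup):
        genome, models = setup
        clone = GeneModel("g2", "m", "+", models[0].start, models[0].end,
                          cds=list(models[0].cds))
        with pytest.raises(ValueError, match="overlap"):
            locate_site(site(520, "F"), models + [clone])

    def test_intron_and_partition(self, small_genome):
        # every (position, strand_group) maps to exactly one region
        seq, models = small_genome
        intron_genes = [m for m in models if m.introns]
        if intron_genes:
            g = intron_genes[0]
            s, e = g.introns[0]
            region, _, _ = locate_site(site(s + 1, "F"), models)
            assert region == "intron"
        rng = np.random.default_rng(4)
        for pos in rng.integers(1, len(seq) + 1, size=100):
            locate_site(site(int(pos), "F"), models)  # must not raise


class TestCodonEffect:
    def _run(self, ref_codon_rna, codon_position, alt="U"):
        # embed the codon as codon 2 of a short CDS
        cds = "ATG" + ref_codon_rna.replace("U", "T") + "GCTTAA"
        genome, gene = gene_with_cds(cds, 301)
        pos = 301 + 3 + (codon_position - 1)
        ref = ref_codon_rna[codon_position - 1]
        ann = AnnotatedSite(site=site(pos, "F", ref, alt), region="CDS",
                            gene_id="g1", orientation="sense")
        return codon_effect(ann, genome, gene)

    def test_ser_to_leu_missense(self):
        ann = self._run("UCA", 2)
        assert (ann.ref_codon, ann.alt_codon) == ("UCA", "UUA")
        assert (ann.ref_aa, ann.alt_aa) == ("S", "L")
        assert ann.effect == "missense"

    def test_silent_third_position(self):
        ann = self._run("UAC", 3)
        assert ann.alt_codon == "UAU" and ann.effect == "silent"

    def test_stop_gain(self):
        ann = self._run("CAA", 1)
        assert ann.alt_codon == "UAA" and ann.effect == "stop_gain"

    def test_start_gain_acg_to_aug(self):
        # an ACG first codon edited at position 2 becomes AUG
        cds = "ACG" + "GCT" * 3 + "TAA"
        genome, gene = gene_with_cds(cds, 401)
        ann = AnnotatedSite(site=site(402, "F", "C", "U"), region="CDS",
                            gene_id="g1", orientation="sense")
        ann = codon_effect(ann, genome, gene)
        assert ann.codon_index == 1 and ann.alt_codon == "AUG"
        assert ann.effect == "start_gain"

    def test_offset_invariant(self):
        ann = self._run("UCA", 2)
        assert ann.cds_offset == 3 * (ann.codon_index - 1) + ann.codon_position

    def test_minus_strand_gene(self):
        cds = "ATG" + "TCA" + "GCTTAA"  # codon 2 = UCA
        genome, gene = gene_with_cds(cds, 301, strand="-")
        # transcript offset 5 (codon 2, position 2) in genome coordinates
        pos = gene.genomic_position_of(5)
        ann = AnnotatedSite(site=site(pos, "R", "C", "U"), region="CDS",
                            gene_id="g1", orientation="sense")
        ann = codon_effect(ann, genome, gene)
        assert (ann.ref_codon, ann.alt_codon) == ("UCA", "UUA")
        assert ann.effect == "missense"

    def test_agrees_with_full_cds_mutate_translate_oracle(self):
        # all 64 codons x 3 positions where the reference base is C:
        # oracle mutates the entire CDS string, translates both, diffs
        bases = "ACGT"
        codons = [a + b + c for a in bases for b in bases for c in bases]
        checked = 0
        for codon in codons:
            for cp in (1, 2, 3):
                if codon[cp - 1] != "C":
                    continue
                cds = "ATG" + codon + "GCTTAA"
                if "TAA" in (cds[3:6],) or "TAG" in (cds[3:6],) or "TGA" in (cds[3:6],):
                    pass  # internal stops allowed for the comparison
                genome, gene = gene_with_cds(cds, 201)
                pos = 201 + 3 + (cp - 1)
                ann = AnnotatedSite(site=site(pos, "F", "C", "U"), region="CDS",
                                    gene_id="g1", orientation="sense")
                ann = codon_effect(ann, genome, gene)
                mutated = cds[: 3 + cp - 1] + "T" + cds[3 + cp:]
                aa_before = str(Seq(cds).translate())
                aa_after = str(Seq(mutated).translate())
                diffs = [i for i, (x, y) in enumerate(zip(aa_before, aa_after)) if x != y]
                if ann.effect == "silent":
                    assert diffs == []
                else:
                    assert diffs == [1]
                    assert aa_before[1] == ann.ref_aa
                    assert aa_after[1] == ann.alt_aa
                checked += 1
        assert checked == 48  # 16 codons with C at each of 3 positions


class TestHydrophobicity:
    def _ann(self, ref_aa, alt_aa):
        return AnnotatedSite(site=site(1), region="CDS", orientation="sense",
                             ref_aa=ref_aa, alt_aa=alt_aa)

    def test_ser_to_leu(self):
        assert hydrophobicity_shift([self._ann("S", "L")]) == (0.0, 100.0)

    def test_silent_tyr(self):
        assert hydrophobicity_shift([self._ann("Y", "Y")]) == (0.0, 0.0)

    def test_mixed(self):
        anns = [self._ann("P", "L"), self._ann("S", "S")]
        assert hydrophobicity_shift(anns) == (50.0, 50.0)

    def test_stops_excluded_from_denominator(self):
        anns = [self._ann("S", "*"), self._ann("S", "L")]
        before, after = hydrophobicity_shift(anns)
        assert before == 0.0 and after == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hydrophobicity_shift([])


class TestTypeFrequencySummary:
    def test_full_frequency_in_top_bin(self):
        counts, hist = type_frequency_summary([site(1, freq=1.0)])
        assert hist["91-100%"] == 1 and hist.sum() == 1

    def test_type_counts(self):
        sites = [site(1, "F", "C", "U"), site(2, "F", "C", "U"), site(3, "F", "G", "A")]
        counts, _ = type_frequency_summary(sites)
        assert counts.loc["C>U", "F"] == 2 and counts.loc["G>A", "F"] == 1
        assert counts.values.sum() == 3

    def test_bin_conservation_random(self, rng):
        sites = [site(i + 1, freq=float(f))
                 for i, f in enumerate(rng.uniform(0.01, 1.0, size=200))]
        counts, hist = type_frequency_summary(sites)
        assert hist.sum() == 200 and counts.values.sum() == 200

    def test_boundary_frequency_bins(self):
        _, hist = type_frequency_summary([site(1, freq=0.1), site(2, freq=0.101)])
        assert hist["1-10%"] == 1 and hist["11-20%"] == 1


class TestUpstreamWindows:
    @pytest.fixture()
    def genome(self):
        return Genome("m", "".join(np.random.default_rng(2).choice(list("ACGT"), size=400)))

    def _ann(self, pos, group):
        return AnnotatedSite(site=site(pos, group), region="CDS",
                             orientation="sense", site_name=f"s{pos}{group}")

    def test_forward_window(self, genome):
        ((name, seq),) = extract_upstream_windows([self._ann(100, "F")], genome)
        assert seq == genome.seq[74:100] and len(seq) == 26

    def test_reverse_window(self, genome):
        ((_, seq),) = extract_upstream_windows([self._ann(100, "R")], genome)
        assert seq == revcomp(genome.seq[99:125])

    def test_boundary_site_dropped(self, genome):
        assert extract_upstream_windows([self._ann(10, "F")], genome) == []

    def test_span_without_site_base(self, genome):
        ((_, seq),) = extract_upstream_windows(
            [self._ann(100, "F")], genome, include_site=False
        )
        assert len(seq) == 25 and seq == genome.seq[74:99]


class TestAnnotateSites:
    def test_names_and_effects_on_synthetic_genome(self, small_genome):
        seq, models = small_genome
        genome = Genome("mito", seq)
        truth = simulate.plant_events(seq, models, n_edits=40, sre_fraction=0.5, seed=12)
        sites = [
            EditingSite("mito", e.position, e.strand_group, e.rna_ref, e.rna_alt,
                        30, 15, 0.5, 1e-9)
            for e in truth.edits
        ]
        annotated = annotate_sites(sites, genome, models)
        assert len(annotated) == len(sites)
        cds_sense = [a for a in annotated if a.region == "CDS" and a.orientation == "sense"]
        assert cds_sense
        for a in cds_sense:
            assert a.site_name == f"{a.gene_id}-{a.cds_offset}"
            assert a.cds_offset == 3 * (a.codon_index - 1) + a.codon_position
            assert a.effect in {"silent", "missense", "start_gain", "stop_gain", "stop_loss"}
        # SRE partners on the antisense strand share the genomic position
        antisense = [a for a in annotated if a.orientation == "antisense"]
        assert antisense
        for a in antisense:
            assert a.effect == "noncoding"
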