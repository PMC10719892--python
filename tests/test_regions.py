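"""Genome model: promoters, flanking assignment, region-class annotation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from introchron.regions import (
    GeneModel,
    GenomicInterval,
    RegulatoryElement,
    VariantSite,
    annotate_variants,
    assign_flanking_elements,
    build_promoter,
)


def gene(gene_id="G1", chrom="chr1", start=90_000, end=160_000, strand="+", tss=None):
    if tss is None:
        tss = start if strand == "+" else end
    return GeneModel(gene_id, gene_id, GenomicInterval(chrom, start, end, strand), tss, strand)


class TestIntervals:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)

    def test_variant_alleles_validated(self):
        with pytest.raises(ValueError):
            VariantSite("chr1", 10, "A", "A")
        with pytest.raises(ValueError):
            VariantSite("chr1", 10, "A", "G", ancestral_allele="C")

    def test_vcf_position_conversion(self):
        v = VariantSite.from_vcf("chr1", 100, "A", "G")
        assert v.pos == 99


class TestPromoter:
    def test_plus_strand_window(self):
        g = gene(start=95_000, end=160_000, strand="+", tss=100_000)
        p = build_promoter(g)
        assert (p.start, p.end) == (95_000, 101_000)

    def test_minus_strand_window_is_mirror(self):
        g = gene(start=40_000, end=100_000, strand="-", tss=100_000)
        p = build_promoter(g)
        assert (p.start, p.end) == (99_000, 105_000)

    def test_degenerate_zero_window(self):
        g = gene(strand="+", tss=90_000)
        p = build_promoter(g, upstream_bp=0, downstream_bp=0)
        assert (p.start, p.end) == (90_000, 90_000)
        assert p.length == 0

    def test_clipped_at_origin(self):
        g = gene(start=2_000, end=30_000, strand="+", tss=2_000)
        p = build_promoter(g)
        assert p.start == 0

    @given(up=st.integers(0, 10_000), down=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_length_is_window_sum_without_clipping(self, up, down):
        g = gene(start=50_000, end=120_000, strand="+", tss=50_000)
        assert build_promoter(g, up, down).length == up + down


class TestFlanking:
    def test_within_window_assigned(self):
        g = gene(start=1_000_000, end=1_100_000)
        el = RegulatoryElement("E1", GenomicInterval("chr1", 1_900_000, 1_900_100))
        assert assign_flanking_elements([g], [el])["G1"] == [el]

    def test_overlapping_element_distance_zero(self):
        g = gene(start=1_000_000, end=1_100_000)
        el = RegulatoryElement("E1", GenomicInterval("chr1", 1_050_000, 1_050_300))
        assert assign_flanking_elements([g], [el])["G1"] == [el]

    def test_just_beyond_window_excluded(self):
        g = gene(start=1_000_000, end=1_100_000)
        el = RegulatoryElement("E1", GenomicInterval("chr1", 2_100_001, 2_100_101))
        assert assign_flanking_elements([g], [el])["G1"] == []

    def test_boundary_inclusive(self):
        g = gene(start=1_000_000, end=1_100_000)
        el = RegulatoryElement("E1", GenomicInterval("chr1", 2_100_000, 2_100_100))
        assert assign_flanking_elements([g], [el])["G1"] == [el]

    def test_empty_inputs(self):
        assert assign_flanking_elements([], []) == {}


class TestAnnotation:
    def setup_method(self):
        self.gene = gene(start=100_000, end=160_000, strand="+", tss=100_000)
        self.promoters = {"G1": build_promoter(self.gene)}
        self.element = RegulatoryElement("E1", GenomicInterval("chr1", 500_000, 500_300))
        self.inside_el = RegulatoryElement("E2", GenomicInterval("chr1", 120_000, 130_000))
        self.flanking = {"G1": [self.element, self.inside_el]}

    def annotate(self, variants):
        return annotate_variants(variants, [self.gene], self.promoters, self.flanking)

    def test_gene_body_beats_overlapping_element(self):
        v = VariantSite("chr1", 125_000, "A", "G")
        assert self.annotate([v]).region_class(v) == "gene_body"

    def test_promoter_only(self):
        v = VariantSite("chr1", 96_000, "A", "G")
        assert self.annotate([v]).region_class(v) == "promoter"

    def test_distal_element_within_1mb(self):
        v = VariantSite("chr1", 500_100, "A", "G")
        ann = self.annotate([v])
        assert ann.region_class(v) == "distal_regulatory"
        assert ann.genes(v) == {"G1"}

    def test_unknown_chromosome_is_none(self):
        v = VariantSite("chrX", 125_000, "A", "G")
        assert self.annotate([v]).region_class(v) == "none"

    def test_order_independent(self):
        vs = [
            VariantSite("chr1", p, "A", "G")
            for p in (96_000, 125_000, 500_100, 90_000, 200_000)
        ]
        fwd = self.annotate(vs)
        rev = self.annotate(list(reversed(vs)))
        for v in vs:
            assert fwd.region_class(v) == rev.region_class(v)

    def test_membership_matches_brute_force_scan(self, rng):
        genes = []
        cursor = 10_000
        for i in range(40):
            ln = int(rng.integers(5_000, 30_000))
            genes.append(gene(f"G{i}", "chr1", cursor, cursor + ln))
            cursor += ln + int(rng.integers(1_000, 20_000))
        promoters = {g.gene_id: build_promoter(g) for g in genes}
        elements = [
            RegulatoryElement(
                f"E{i}",
                GenomicInterval("chr1", int(p), int(p) + 300),
            )
            for i, p in enumerate(rng.integers(0, cursor, size=100))
        ]
        flanking = assign_flanking_elements(genes, elements)
        variants = [
            VariantSite("chr1", int(p), "A", "G")
            for p in rng.integers(0, cursor, size=500)
        ]
        ann = annotate_variants(variants, genes, promoters, flanking)
        flank_spans = [el.span for els in flanking.values() for el in els]
        for v in variants:
            if any(g.body.contains(v.chrom, v.pos) for g in genes):
                expected = "gene_body"
            elif any(p.contains(v.chrom, v.pos) for p in promoters.values()):
                expected = "promoter"
            elif any(s.contains(v.chrom, v.pos) for s in flank_spans):
                expected = "distal_regulatory"
            else:
                expected = "none"
            assert ann.region_class(v) == expected
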