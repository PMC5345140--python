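import dataclasses

import pytest

from cryptmeth.chip_annotation import (
    CATEGORIES,
    ElementWindows,
    annotate_peak,
    annotate_peaks,
    element_distribution,
    intersect_gene_list,
    tss_offset,
)
from cryptmeth.io_formats import ChIPPeak, GeneModel
from cryptmeth.synthetic_data import simulate_chip_peaks


def peak_at(summit, chrom="chr1", width=200, label=""):
    return ChIPPeak(chrom, summit - width // 2, summit + width // 2, summit,
                    group_label=label)


GENE_PLUS = GeneModel("gP", "chr1", "+", 1_000_000, 1_000_000, 1_020_000,
                      exons=((1_000_000, 1_000_300), (1_002_800, 1_003_200),
                             (1_019_000, 1_020_000)))
GENE_MINUS = GeneModel("gM", "chr2", "-", 1_000_000, 980_000, 1_000_001)


class TestTssOffset:
    def test_plus_strand_downstream(self):
        assert tss_offset(peak_at(1_003_011), GENE_PLUS) == 3011

    def test_minus_strand_upstream(self):
        assert tss_offset(peak_at(1_020_391, chrom="chr2"), GENE_MINUS) == -20_391

    def test_summit_at_tss(self):
        assert tss_offset(peak_at(1_000_000), GENE_PLUS) == 0


class TestAnnotatePeak:
    def test_exonic_summit_with_and_without_exon_context(self):
        peak = peak_at(1_003_011)
        ann = annotate_peak(peak, [GENE_PLUS])
        assert (ann.category, ann.gene_id, ann.tss_offset) == ("exon", "gP", 3011)
        stripped = dataclasses.replace(GENE_PLUS, exons=())
        ann2 = annotate_peak(peak, [stripped])
        assert ann2.category == "intron"

    def test_extended_enhancer_beyond_50kb(self):
        # -95,988 of a gene with nothing else nearby: extended enhancer only
        peak = peak_at(1_000_000 - 95_988)
        ann = annotate_peak(peak, [GENE_PLUS])
        assert ann.category == "extended_enhancer"
        assert ann.tss_offset == -95_988

    def test_upstream_enhancer_within_50kb(self):
        peak = peak_at(1_000_000 - 16_676)
        ann = annotate_peak(peak, [GENE_PLUS])
        assert (ann.category, ann.tss_offset) == ("enhancer", -16_676)

    def test_far_summit_is_intergenic(self):
        ann = annotate_peak(peak_at(5_000_000), [GENE_PLUS])
        assert (ann.category, ann.gene_id, ann.tss_offset) == ("intergenic", None, None)

    def test_promoter_takes_precedence_over_exon(self):
        ann = annotate_peak(peak_at(1_000_100), [GENE_PLUS])
        assert ann.category == "promoter"

    def test_nearest_tss_breaks_ties(self):
        other = GeneModel("far", "chr1", "+", 1_030_000, 1_030_000, 1_040_000)
        peak = peak_at(1_000_000 - 10_000)
        ann = annotate_peak(peak, [GENE_PLUS, other])
        assert ann.gene_id == "gP"

    def test_translation_invariance(self):
        shift = 7_654_321
        moved_gene = dataclasses.replace(
            GENE_PLUS,
            tss=GENE_PLUS.tss + shift,
            gene_start=GENE_PLUS.gene_start + shift,
            gene_end=GENE_PLUS.gene_end + shift,
            exons=tuple((s + shift, e + shift) for s, e in GENE_PLUS.exons),
        )
        for offset in (-95_988, -16_676, 100, 3011, 500_000):
            a = annotate_peak(peak_at(1_000_000 + offset), [GENE_PLUS])
            b = annotate_peak(peak_at(1_000_000 + shift + offset), [moved_gene])
            assert (a.category, a.tss_offset) == (b.category, b.tss_offset)

    def test_strand_flip_preserves_oriented_offsets(self):
        # mirror the whole locus around the TSS: categories and offsets persist
        tss = 1_000_000
        flipped = GeneModel(
            "gP", "chr1", "-",
            tss=tss,
            gene_start=tss - (GENE_PLUS.gene_end - 1 - tss),
            gene_end=tss + 1,
            exons=tuple(
                sorted((2 * tss - (e - 1), 2 * tss - s + 1) for s, e in GENE_PLUS.exons)
            ),
        )
        for offset in (-95_988, -16_676, 3011):
            a = annotate_peak(peak_at(tss + offset), [GENE_PLUS])
            b = annotate_peak(peak_at(tss - offset), [flipped])
            assert (a.category, a.tss_offset) == (b.category, b.tss_offset)

    def test_enhancer_equals_extended_in_the_window_limit(self):
        wide = ElementWindows(enhancer_upstream=100_000)
        for offset in (-95_988, -60_000, -16_676):
            ann = annotate_peak(peak_at(1_000_000 + offset), [GENE_PLUS], wide)
            assert ann.category == "enhancer"


class TestDistributionsAndLists:
    def test_every_peak_in_exactly_one_category(self):
        peaks = [peak_at(1_000_000 + off) for off in
                 (-95_988, -30_000, 100, 3011, 10_000, 800_000)]
        annotations = annotate_peaks(peaks, [GENE_PLUS])
        dist = element_distribution(annotations)
        assert dist["count"].sum() == len(peaks)
        assert dist["percent"].sum() == pytest.approx(100.0)
        assert list(dist["category"]) == list(CATEGORIES)

    def test_empty_annotations(self):
        assert element_distribution([]).empty

    def test_gene_list_intersection_returns_only_planted_genes(self):
        genes = [
            GeneModel("Wnt4", "chr4", "+", 500_000, 500_000, 520_000),
            GeneModel("Cdk1", "chr10", "+", 2_000_000, 2_000_000, 2_016_000),
            GeneModel("Other", "chr7", "+", 3_000_000, 3_000_000, 3_010_000),
        ]
        peaks = simulate_chip_peaks(
            genes, {"Wnt4": -16_676, "Cdk1": -95_988, "Other": -1_000}, n_decoys=3
        )
        annotations = annotate_peaks(peaks, genes)
        table = intersect_gene_list(annotations, ["Wnt4", "Cdk1"])
        assert list(table["gene"]) == ["Wnt4", "Cdk1"]  # sorted by |offset|
        assert list(table["tss_offset"]) == [-16_676, -95_988]

    def test_empty_gene_list(self):
        annotations = annotate_peaks([peak_at(1_000_100)], [GENE_PLUS])
        assert intersect_gene_list(annotations, []).empty
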