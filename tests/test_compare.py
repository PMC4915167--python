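"""Cross-trait region intersection, Venn counting and gene annotation."""
import numpy as np
import pytest

import bayesqtl as bq
from bayesqtl import datasets
from bayesqtl.containers import GeneInterval, QTLRegion


def region(chrom, start_mb, end_mb, peak_mb=None, logbf=13.0):
    peak_mb = peak_mb if peak_mb is not None else (start_mb + end_mb) / 2
    return QTLRegion(
        chromosome=str(chrom),
        start_bp=int(round(start_mb * 1e6)),
        end_bp=int(round(end_mb * 1e6)),
        peak_bp=int(round(peak_mb * 1e6)),
        peak_logbf=logbf,
        evidence_class=bq.classify_evidence(logbf),
    )


class TestCommonRegions:
    def test_chr6_suckling_intersection_matches_reported(self):
        """US [88.485, 88.959] x MY [88.485, 89.223] on chromosome 6 gives the
        reported common interval [88.485, 88.959]."""
        us = datasets.load_major_qtl_regions("US")
        my = datasets.load_major_qtl_regions("MY")
        commons = bq.common_regions(us, my, traits=("US", "MY"))
        chr6 = [c for c in commons if c.chromosome == "6"]
        assert len(chr6) == 1
        assert chr6[0].start_bp == 88_485_000
        assert chr6[0].end_bp == 88_959_000
        assert chr6[0].peak_bp_by_trait == {"US": 88_922_396, "MY": 88_919_352}

    def test_disjoint_intervals_yield_nothing(self):
        a = [region(1, 10.0, 11.0)]
        b = [region(1, 12.0, 13.0)]
        assert bq.common_regions(a, b) == []

    def test_self_intersection_is_identity(self):
        regs = [region(1, 10.0, 11.0), region(2, 5.0, 6.5)]
        commons = bq.common_regions(regs, regs)
        assert [(c.chromosome, c.start_bp, c.end_bp) for c in commons] == [
            (r.chromosome, r.start_bp, r.end_bp) for r in regs
        ]

    def test_shared_boundary_counts_as_overlap(self):
        a = [region(1, 10.0, 11.0)]
        b = [region(1, 11.0, 12.0)]
        commons = bq.common_regions(a, b)
        assert len(commons) == 1
        assert commons[0].start_bp == commons[0].end_bp == 11_000_000

    def test_one_region_overlapping_two_gives_two_records(self):
        a = [region(1, 10.0, 20.0)]
        b = [region(1, 11.0, 12.0), region(1, 15.0, 16.0)]
        assert len(bq.common_regions(a, b)) == 2

    def test_commutative_and_bounded_width(self):
        rng = np.random.default_rng(30)
        a = [region(1, s, s + w) for s, w in zip(rng.uniform(0, 50, 8),
                                                 rng.uniform(0.1, 3, 8))]
        b = [region(1, s, s + w) for s, w in zip(rng.uniform(0, 50, 8),
                                                 rng.uniform(0.1, 3, 8))]
        ab = bq.common_regions(a, b, traits=("A", "B"))
        ba = bq.common_regions(b, a, traits=("B", "A"))
        assert {(c.start_bp, c.end_bp) for c in ab} == {
            (c.start_bp, c.end_bp) for c in ba
        }
        max_input = max(r.width_bp for r in a + b)
        for c in ab:
            assert c.end_bp - c.start_bp <= max_input
        if ab:
            avg_common = np.mean([c.end_bp - c.start_bp for c in ab])
            avg_input = np.mean([r.width_bp for r in a + b])
            assert avg_common <= avg_input

    def test_putative_regions_excluded_at_default_class(self):
        a = [region(1, 10.0, 11.0, logbf=7.0)]  # putative only
        b = [region(1, 10.5, 11.5, logbf=13.0)]
        assert bq.common_regions(a, b) == []
        assert len(bq.common_regions(a, b, min_class="putative")) == 1


class TestVennCounts:
    def test_empty_inputs(self):
        counts = bq.venn_counts({"A": [], "B": [], "C": []}, reference="A")
        assert counts["reference"] == 0
        assert counts["none"] == 0

    def test_pairwise_overlap_only(self):
        counts = bq.venn_counts(
            {
                "A": [region(1, 1.0, 2.0)],
                "B": [region(1, 1.5, 3.0)],
                "C": [],
            },
            reference="A",
        )
        assert counts["with_B"] == 1
        assert counts["with_both"] == 0
        assert counts["none"] == 0

    def test_identical_region_everywhere_counts_triple(self):
        r = [region(1, 1.0, 2.0)]
        counts = bq.venn_counts({"A": r, "B": r, "C": r}, reference="A")
        assert counts["with_both"] == 1
        assert counts["with_B"] == counts["with_C"] == 0

    def test_cells_sum_to_reference_total(self):
        rng = np.random.default_rng(31)

        def rand_regions(k):
            return [
                region(int(rng.integers(1, 4)), s, s + w)
                for s, w in zip(rng.uniform(0, 30, k), rng.uniform(0.2, 2, k))
            ]

        by_trait = {"A": rand_regions(6), "B": rand_regions(5), "C": rand_regions(4)}
        counts = bq.venn_counts(by_trait, reference="A")
        assert (
            counts["none"] + counts["with_B"] + counts["with_C"] + counts["with_both"]
            == counts["reference"]
        )

    def test_requires_three_traits(self):
        with pytest.raises(ValueError):
            bq.venn_counts({"A": [], "B": []})


class TestAnnotateGenes:
    def test_gc_gene_overlaps_chr6_suckling_region(self):
        """The GC gene at [88.695940, 88.739180] Mb falls inside the
        chromosome-6 udder-swelling QTL region [88.485, 88.959] Mb."""
        us_chr6 = [r for r in datasets.load_major_qtl_regions("US")
                   if r.chromosome == "6"]
        genes = datasets.load_candidate_genes()
        records = bq.annotate_genes(us_chr6, genes)
        assert "GC" in records[0]["overlapping_genes"]

    def test_no_same_chromosome_genes_gives_empty_annotation(self):
        records = bq.annotate_genes(
            [region(9, 10.0, 11.0)], datasets.load_candidate_genes()
        )
        assert records[0]["overlapping_genes"] == []
        assert records[0]["nearest_gene"] is None

    def test_nearest_gene_distance(self):
        """Region [10, 11] Mb with genes at [8, 9.5] and [11.2, 12]: nearest
        is the downstream gene at 0.200 Mb."""
        genes = [
            GeneInterval("g_left", "1", int(8.0e6), int(9.5e6)),
            GeneInterval("g_right", "1", int(11.2e6), int(12.0e6)),
        ]
        rec = bq.annotate_genes([region(1, 10.0, 11.0)], genes)[0]
        assert rec["overlapping_genes"] == []
        assert rec["nearest_gene"] == "g_right"
        assert rec["nearest_distance_mb"] == pytest.approx(0.200)


class TestPeakDistance:
    def test_reported_chr6_dual_peak_distance(self):
        """The two suckling peaks at 88.745 and 88.922 Mb are 0.177 Mb apart."""
        a, b = datasets.SUCKLING_CHR6_DUAL_PEAKS_MB
        assert bq.peak_distance("6", a * 1e6, "6", b * 1e6) == pytest.approx(0.177)

    def test_symmetric_and_zero_on_identity(self):
        assert bq.peak_distance("1", 5e6, "1", 7e6) == bq.peak_distance("1", 7e6, "1", 5e6)
        assert bq.peak_distance("1", 5e6, "1", 5e6) == 0.0

    def test_different_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            bq.peak_distance("1", 5e6, "2", 5e6)


class TestReportedTables:
    def test_reported_common_regions_reproduced_from_major_qtl(self):
        """For trait pairs whose major QTL appear in the shipped major-QTL
        table, intersecting them reproduces the reported common intervals
        (the chromosome-6 suckling rows)."""
        table = datasets.load_common_region_table()
        majors = {t: datasets.load_major_qtl_regions(t) for t in ("US", "MY", "WWm")}
        row = table[(table.trait_1 == "US") & (table.trait_2 == "MY")
                    & (table.chrom == "6")].iloc[0]
        commons = bq.common_regions(majors["US"], majors["MY"], traits=("US", "MY"))
        chr6 = [c for c in commons if c.chromosome == "6"][0]
        assert chr6.start_bp == int(round(row.start_mb * 1e6))
        assert chr6.end_bp == int(round(row.end_mb * 1e6))

    def test_chr27_calving_peaks_are_close(self):
        """The calving-score peaks on chromosome 27 lie within 0.025 Mb."""
        table = datasets.load_common_region_table()
        row = table[(table.chrom == "27")].iloc[0]
        d = bq.peak_distance("27", row.peak_mb_1 * 1e6, "27", row.peak_mb_2 * 1e6)
        assert d < 0.025
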