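import numpy as np
import pytest
from scipy import stats as sps

from equicnv import (
    GeneInterval,
    annotate_genic,
    build_genome,
    chromosome_enrichment,
    cohort_summary,
    consolidate_calls,
    enrichment_percent,
    flag_subtelomeric,
    summarize_call_counts,
    tissue_comparison,
)
from equicnv import published

from test_regions import make_call


def region(chrom, start, end, sample="s1", direction="loss"):
    [r] = consolidate_calls([make_call(sample, chrom, start, end, direction)])
    return r


class TestGenicAnnotation:
    def test_one_base_overlap_is_genic(self):
        r = region("chr1", 100, 200)
        annotate_genic([r], [GeneInterval("G1", "chr1", 150, 400)])
        assert r.genic is True and r.gene_ids == ("G1",)

    def test_no_shared_base_is_intergenic(self):
        r = region("chr1", 100, 200)
        annotate_genic([r], [GeneInterval("G1", "chr1", 201, 400)])
        assert r.genic is False and r.gene_ids == ()

    def test_no_genes_means_all_intergenic(self):
        rs = [region("chr1", 100, 200), region("chr2", 1, 50)]
        annotate_genic(rs, [])
        assert all(r.genic is False for r in rs)

    def test_gene_on_unknown_chromosome_warns_and_skips(self, toy_genome):
        r = region("chr1", 100, 200)
        with pytest.warns(UserWarning, match="chrZZ"):
            annotate_genic([r], [GeneInterval("G", "chrZZ", 1, 500)], genome=toy_genome)
        assert r.genic is False

    def test_order_independent_and_counts_partition(self, toy_genome):
        rng = np.random.default_rng(3)
        regions = [
            region("chr1", int(s), int(s) + 500, sample=f"s{i}")
            for i, s in enumerate(rng.integers(1, 9_000_000, size=15))
        ]
        genes = [
            GeneInterval(f"g{i}", "chr1", int(s), int(s) + 2_000)
            for i, s in enumerate(rng.integers(1, 9_000_000, size=30))
        ]
        annotate_genic(regions, genes)
        first = [(r.genic, r.gene_ids) for r in regions]
        annotate_genic(regions, genes[::-1])
        assert [(r.genic, r.gene_ids) for r in regions] == first
        n_genic = sum(r.genic for r in regions)
        n_inter = sum(not r.genic for r in regions)
        assert n_genic + n_inter == len(regions)


class TestSubtelomeres:
    def test_head_window_flagged(self):
        g = build_genome(spec=[("chr1", 50_000_000)])
        r = region("chr1", 200_000, 400_000)
        flag_subtelomeric([r], g)
        assert r.subtelomeric is True

    def test_interior_not_flagged(self):
        g = build_genome(spec=[("chr1", 50_000_000)])
        r = region("chr1", 25_000_000, 26_000_000)
        flag_subtelomeric([r], g)
        assert r.subtelomeric is False

    def test_tail_window_flagged(self):
        g = build_genome(spec=[("chr1", 50_000_000)])
        r = region("chr1", 49_500_000, 49_800_000)
        flag_subtelomeric([r], g)
        assert r.subtelomeric is True

    def test_single_end_option_ignores_head(self):
        g = build_genome(spec=[("chr1", 50_000_000)])
        head = region("chr1", 200_000, 400_000)
        tail = region("chr1", 49_500_000, 49_800_000)
        flag_subtelomeric([head, tail], g, both_ends=False)
        assert head.subtelomeric is False and tail.subtelomeric is True


class TestEnrichment:
    def test_published_chromosome_values(self):
        # recompute the printed per-chromosome enrichment from the length columns
        assert round(enrichment_percent(3_231_871, 33_091_231), 2) == 9.77
        assert round(enrichment_percent(5_078_379, 185_838_109), 2) == 2.73

    def test_every_published_row_reproduces_to_2dp(self):
        df = published.chromosome_cnvr_frame()
        expected = {
            "chr1": 2.73, "chr2": 0.75, "chr3": 0.94, "chr4": 0.99, "chr5": 0.42,
            "chr6": 2.68, "chr7": 1.45, "chr8": 1.63, "chr9": 0.77, "chr10": 1.39,
            "chr11": 0.02, "chr12": 9.77, "chr13": 0.28, "chr14": 0.47, "chr15": 0.18,
            "chr16": 0.26, "chr17": 0.75, "chr18": 0.58, "chr19": 0.70, "chr20": 3.04,
            "chr21": 0.80, "chr22": 0.39, "chr23": 1.76, "chr24": 0.90, "chr25": 0.35,
            "chr26": 1.52, "chr27": 0.08, "chr28": 0.33, "chr29": 2.23, "chr30": 0.90,
            "chr31": 0.27, "chrX": 0.84, "chrUn": 0.04,
        }
        for row in df.itertuples(index=False):
            got = round(enrichment_percent(row.cnvr_length, row.chrom_length), 2)
            assert got == expected[row.chromosome], row.chromosome

    def test_zero_cnvrs_gives_zero_enrichment(self, toy_genome):
        df = chromosome_enrichment([], toy_genome)
        assert (df.enrichment_percent == 0).all()
        assert list(df.chromosome) == list(toy_genome.names)

    def test_genome_enrichment_is_length_weighted_mean(self, toy_genome):
        regions = [region("chr1", 1, 1_000_000), region("chr2", 1, 250_000)]
        df = chromosome_enrichment(regions, toy_genome)
        weighted = np.average(df.enrichment_percent, weights=df.chrom_length)
        total = enrichment_percent(1_250_000, toy_genome.total_length)
        assert weighted == pytest.approx(total)


class TestCohortSummary:
    def test_published_call_count_statistics(self):
        per = published.individual_calls_frame()
        s = summarize_call_counts(per)
        assert round(s["mean_calls"], 1) == 26.4
        assert s["median_calls"] == 22.5
        assert round(s["mean_gains"], 1) == 7.3
        assert round(s["mean_losses"], 1) == 19.1
        assert s["median_gains"] == 7.5
        assert s["median_losses"] == 17.0

    def test_single_call_degenerate_summary(self, toy_genome):
        calls = [make_call("s1", "chr1", 100, 1099)]
        cnvrs = consolidate_calls(calls, genome=toy_genome)
        cs = cohort_summary(calls, cnvrs, toy_genome)
        assert cs.mean_cnvr_size == cs.median_cnvr_size == 1000
        assert cs.mean_calls == 1 and cs.mean_losses == 1 and cs.mean_gains == 0

    def test_empty_inputs_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            cohort_summary([], [], toy_genome)


class TestTissueComparison:
    def test_identical_groups_t_zero_p_one(self):
        t, p = tissue_comparison([1, 2, 3, 1, 2, 3],
                                 ["blood"] * 3 + ["hair"] * 3)
        assert t == 0 and p == pytest.approx(1.0)

    def test_matches_textbook_pooled_t(self):
        a, b = [10.0, 12.0, 14.0], [20.0, 22.0, 24.0]
        t, p = tissue_comparison(a + b, ["blood"] * 3 + ["hair"] * 3)
        # hand computation: pooled variance = 4, se = 2*sqrt(2/3), t = -10/se
        se = 2 * np.sqrt(2 / 3)
        expected_t = (np.mean(a) - np.mean(b)) / se
        assert t == pytest.approx(expected_t)
        assert p == pytest.approx(2 * sps.t.sf(abs(expected_t), df=4))

    def test_third_tissue_excluded(self):
        t_all, _ = tissue_comparison(
            [1, 2, 3, 4, 100, 200],
            ["blood", "blood", "hair", "hair", "fibroblast", "fibroblast"],
        )
        t_two, _ = tissue_comparison([1, 2, 3, 4], ["blood", "blood", "hair", "hair"])
        assert t_all == t_two

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            tissue_comparison([1, 2, 3], ["blood", "blood", "hair"])
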