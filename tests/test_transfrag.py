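"""Probe statistics, transfrag segmentation rules, merging, annotation
filtering, orientation classes and cross-condition unions."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nucshift as ns
from nucshift.transfrag import Transfrag, probe_stats_expression


def stats_frame(fc, p=None, start=1001, step=4, strand="+", chrom="chr1"):
    fc = np.asarray(fc, float)
    p = np.full(len(fc), 0.01) if p is None else np.asarray(p, float)
    pos = np.arange(start, start + step * len(fc), step)
    return pd.DataFrame({"chrom": chrom, "pos": pos, "strand": strand,
                         "log2_fc": fc, "p": p})


class TestRankSum:
    def test_complete_separation_matches_exact_enumeration(self):
        # n = m = 7, all treatment above all control: p = 2 / C(14, 7)
        p = ns.rank_sum_p(np.full(7, 8.0), np.full(7, 2.0))
        assert p == pytest.approx(2 / comb(14, 7), rel=1e-12)

    def test_tiny_groups_return_one(self):
        assert ns.rank_sum_p(np.array([1.0, 2.0]), np.array([3.0, 4.0, 5.0])) == 1.0


class TestProbeStats:
    def test_null_data_flat_fc_and_large_p(self, small_genome):
        es = ns.simulate_expression(small_genome, None, noise_sd=0.1,
                                    n_replicates=2, seed=1)[0]
        stats = probe_stats_expression(es)
        assert np.abs(stats["log2_fc"]).max() < 0.5
        assert (stats["p"] <= 0.05).mean() < 0.10

    def test_fourfold_region_recovers_log2_of_four(self, small_genome):
        gene = next(g for g in small_genome.genes if g.strand == "+")
        interval = (gene.start + 200, gene.start + 700)
        pert = ns.PerturbationSpec(cryptic_transcripts=[("chr1", *interval, "+", 4.0)])
        es = next(e for e in ns.simulate_expression(small_genome, pert, noise_sd=0.05,
                                                    n_replicates=2, seed=2)
                  if e.strand == "+")
        stats = probe_stats_expression(es)
        inside = stats[(stats["pos"] >= interval[0] + 40) & (stats["pos"] <= interval[1] - 40)]
        assert inside["log2_fc"].mean() == pytest.approx(2.0, abs=0.1)
        assert (inside["p"] <= 0.05).all()


class TestDetect:
    def test_enough_probes_but_short_span_rejected(self):
        # 12 passing probes on a 4-bp grid span only 45 bp
        assert ns.detect(stats_frame(np.full(12, 1.5))) == []

    def test_span_and_count_met_gives_one_transfrag(self):
        out = ns.detect(stats_frame(np.full(21, 1.5)))
        assert len(out) == 1
        tf = out[0]
        assert (tf.start, tf.end, tf.n_probes, tf.direction) == (1001, 1081, 21, "up")

    def test_gap_beyond_48_splits_runs(self):
        fc = np.r_[np.full(21, 1.5), np.zeros(13), np.full(21, 1.5)]
        p = np.where(fc != 0, 0.01, 1.0)
        out = ns.detect(stats_frame(fc, p))
        assert len(out) == 2

    def test_gap_within_48_bridges_runs(self):
        fc = np.r_[np.full(11, 1.5), np.zeros(10), np.full(11, 1.5)]
        p = np.where(fc != 0, 0.01, 1.0)
        out = ns.detect(stats_frame(fc, p))  # passing probes 44 bp apart
        assert len(out) == 1 and out[0].n_probes == 22

    def test_sign_change_breaks_run(self):
        fc = np.r_[np.full(21, 1.5), np.full(21, -1.5)]
        out = ns.detect(stats_frame(fc))
        assert [t.direction for t in out] == ["up", "down"]

    def test_emitted_transfrags_satisfy_invariants(self):
        rng = np.random.default_rng(8)
        fc = rng.normal(0, 1.5, 2000)
        p = rng.uniform(0, 1, 2000)
        for tf in ns.detect(stats_frame(fc, p)):
            assert tf.length >= 80 and tf.n_probes >= 10
            assert (tf.mean_log2_fc > 0) == (tf.direction == "up")

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_relaxing_thresholds_never_reduces_count(self, seed):
        rng = np.random.default_rng(seed)
        frame = stats_frame(rng.normal(0, 1.5, 400), rng.uniform(0, 1, 400))
        strict = len(ns.detect(frame, fc_thresh=2.0, p_thresh=0.05))
        relaxed = len(ns.detect(frame, fc_thresh=1.5, p_thresh=0.20))
        assert relaxed >= strict


class TestMerge:
    def base_stats(self, mid_fc):
        fc = np.r_[np.full(21, 1.5), np.full(25, mid_fc), np.full(21, 1.5)]
        p = np.r_[np.full(21, 0.01), np.full(25, 1.0), np.full(21, 0.01)]
        return stats_frame(fc, p)

    def test_consistent_intervening_probes_merge(self):
        stats = self.base_stats(0.3)
        out = ns.merge(ns.detect(stats), stats)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (1001, 1001 + 66 * 4)

    def test_inconsistent_intervening_probe_blocks_merge(self):
        stats = self.base_stats(0.3)
        stats.loc[30, "log2_fc"] = -0.2
        out = ns.merge(ns.detect(stats), stats)
        assert len(out) == 2

    def test_opposite_directions_never_merge(self):
        fc = np.r_[np.full(21, 1.5), np.full(25, 0.0), np.full(21, -1.5)]
        p = np.r_[np.full(21, 0.01), np.full(25, 1.0), np.full(21, 0.01)]
        stats = stats_frame(fc, p)
        # make intervening probes sign-consistent with neither direction
        assert len(ns.merge(ns.detect(stats, ), stats)) == 2

    def test_gap_above_250_blocks_merge(self):
        fc = np.r_[np.full(21, 1.5), np.full(70, 0.5), np.full(21, 1.5)]
        p = np.r_[np.full(21, 0.01), np.full(70, 1.0), np.full(21, 0.01)]
        stats = stats_frame(fc, p)  # gap = 279 bp
        assert len(ns.merge(ns.detect(stats), stats)) == 2

    def test_merge_idempotent(self):
        rng = np.random.default_rng(9)
        stats = stats_frame(rng.normal(0.5, 1.2, 1500), rng.uniform(0, 0.4, 1500))
        once = ns.merge(ns.detect(stats), stats)
        twice = ns.merge(once, stats)
        assert once == twice


class TestFilterAnnotated:
    genes = [ns.Gene("g1", "chr1", "+", 1000, 2000)]

    def tf(self, start, end, strand="+"):
        return Transfrag("chr1", strand, start, end, "up", 15, 1.5)

    def test_opposite_strand_overlap_retained(self):
        tf = self.tf(1200, 1400, strand="-")
        assert ns.filter_annotated([tf], self.genes) == [tf]

    def test_21_percent_overlap_removed(self):
        tf = self.tf(1980, 2079)  # 100 bp, 21 bp inside the gene
        assert ns.filter_annotated([tf], self.genes) == []

    def test_exactly_20_percent_retained(self):
        tf = self.tf(1981, 2080)  # 20 bp inside: strictly-more-than rule
        assert ns.filter_annotated([tf], self.genes) == [tf]

    def test_overlap_union_not_double_counted(self):
        genes = [ns.Gene("g1", "chr1", "+", 1000, 2000),
                 ns.Gene("g2", "chr1", "+", 1500, 2000)]
        tf = self.tf(1981, 2080)
        assert ns.filter_annotated([tf], genes) == [tf]


class TestClassify:
    def test_diverging_upstream_of_plus_gene(self):
        gene = ns.Gene("g1", "chr1", "+", 5000, 8000)
        tf = Transfrag("chr1", "-", 4550, 4850, "up", 15, 1.5)  # 5' end 150 bp upstream
        assert ns.classify(tf, [gene]) == "diverging"

    def test_intragenic_antisense_inside_opposite_gene(self):
        gene = ns.Gene("g1", "chr1", "+", 5000, 8000)
        tf = Transfrag("chr1", "-", 6000, 6300, "up", 15, 1.5)
        assert ns.classify(tf, [gene]) == "intragenic-antisense"

    def test_sense_inside_same_strand_gene_unclassified(self):
        gene = ns.Gene("g1", "chr1", "+", 5000, 8000)
        tf = Transfrag("chr1", "+", 6000, 6300, "up", 15, 1.5)
        assert ns.classify(tf, [gene]) == "unclassified"

    def test_converging_toward_oncoming_gene(self):
        gene = ns.Gene("g1", "chr1", "-", 8000, 5000)  # transcribes leftward
        tf = Transfrag("chr1", "+", 4000, 4300, "up", 15, 1.5)
        assert ns.classify(tf, [gene]) == "converging"

    def test_tandem_sense_downstream_of_same_strand_gene(self):
        gene = ns.Gene("g1", "chr1", "+", 1000, 4000)
        tf = Transfrag("chr1", "+", 4500, 4800, "up", 15, 1.5)
        assert ns.classify(tf, [gene]) == "tandem-sense"

    def test_no_gene_within_flank_unclassified(self):
        gene = ns.Gene("g1", "chr1", "+", 50_000, 53_000)
        tf = Transfrag("chr1", "+", 1000, 1300, "up", 15, 1.5)
        assert ns.classify(tf, [gene]) == "unclassified"


class TestUnionRegions:
    def tf(self, start, end, fc=1.0):
        return Transfrag("chr1", "+", start, end, "up", 15, fc)

    def test_disjoint_sets_concatenate(self):
        out = ns.union_regions({"a": [self.tf(100, 200)], "b": [self.tf(400, 500)]})
        assert len(out) == 2

    def test_identical_transfrag_collapses(self):
        out = ns.union_regions({"a": [self.tf(100, 200, 1.0)],
                                "b": [self.tf(100, 200, 2.0)]})
        assert len(out) == 1
        assert out.iloc[0]["mean_fc_a"] == 1.0 and out.iloc[0]["mean_fc_b"] == 2.0

    def test_transitive_chain_spans_all(self):
        out = ns.union_regions({"a": [self.tf(100, 250), self.tf(400, 600)],
                                "b": [self.tf(200, 450)]})
        assert len(out) == 1
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (100, 600)
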