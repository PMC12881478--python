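"""Loop inclusion filtering, classification, de-novo detection, stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epiloop.loops import (AnnotationContext, LoopSet, anchor_overlap_proportions,
                           classify_anchor, classify_loops, cohens_d,
                           de_novo_anchors, filter_loops, inclusion_mask,
                           loop_class_label, loop_expression_shift, loop_size,
                           loop_sizes, size_comparison, tss_upstream_windows)


def loopset(rows, bin_size=5000):
    df = pd.DataFrame(rows, columns=[
        "chrom1", "start1", "end1", "chrom2", "start2", "end2",
        "white_rep1", "white_rep2", "beige_rep1", "beige_rep2"])
    return LoopSet(df, bin_size=bin_size)


def simple_context():
    """chr1: TSS at 10_000 (+), K4me3 peak under it, K27ac peak at 50 kb."""
    tss = pd.DataFrame({"chrom": ["chr1"], "tss": [10_000],
                        "strand": ["+"], "transcript_id": ["tx1"]})
    return AnnotationContext(
        tss_windows=tss_upstream_windows(tss),
        h3k4me3_peaks=pd.DataFrame({"chrom": ["chr1"], "start": [9_000],
                                    "end": [9_500]}),
        h3k27ac_peaks=pd.DataFrame({"chrom": ["chr1"], "start": [50_000],
                                    "end": [51_000]}),
    )


class TestInclusionFilter:
    @pytest.mark.parametrize("white,beige,kept", [
        ((0, 1), (10, 9), True),     # beige passes: both > 6, 19 > 18
        ((6, 20), (6, 20), False),   # 6 is not > 6 in either condition
        ((0, 0), (7, 13), True),     # total 20 > 18
        ((0, 0), (7, 11), False),    # total 18 is not > 18
        ((10, 10), (0, 0), True),    # white can carry the loop too
    ])
    def test_rule(self, white, beige, kept):
        ls = loopset([("chr1", 0, 5000, "chr1", 10_000, 15_000,
                       white[0], white[1], beige[0], beige[1])])
        assert bool(inclusion_mask(ls)[0]) is kept

    @given(st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 3), st.sampled_from(range(4)))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotone_in_counts(self, w1, w2, b1, b2, bump, which):
        counts = [w1, w2, b1, b2]
        ls = loopset([("chr1", 0, 5000, "chr1", 10_000, 15_000, *counts)])
        counts[which] += bump
        ls2 = loopset([("chr1", 0, 5000, "chr1", 10_000, 15_000, *counts)])
        if inclusion_mask(ls)[0]:
            assert inclusion_mask(ls2)[0]

    def test_negative_counts_rejected(self):
        ls = loopset([("chr1", 0, 5000, "chr1", 10_000, 15_000,
                       -1, 0, 0, 0)])
        with pytest.raises(ValueError, match="negative"):
            filter_loops(ls)


class TestAnchorClassification:
    def test_promoter_precedence_over_enhancer(self):
        ctx = simple_context()
        # overlaps the TSS upstream window, the K4me3 peak, and a K27ac
        # peak added right there
        ctx.h3k27ac_peaks = pd.concat([
            ctx.h3k27ac_peaks,
            pd.DataFrame({"chrom": ["chr1"], "start": [9_100],
                          "end": [9_300]})], ignore_index=True)
        assert classify_anchor("chr1", 5_000, 10_000, ctx) == "Promoter"

    def test_enhancer_and_other(self):
        ctx = simple_context()
        assert classify_anchor("chr1", 50_000, 55_000, ctx) == "Enhancer"
        assert classify_anchor("chr1", 100_000, 105_000, ctx) == "Other"

    def test_k4me3_without_tss_window_is_not_promoter(self):
        ctx = simple_context()
        ctx.h3k4me3_peaks = pd.concat([
            ctx.h3k4me3_peaks,
            pd.DataFrame({"chrom": ["chr1"], "start": [200_000],
                          "end": [201_000]})], ignore_index=True)
        assert classify_anchor("chr1", 200_000, 205_000, ctx) == "Other"

    @pytest.mark.parametrize("a,b,label", [
        ("Enhancer", "Promoter", "Enhancer-Promoter"),
        ("Promoter", "Enhancer", "Enhancer-Promoter"),
        ("Enhancer", "Enhancer", "Enhancer-Enhancer"),
        ("Other", "Promoter", "Promoter-Other"),
        ("Other", "Other", "Other-Other"),
    ])
    def test_loop_class_is_unordered(self, a, b, label):
        assert loop_class_label(a, b) == label

    def test_degenerate_flagged_and_proportions_sum_to_one(self):
        ctx = simple_context()
        ls = loopset([
            ("chr1", 5_000, 10_000, "chr1", 50_000, 55_000, 9, 9, 9, 9),
            ("chr1", 100_000, 105_000, "chr1", 300_000, 305_000,
             9, 9, 9, 9),
        ])
        out = classify_loops(ls, ctx)
        assert out.loc[0, "loop_class"] == "Enhancer-Promoter"
        assert bool(out.loc[1, "degenerate"])


class TestDeNovo:
    def test_set_difference_semantics(self):
        beige = loopset([
            ("chr1", 0, 5000, "chr1", 20_000, 25_000, 0, 0, 9, 9),
            ("chr1", 40_000, 45_000, "chr1", 60_000, 65_000, 0, 0, 9, 9),
        ])
        common = loopset([
            ("chr1", 0, 5000, "chr1", 80_000, 85_000, 9, 9, 9, 9),
        ])
        novel, flags, prop = de_novo_anchors(beige, common)
        assert novel == {("chr1", 4), ("chr1", 8), ("chr1", 12)}
        assert flags.tolist() == [True, True]
        assert prop == 1.0

    def test_empty_common_set_everything_novel(self):
        beige = loopset([("chr1", 0, 5000, "chr1", 20_000, 25_000,
                          0, 0, 9, 9)])
        common = LoopSet(beige.df.iloc[:0])
        novel, flags, prop = de_novo_anchors(beige, common)
        assert flags.all() and prop == 1.0 and len(novel) == 2

    def test_resolution_mismatch_rejected(self):
        beige = loopset([("chr1", 0, 5000, "chr1", 20_000, 25_000,
                          0, 0, 9, 9)])
        common = loopset([("chr1", 0, 10_000, "chr1", 20_000, 30_000,
                           9, 9, 9, 9)], bin_size=10_000)
        with pytest.raises(ValueError, match="bin size"):
            de_novo_anchors(beige, common)


class TestLoopSize:
    def test_edge_gap(self):
        assert loop_size("chr1", 1000, 6000, "chr1", 16_000, 21_000) == 10_000

    def test_touching_anchors(self):
        assert loop_size("chr1", 0, 5000, "chr1", 5000, 10_000) == 0

    def test_symmetric_under_anchor_swap(self):
        a = loop_size("chr1", 1000, 6000, "chr1", 16_000, 21_000)
        b = loop_size("chr1", 16_000, 21_000, "chr1", 1000, 6000)
        assert a == b

    def test_matches_gap_base_counting_oracle(self, rng):
        for _ in range(25):
            s1 = int(rng.integers(0, 50))
            e1 = s1 + int(rng.integers(1, 20))
            s2 = int(rng.integers(0, 80))
            e2 = s2 + int(rng.integers(1, 20))
            if s1 > s2:
                (s1, e1), (s2, e2) = (s2, e2), (s1, e1)
            got = loop_size("chr1", s1, e1, "chr1", s2, e2)
            between = [b for b in range(e1, s2)] if s2 > e1 else []
            assert got == len(between)

    def test_interchromosomal_rejected(self):
        with pytest.raises(ValueError, match="interchromosomal"):
            loop_size("chr1", 0, 5000, "chr2", 0, 5000)
        ls = loopset([("chr1", 0, 5000, "chr2", 10_000, 15_000,
                       1, 1, 1, 1)])
        with pytest.raises(ValueError):
            loop_sizes(ls)


class TestSizeComparison:
    def test_identical_groups_null(self):
        out = size_comparison([1, 2, 3, 4], [1, 2, 3, 4])
        assert out["median_a"] == out["median_b"]
        assert out["pvalue"] > 0.9

    def test_exact_small_sample_p(self):
        # complete separation of 3 vs 3: two-sided exact p = 2/C(6,3)
        out = size_comparison([1, 2, 3], [10, 11, 12])
        assert out["method"] == "exact"
        assert out["pvalue"] == pytest.approx(0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            size_comparison([], [1.0])


class TestExpressionShift:
    def context_with_transcripts(self, n, prefix="tx", start=0):
        tss = pd.DataFrame({
            "chrom": "chr1",
            "tss": start + 10_000 + 50_000 * np.arange(n),
            "strand": "+",
            "transcript_id": [f"{prefix}{i}" for i in range(n)]})
        return tss, AnnotationContext(
            tss_windows=tss_upstream_windows(tss),
            h3k4me3_peaks=pd.DataFrame(columns=["chrom", "start", "end"]),
            h3k27ac_peaks=pd.DataFrame(columns=["chrom", "start", "end"]))

    def loops_at(self, tss):
        rows = []
        for t in tss["tss"]:
            a1 = (t // 5000) * 5000 - 5000   # bin containing the window
            rows.append(("chr1", a1, a1 + 5000, "chr1", a1 + 100_000,
                         a1 + 105_000, 0, 0, 9, 9))
        return loopset(rows)

    def test_planted_shift_detected(self, rng):
        n = 25
        tss, ctx = self.context_with_transcripts(n)
        lfc = pd.Series(rng.normal(1.0, 0.5, n),
                        index=tss["transcript_id"])
        out = loop_expression_shift({"beige": self.loops_at(tss)}, ctx, lfc)
        assert out.loc["beige", "median_lfc"] > 0
        assert out.loc["beige", "pvalue"] < 0.05

    def test_symmetric_null_mostly_insignificant(self):
        n = 30
        tss, ctx = self.context_with_transcripts(n)
        loops = self.loops_at(tss)
        hits = 0
        seeds = range(40)
        for seed in seeds:
            lfc = pd.Series(np.random.default_rng(seed).normal(0, 1, n),
                            index=tss["transcript_id"])
            out = loop_expression_shift({"g": loops}, ctx, lfc)
            hits += out.loc["g", "pvalue"] < 0.05
        assert hits <= 4   # ~5% false positives expected over 40 runs

    def test_no_associated_transcripts_is_an_error(self):
        tss, ctx = self.context_with_transcripts(3)
        far = loopset([("chr1", 10_000_000, 10_005_000,
                        "chr1", 10_100_000, 10_105_000, 0, 0, 9, 9)])
        lfc = pd.Series([1.0, 2.0, 3.0], index=tss["transcript_id"])
        with pytest.raises(ValueError, match="no associated"):
            loop_expression_shift({"beige": far}, ctx, lfc)


class TestOverlapProportions:
    def test_categories_partition(self):
        ctx = simple_context()
        ctx.dars = pd.DataFrame({"chrom": ["chr1"], "start": [1_000],
                                 "end": [1_200]})
        ctx.diff_h3k27ac = pd.DataFrame(columns=["chrom", "start", "end"])
        ls = loopset([
            ("chr1", 0, 5000, "chr1", 50_000, 55_000, 0, 0, 9, 9),
            ("chr1", 200_000, 205_000, "chr1", 400_000, 405_000,
             0, 0, 9, 9),
        ])
        out = anchor_overlap_proportions(ls, ctx)
        assert out["dar_only"] == pytest.approx(0.5)
        assert out["neither"] == pytest.approx(0.5)
        assert sum(out.values()) == pytest.approx(1.0)

    def test_missing_sets_rejected(self):
        ctx = simple_context()
        ls = loopset([("chr1", 0, 5000, "chr1", 50_000, 55_000,
                       0, 0, 9, 9)])
        with pytest.raises(ValueError, match="DAR"):
            anchor_overlap_proportions(ls, ctx)


class TestCohensD:
    def test_unit_case(self, rng):
        a = rng.normal(1.0, 1.0, 100_000)
        b = rng.normal(0.0, 1.0, 100_000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.02)

    def test_identical_groups_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cohens_d(x, x) == 0.0

    def test_exact_hand_computation(self):
        # means 1 and 0, both sample SD 1, equal n → D = 1 exactly
        a = np.array([0.0, 1.0, 2.0])
        b = np.array([-1.0, 0.0, 1.0])
        assert cohens_d(a, b) == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="2 values"):
            cohens_d([1.0], [1.0, 2.0])
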