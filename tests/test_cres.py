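"""Robust CRE filtering, sharing, promoter calls, stand-in count test."""

import itertools

import numpy as np
import pytest

from sexqtl.cres import (CreRecord, DiffRegion, bh_fdr, call_robust_regions,
                         classify_cre_sharing, classify_promoter,
                         standin_diff_test)
from sexqtl.intervals import GeneRecord, GenomicInterval


def diff(start=1000, end=1600, assay="K27ac", strain="B6", lfc=1.5,
         fdr=0.01, count=30):
    return DiffRegion(GenomicInterval("chr1", start, end), assay, strain,
                      lfc, fdr, count)


PEAKS = [GenomicInterval("chr1", 900, 1700)]


class TestCallRobustRegions:
    def test_all_filters_pass(self):
        fc25 = np.log2(2.5)
        out = call_robust_regions([diff(lfc=fc25, count=20)], PEAKS)
        assert len(out) == 1
        assert out[0].direction == "male"

    @pytest.mark.parametrize("kwargs", [
        dict(lfc=np.log2(2.5), count=12),            # below min count 15
        dict(lfc=np.log2(1.8)),                      # below K27ac 2-fold
        dict(lfc=np.log2(2.5), fdr=0.2),             # FDR fail
    ])
    def test_single_filter_failures(self, kwargs):
        assert call_robust_regions([diff(**kwargs)], PEAKS) == []

    def test_no_peak_overlap_drops_region(self):
        assert call_robust_regions([diff(lfc=np.log2(2.5))], []) == []

    def test_dhs_uses_relaxed_cutoffs(self):
        d = diff(assay="DHS", lfc=np.log2(1.7), count=11)
        out = call_robust_regions([d], PEAKS)
        assert len(out) == 1
        # same region fails under the ChIP cutoffs
        d2 = diff(assay="K27ac", lfc=np.log2(1.7), count=11)
        assert call_robust_regions([d2], PEAKS) == []

    def test_female_direction_from_negative_fold_change(self):
        out = call_robust_regions([diff(lfc=-np.log2(3))], PEAKS)
        assert out[0].direction == "female"

    def test_exclusion_mask_applied_first(self):
        mask = [GenomicInterval("chr1", 1500, 1550)]
        assert call_robust_regions([diff(lfc=np.log2(3))], PEAKS,
                                   exclusion_mask=mask) == []

    def test_filter_order_irrelevant(self, rng):
        """The survivor set equals the intersection of the four per-filter
        survivor sets, so application order cannot matter."""
        diffs = [diff(start=int(s), end=int(s) + 500,
                      lfc=float(rng.normal(0, 1.5)),
                      fdr=float(rng.uniform(0, 0.2)),
                      count=int(rng.integers(0, 40)))
                 for s in rng.integers(0, 5000, 40)]
        peaks = [GenomicInterval("chr1", 0, 2500)]
        survivors = {c.interval for c in call_robust_regions(diffs, peaks)}
        by_fc = {d.interval for d in diffs if abs(d.log2fc_mf) > np.log2(2)}
        by_fdr = {d.interval for d in diffs if d.fdr < 0.05}
        by_count = {d.interval for d in diffs if d.max_group_count >= 15}
        by_peak = {d.interval for d in diffs
                   if any(max(d.interval.start, p.start) < min(d.interval.end, p.end)
                          for p in peaks)}
        assert {i for i in survivors} == by_fc & by_fdr & by_count & by_peak

    def test_unknown_assay_rejected(self):
        with pytest.raises(ValueError, match="unknown assay"):
            DiffRegion(GenomicInterval("chr1", 0, 10), "ATAC", "B6", 1, 0.01, 20)


def cre(start, end, strain="B6", direction="male", assay="K27ac"):
    return CreRecord(GenomicInterval("chr1", start, end), assay, strain,
                     direction)


class TestSharing:
    def test_shared_concordant(self):
        out = classify_cre_sharing([cre(100, 200)],
                                   [cre(150, 250, strain="CAST")])
        assert all(c.share_class == "shared" and c.concordant for c in out)

    def test_shared_discordant(self):
        out = classify_cre_sharing(
            [cre(100, 200)], [cre(150, 250, strain="CAST", direction="female")])
        assert all(c.share_class == "shared" and c.concordant is False
                   for c in out)

    def test_unique_when_no_overlap(self):
        out = classify_cre_sharing([cre(100, 200)],
                                   [cre(300, 400, strain="CAST")])
        assert {c.share_class for c in out} == {"b6_unique", "cast_unique"}

    def test_cross_assay_overlap_does_not_share(self):
        out = classify_cre_sharing(
            [cre(100, 200)], [cre(150, 250, strain="CAST", assay="DHS")])
        assert {c.share_class for c in out} == {"b6_unique", "cast_unique"}

    def test_nearest_midpoint_partner_decides_concordance(self):
        # B6 CRE overlaps two CAST CREs; the nearer-midpoint one is discordant
        b6 = [cre(100, 300)]
        cast = [cre(150, 260, strain="CAST", direction="female"),
                cre(280, 500, strain="CAST", direction="male")]
        out = classify_cre_sharing(b6, cast)
        assert out[0].share_class == "shared" and out[0].concordant is False

    def test_partition_is_complete(self, rng):
        b6 = [cre(int(s), int(s) + 100) for s in rng.integers(0, 3000, 15)]
        cast = [cre(int(s), int(s) + 100, strain="CAST")
                for s in rng.integers(0, 3000, 15)]
        out = classify_cre_sharing(b6, cast)
        assert len(out) == len(b6) + len(cast)
        counts = {}
        for c in out:
            counts[c.share_class] = counts.get(c.share_class, 0) + 1
        assert sum(counts.values()) == 30


class TestPromoter:
    GENES = [GeneRecord("g1", "chr1", 5000)]

    @pytest.mark.parametrize("start, end, expected", [
        (4900, 5100, True),      # CRE contains the TSS
        (8000, 8500, False),     # nearest TSS at 3 kb -> enhancer
        (7500, 8000, True),      # nearest TSS exactly 2,500 bp -> promoter
    ])
    def test_boundary(self, start, end, expected):
        c = cre(start, end)
        assert classify_promoter(c, self.GENES) is expected


class TestStandinDiffTest:
    def test_identical_groups_null(self):
        lfc, p = standin_diff_test([10, 10, 10], [10, 10, 10])
        assert lfc == 0.0 and p > 0.05

    def test_fourfold_means_near_log2fc_2(self, rng):
        a = rng.poisson(4000, 6)
        b = rng.poisson(1000, 6)
        lfc, p = standin_diff_test(a, b)
        assert lfc == pytest.approx(2.0, abs=0.15)
        assert p < 0.01

    def test_library_size_normalization_cancels_depth(self):
        # group a sequenced twice as deep; identical underlying signal
        lfc, _ = standin_diff_test([200, 210, 190], [100, 105, 95],
                                   lib_sizes_a=[2e6, 2e6, 2e6],
                                   lib_sizes_b=[1e6, 1e6, 1e6])
        assert lfc == pytest.approx(0.0, abs=0.1)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            standin_diff_test([5], [5, 6])

    def test_bh_hand_computation(self):
        # BH on (0.01, 0.02, 0.03, 0.04), m=4: p_(i) * m / i, monotone
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])
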