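"""Matched shuffling, enrichment statistics and qPCR formulas."""

import numpy as np
import pytest

from sexqtl.enrichment import (EnrichmentResult, _count_overlaps,
                               _variant_arrays, enrichment, enrichment_ratio,
                               shuffle_matched)
from sexqtl.intervals import GenomicInterval
from sexqtl.qpcr import percent_input, signal_to_noise
from sexqtl.variants import FOUNDERS, FounderVariant, count_variants_overlapping


def specific_variant(pos, chrom="chr1"):
    alleles = {f: "A" for f in FOUNDERS}
    alleles["CAST"] = "T"
    return FounderVariant(chrom, pos, "A", alleles)


UNIVERSE = [GenomicInterval("chr1", 0, 1_000_000)]


class TestShuffleMatched:
    def test_width_multiset_preserved(self, rng):
        regions = [GenomicInterval("chr1", int(s), int(s) + int(w))
                   for s, w in zip(rng.integers(0, 900_000, 30),
                                   rng.integers(100, 5000, 30))]
        shuffled = shuffle_matched(regions, UNIVERSE, rng)
        assert sorted(len(r) for r in shuffled) \
            == sorted(len(r) for r in regions)

    def test_fixed_seed_reproducible(self):
        regions = [GenomicInterval("chr1", 0, 500)] * 5
        a = shuffle_matched(regions, UNIVERSE, np.random.default_rng(3))
        b = shuffle_matched(regions, UNIVERSE, np.random.default_rng(3))
        assert a == b

    def test_placements_stay_inside_segments(self, rng):
        universe = [GenomicInterval("chr1", 100, 600),
                    GenomicInterval("chr2", 0, 400)]
        regions = [GenomicInterval("chr1", 100, 400)] * 50
        for r in shuffle_matched(regions, universe, rng):
            assert any(r.chrom == s.chrom and r.start >= s.start
                       and r.end <= s.end for s in universe)

    def test_oversized_region_rejected(self, rng):
        with pytest.raises(ValueError, match="does not fit"):
            shuffle_matched([GenomicInterval("chr1", 0, 700)],
                            [GenomicInterval("chr1", 0, 500)], rng)


class TestEnrichment:
    def test_published_ratio_arithmetic(self):
        assert enrichment_ratio(4463, 1767) == 2.53

    def test_constructed_extreme_enrichment(self):
        # all variants inside the regions; shuffles roam a 100x universe
        regions = [GenomicInterval("chr1", 1000 * k, 1000 * k + 500)
                   for k in range(10)]
        variants = [specific_variant(1000 * k + 250) for k in range(10)]
        res = enrichment(variants, regions, UNIVERSE, n_perm=99, seed=0)
        assert res.observed == 10
        assert res.ratio is None or res.ratio > 5
        assert res.empirical_p == pytest.approx(1 / 100)

    def test_uniform_null_ratio_near_one(self, rng):
        variants = [specific_variant(int(p))
                    for p in rng.integers(0, 1_000_000, 500)]
        regions = [GenomicInterval("chr1", int(s), int(s) + 400)
                   for s in rng.integers(0, 999_000, 80)]
        res = enrichment(variants, regions, UNIVERSE, n_perm=200, seed=5)
        assert res.ratio == pytest.approx(1.0, abs=0.25)

    def test_expected_zero_flagged_not_crashed(self):
        # a single variant far from anywhere shuffles can reach it rarely
        universe = [GenomicInterval("chr1", 0, 10_000_000)]
        regions = [GenomicInterval("chr1", 0, 100)]
        variants = [specific_variant(50)]
        res = enrichment(variants, regions, universe, n_perm=19, seed=1)
        assert res.expected == 0.0 and res.ratio is None
        assert res.observed == 1

    def test_same_seed_byte_identical_result(self, rng):
        variants = [specific_variant(int(p))
                    for p in rng.integers(0, 1_000_000, 100)]
        regions = [GenomicInterval("chr1", int(s), int(s) + 300)
                   for s in rng.integers(0, 999_000, 20)]
        a = enrichment(variants, regions, UNIVERSE, n_perm=50, seed=9)
        b = enrichment(variants, regions, UNIVERSE, n_perm=50, seed=9)
        assert a == b

    def test_fast_counter_matches_reference(self, rng):
        for _ in range(100):
            variants = [specific_variant(int(p))
                        for p in rng.integers(0, 2000, 40)]
            regions = [GenomicInterval("chr1", int(s), int(s) + int(w))
                       for s, w in zip(rng.integers(0, 1900, 12),
                                       rng.integers(1, 200, 12))]
            assert _count_overlaps(_variant_arrays(variants), regions) \
                == count_variants_overlapping(variants, regions)


class TestQpcr:
    def test_equal_deltas_give_two(self):
        # every region's ΔCT equal: exponent is 1
        assert signal_to_noise(10, 7, [12, 11, 13], [9, 8, 10]) == 2.0

    def test_double_delta_gives_four(self):
        assert signal_to_noise(10, 4, [12, 11, 13], [9, 8, 10]) == 4.0

    def test_zero_delta_gives_one(self):
        assert signal_to_noise(10, 10, [12, 11, 13], [9, 8, 10]) == 1.0

    def test_conventional_form_differs(self):
        verbatim = signal_to_noise(10, 6, [12, 11, 13], [9, 8, 10])
        conventional = signal_to_noise(10, 6, [12, 11, 13], [9, 8, 10],
                                       conventional=True)
        assert verbatim != conventional
        assert conventional == 2.0 ** (4 - 3)

    def test_zero_negavg_rejected(self):
        with pytest.raises(ValueError, match="NegAvg"):
            signal_to_noise(10, 7, [9, 8, 10], [9, 8, 10])

    @pytest.mark.parametrize(
        "ct_chip, ct_input, vols, expected", [
            (20, 20, (1, 1, 1, 1), 100.0),
            (21, 20, (1, 1, 1, 1), 50.0),
            (20, 20, (1, 2, 1, 1), 200.0),   # ChIP final volume doubled
        ])
    def test_percent_input(self, ct_chip, ct_input, vols, expected):
        ci, cf, ii, inf = vols
        assert percent_input(ct_chip, ct_input, ci, cf, ii, inf) == expected

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            percent_input(20, 20, 0, 1, 1, 1)
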