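"""Regulating strains, interval funnel, categories, impacts, relevant CREs."""

import itertools

import numpy as np
import pytest

from sexqtl.cres import CreRecord
from sexqtl.eqtl import (CATEGORY_TABLE, EqtlScanRecord, ScanSet,
                         assign_regulating_strains, categorize_eqtl,
                         classify_impact, count_relevant_cres,
                         merge_cre_components, position_class,
                         select_interval)
from sexqtl.intervals import GeneRecord, GenomicInterval, TadMap, TadRecord
from sexqtl.variants import FOUNDERS, FounderVariant


def coef(**vals):
    out = {f: 0.01 for f in FOUNDERS}
    out.update(vals)
    return out


class TestRegulatingStrains:
    def test_second_strain_within_20_percent_included(self):
        got = assign_regulating_strains(coef(CAST=-1.0, PWK=-0.85))
        assert got[:2] == ("CAST", "PWK")

    def test_below_band_excluded(self):
        got = assign_regulating_strains(coef(CAST=-1.0, PWK=-0.79))
        assert got == ("CAST",)

    def test_exact_tie_orders_alphabetically(self):
        got = assign_regulating_strains(coef(B6=0.5, CAST=-0.5))
        assert got == ("B6", "CAST")

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            assign_regulating_strains({f: 0.0 for f in FOUNDERS})


def scan_set(sig, lod, interval=None, **coef_vals):
    return ScanSet(significant=sig, lod=lod, coef=coef(**coef_vals),
                   interval=interval)


class TestSelectInterval:
    IV_2MB = GenomicInterval("chr1", 0, 2_000_000)
    IV_1MB = GenomicInterval("chr1", 500_000, 1_500_000)

    def test_shortest_of_qualifying_sets(self):
        rec = EqtlScanRecord("g", {
            "all": scan_set(True, 8, self.IV_2MB, CAST=-1.0),
            "male": scan_set(True, 10, self.IV_1MB, CAST=-0.9)})
        chosen, intersected = select_interval(rec, "CAST")
        assert chosen == self.IV_1MB
        assert intersected == self.IV_1MB    # nested intervals

    def test_single_significant_set_is_default(self):
        rec = EqtlScanRecord("g", {
            "female": scan_set(True, 9, self.IV_2MB, B6=0.8),
            "male": scan_set(False, 2, None, B6=0.1)})
        chosen, intersected = select_interval(rec, "B6")
        assert chosen == self.IV_2MB and intersected is None

    def test_partial_overlap_intersection(self):
        a = GenomicInterval("chr1", 0, 1_000_000)
        b = GenomicInterval("chr1", 600_000, 1_400_000)
        rec = EqtlScanRecord("g", {
            "all": scan_set(True, 8, a, CAST=1.0),
            "female": scan_set(True, 9, b, CAST=1.0)})
        chosen, intersected = select_interval(rec, "CAST")
        assert chosen == b   # shorter: 0.8 Mb
        assert intersected == GenomicInterval("chr1", 600_000, 1_000_000)

    def test_sets_regulated_by_other_strains_do_not_qualify(self):
        rec = EqtlScanRecord("g", {
            "male": scan_set(True, 10, self.IV_1MB, PWK=-1.0, CAST=-0.1)})
        with pytest.raises(ValueError, match="no scan set"):
            select_interval(rec, "CAST")


class TestPositionClass:
    TADS = TadMap([TadRecord("t1", GenomicInterval("chr1", 0, 1_000_000)),
                   TadRecord("t2", GenomicInterval("chr1", 1_100_000, 2_000_000))])
    GENE = GeneRecord("g", "chr1", 500_000)

    def test_intra_tad_with_narrowed_interval(self):
        eqtl = GenomicInterval("chr1", 800_000, 1_300_000)
        cls, tad_iv = position_class(eqtl, self.GENE, self.TADS)
        assert cls == "tad"
        assert tad_iv == GenomicInterval("chr1", 800_000, 1_000_000)

    def test_same_chromosome_outside_tad(self):
        eqtl = GenomicInterval("chr1", 1_200_000, 1_400_000)
        cls, tad_iv = position_class(eqtl, self.GENE, self.TADS)
        assert cls == "chromosome" and tad_iv is None

    def test_trans_on_other_chromosome(self):
        eqtl = GenomicInterval("chr2", 0, 100_000)
        assert position_class(eqtl, self.GENE, self.TADS)[0] == "trans"

    def test_gene_in_no_tad_falls_back_to_chromosome(self):
        gene = GeneRecord("g", "chr1", 1_050_000)    # inter-TAD gap
        eqtl = GenomicInterval("chr1", 0, 100_000)
        assert position_class(eqtl, gene, self.TADS)[0] == "chromosome"


class TestCategorize:
    def test_bijection_over_the_factor_cube(self):
        seen = set()
        for bias, sex, sign in itertools.product(
                ("male", "female"), ("male", "female"), ("+", "-")):
            seen.add(categorize_eqtl(bias, sex, sign))
        assert seen == set(range(1, 9))

    def test_group_structure(self):
        for (bias, sex, sign), cat in CATEGORY_TABLE.items():
            assert (cat % 2 == 1) == (bias == "male")
            assert (cat in {1, 2, 5, 6}) == (sex == "male")
            assert (cat in {1, 4, 6, 7}) == (sign == "-")

    @pytest.mark.parametrize("bias, sex, sign, expected", [
        ("male", "male", "-", 1),       # Cspg5: repressed in CAST males
        ("female", "male", "-", 6),     # Slc16a5: male repression boosts bias
        ("female", "female", "+", 8),   # Ptger3: activated in CAST females
    ])
    def test_reference_cases(self, bias, sex, sign, expected):
        assert categorize_eqtl(bias, sex, sign) == expected


class TestImpact:
    def test_loss(self):
        # regulating CAST not sex-biased; non-regulating B6 male-biased
        assert classify_impact(1, ("none", False), ("male", True)) == "loss"

    def test_gain(self):
        assert classify_impact(8, ("female", True), ("none", False)) == "gain"

    def test_reversal_any_category(self):
        for cat in (1, 5):
            assert classify_impact(cat, ("male", True), ("female", True)) \
                == "reversal"

    def test_retained_split_by_category_side(self):
        both = (("female", True), ("female", True))
        assert classify_impact(6, *both) == "retained_enhanced"
        assert classify_impact(4, *both) == "retained_reduced"

    def test_no_call_when_nothing_significant(self):
        assert classify_impact(1, ("none", False), ("none", False)) == "none"

    def test_polarity_mismatch_gives_none(self):
        # gain-side category but only the non-regulating strain is biased
        assert classify_impact(5, ("none", False), ("male", True)) == "none"


def make_cre(start, end, strain="B6", direction="male", assay="K27ac",
             share=None):
    return CreRecord(GenomicInterval("chr1", start, end), assay, strain,
                     direction, share_class=share)


def specific_variant(pos, strain="CAST"):
    alleles = {f: "A" for f in FOUNDERS}
    alleles[strain] = "T"
    return FounderVariant("chr1", pos, "A", alleles)


class TestRelevantCres:
    SEARCH = GenomicInterval("chr1", 0, 100_000)

    def test_single_qualifying_cre(self):
        cres = [make_cre(1000, 2000, strain="B6", share="b6_unique")]
        got = count_relevant_cres(1, "CAST", "male", self.SEARCH, cres,
                                  [specific_variant(1500)])
        assert got == "one"

    def test_overlapping_dhs_and_k27ac_count_once(self):
        cres = [make_cre(1000, 2000, share="b6_unique"),
                make_cre(1200, 1800, share="b6_unique", assay="DHS")]
        got = count_relevant_cres(1, "CAST", "male", self.SEARCH, cres,
                                  [specific_variant(1500)])
        assert got == "one"

    def test_disjoint_candidates_are_multiple(self):
        cres = [make_cre(1000, 2000, share="b6_unique"),
                make_cre(5000, 6000, share="b6_unique", assay="DHS")]
        vs = [specific_variant(1500), specific_variant(5500)]
        assert count_relevant_cres(1, "CAST", "male", self.SEARCH, cres, vs) \
            == "multiple"

    def test_polarity_wrong_strain_uniqueness_disqualifies(self):
        # category 1 with CAST regulating wants CREs lost in CAST,
        # i.e. unique to B6; a CAST-unique CRE cannot qualify
        cres = [make_cre(1000, 2000, strain="CAST", share="cast_unique")]
        got = count_relevant_cres(1, "CAST", "male", self.SEARCH, cres,
                                  [specific_variant(1500)])
        assert got == "none"

    def test_gain_side_wants_regulating_strain_cre(self):
        cres = [make_cre(1000, 2000, strain="CAST", share="cast_unique")]
        got = count_relevant_cres(8, "CAST", "female", self.SEARCH,
                                  [make_cre(1000, 2000, strain="CAST",
                                            direction="female",
                                            share="cast_unique")],
                                  [specific_variant(1500)])
        assert got == "one"

    def test_no_variant_no_candidate(self):
        cres = [make_cre(1000, 2000, share="b6_unique")]
        assert count_relevant_cres(1, "CAST", "male", self.SEARCH, cres, []) \
            == "none"

    def test_merged_counting_matches_connected_components_oracle(self, rng):
        """500 random landscapes: candidate filtering + single-linkage
        merge equals an explicit brute-force connected-components count."""
        for _ in range(500):
            n = int(rng.integers(0, 8))
            cres, variants = [], []
            for _ in range(n):
                s = int(rng.integers(0, 20_000))
                w = int(rng.integers(200, 3000))
                share = str(rng.choice(["b6_unique", "cast_unique", "shared"]))
                direction = str(rng.choice(["male", "female"]))
                strain = "B6" if share == "b6_unique" else "CAST"
                cres.append(make_cre(s, s + w, strain=strain,
                                     direction=direction,
                                     assay=str(rng.choice(["K27ac", "DHS"])),
                                     share=share))
                if rng.random() < 0.7:
                    variants.append(specific_variant(s + w // 2))
            got = count_relevant_cres(1, "CAST", "male", self.SEARCH,
                                      cres, variants)
            # oracle: explicit qualification + graph components
            var_pos = [v.pos for v in variants]
            quals = [c for c in cres
                     if c.direction == "male" and c.share_class == "b6_unique"
                     and c.interval.start < 100_000
                     and any(c.interval.start <= p < c.interval.end
                             for p in var_pos)]
            adj = {i: set() for i in range(len(quals))}
            for i in range(len(quals)):
                for j in range(i + 1, len(quals)):
                    a, b = quals[i].interval, quals[j].interval
                    if max(a.start, b.start) < min(a.end, b.end):
                        adj[i].add(j)
                        adj[j].add(i)
            seen, comps = set(), 0
            for i in range(len(quals)):
                if i in seen:
                    continue
                comps += 1
                stack = [i]
                while stack:
                    k = stack.pop()
                    if k in seen:
                        continue
                    seen.add(k)
                    stack.extend(adj[k])
            expected = "none" if comps == 0 else \
                ("one" if comps == 1 else "multiple")
            assert got == expected
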