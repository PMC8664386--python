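"""Robust sex-biased CRE calling and strain-sharing classification.

Differential regions (diffReps-style male-vs-female comparisons of
H3K27ac ChIP-seq or DNase-seq signal) are filtered for robustness:

* |fold-change| above the assay cutoff (2 for H3K27ac, 1.5 for DHS),
* FDR < 0.05,
* overlap of >= 1 bp with a called peak of the same strain/assay,
* read count in the up-regulated group of >= 15 (H3K27ac) or >= 10 (DHS).

Survivors become CREs whose direction comes from the fold-change sign
(positive log2 M/F = male-biased).  Cross-strain comparison then labels
each CRE shared (>= 1 bp overlap with an opposite-strain sex-biased CRE
of the same assay) or strain-unique, with direction concordance scored
against the nearest-by-midpoint overlapping partner.

A two-group count test (`standin_diff_test`) animates synthetic replicate
counts; it is a simple normalized-log Welch test with BH correction, not
a negative-binomial window scan.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, GeneRecord, overlaps, tss_distance

ASSAYS = ("K27ac", "DHS")

# robustness cutoffs per assay: (min linear |fold-change|, min read count)
ASSAY_FC_CUTOFF = {"K27ac": 2.0, "DHS": 1.5}
ASSAY_MIN_COUNT = {"K27ac": 15, "DHS": 10}

FDR_CUTOFF = 0.05


@dataclass(frozen=True)
class DiffRegion:
    """One differential region from a male-vs-female comparison."""

    interval: GenomicInterval
    assay: str
    strain: str
    log2fc_mf: float
    fdr: float
    max_group_count: int   # read count in the up-regulated group

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected {ASSAYS}")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr must be in [0,1], got {self.fdr}")
        if self.max_group_count < 0:
            raise ValueError("max_group_count must be >= 0")


@dataclass(frozen=True)
class CreRecord:
    """A regulatory region with direction, robustness and sharing labels."""

    interval: GenomicInterval
    assay: str
    strain: str
    direction: str                       # male / female / none
    robust: bool = True
    share_class: Optional[str] = None    # shared / b6_unique / cast_unique
    concordant: Optional[bool] = None
    promoter: Optional[bool] = None


def call_robust_regions(diffs: Iterable[DiffRegion],
                        peaks: Sequence[GenomicInterval],
                        exclusion_mask: Sequence[GenomicInterval] = (),
                        fdr_cutoff: float = FDR_CUTOFF) -> list[CreRecord]:
    """Filter differential regions to robust sex-biased CREs.

    ``peaks`` is the peak universe for the matching strain/assay.  An
    optional ``exclusion_mask`` (blacklist stand-in) drops any region
    overlapping a masked interval before filtering.  The four filters are
    a pure set intersection — their order cannot change the result.
    """
    out = []
    for d in diffs:
        fc_cut = ASSAY_FC_CUTOFF[d.assay]     # raises KeyError-free: validated
        min_count = ASSAY_MIN_COUNT[d.assay]
        if any(overlaps(d.interval, m) for m in exclusion_mask):
            continue
        if abs(d.log2fc_mf) <= np.log2(fc_cut):
            continue
        if not (d.fdr < fdr_cutoff):
            continue
        if d.max_group_count < min_count:
            continue
        if not any(overlaps(d.interval, p) for p in peaks):
            continue
        direction = "male" if d.log2fc_mf > 0 else "female"
        out.append(CreRecord(d.interval, d.assay, d.strain, direction))
    return out


def classify_cre_sharing(b6_cres: Sequence[CreRecord],
                         cast_cres: Sequence[CreRecord]) -> list[CreRecord]:
    """Label every CRE shared or strain-unique by >= 1 bp overlap with the
    opposite strain's sex-biased CREs of the same assay.

    Concordance of a shared CRE is judged against the overlapping partner
    whose midpoint is nearest (ties broken toward the larger overlap).
    Returns new records for both strains, B6 first.
    """
    def classify(mine: Sequence[CreRecord], theirs: Sequence[CreRecord],
                 unique_label: str) -> list[CreRecord]:
        out = []
        for cre in mine:
            partners = [o for o in theirs
                        if o.assay == cre.assay and overlaps(cre.interval, o.interval)]
            if not partners:
                out.append(replace(cre, share_class=unique_label, concordant=None))
                continue
            def key(o: CreRecord):
                mid_gap = abs(o.interval.midpoint - cre.interval.midpoint)
                olap = (min(cre.interval.end, o.interval.end)
                        - max(cre.interval.start, o.interval.start))
                return (mid_gap, -olap)
            best = min(partners, key=key)
            out.append(replace(cre, share_class="shared",
                               concordant=best.direction == cre.direction))
        return out

    return (classify(b6_cres, cast_cres, "b6_unique")
            + classify(cast_cres, b6_cres, "cast_unique"))


def classify_promoter(cre: CreRecord, genes: Sequence[GeneRecord],
                      promoter_bp: int = 2_500) -> bool:
    """Promoter iff the nearest TSS is within 2.5 kb (inclusive); beyond
    that the CRE is an enhancer."""
    best = None
    for g in genes:
        d = tss_distance(g, cre.interval)
        if d is not None and (best is None or d < best):
            best = d
    return best is not None and best <= promoter_bp


def standin_diff_test(counts_a: Sequence[float], counts_b: Sequence[float],
                      lib_sizes_a: Sequence[float] | None = None,
                      lib_sizes_b: Sequence[float] | None = None,
                      ) -> tuple[float, float]:
    """Two-group count test on replicate read counts.

    Counts are library-size normalized (to the mean library size), given a
    +0.5 pseudo-count, and compared on the log2 scale with a two-sided
    Welch t test.  Returns (log2 fold-change of group means a/b, p).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per group")
    if lib_sizes_a is None:
        lib_sizes_a = np.ones_like(a)
    if lib_sizes_b is None:
        lib_sizes_b = np.ones_like(b)
    la = np.asarray(lib_sizes_a, dtype=float)
    lb = np.asarray(lib_sizes_b, dtype=float)
    scale = np.concatenate([la, lb]).mean()
    na = a * scale / la
    nb = b * scale / lb
    log_a = np.log2(na + 0.5)
    log_b = np.log2(nb + 0.5)
    log2fc = float(np.log2(na.mean() + 0.5) - np.log2(nb.mean() + 0.5))
    if np.allclose(log_a, log_a[0]) and np.allclose(log_b, log_b[0]) \
            and np.isclose(log_a[0], log_b[0]):
        return log2fc, 1.0   # identical constant groups: no evidence
    _, p = sstats.ttest_ind(log_a, log_b, equal_var=False)
    return log2fc, float(p)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values across regions."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
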