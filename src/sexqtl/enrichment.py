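"""Length- and count-matched interval shuffling and permutation enrichment.

The observed number of variants overlapping a feature set is compared to
the median overlap count across permutations in which the features are
re-placed uniformly at random — same number, same widths — inside a
universe of allowed segments (the toy genome, or the eQTL/eQTL∩TAD
intervals for locus-scoped questions).  Shuffled intervals may overlap
one another but never straddle a universe-segment boundary.

The enrichment ratio observed/expected is 1 under no enrichment; the
empirical p-value uses the +1 correction, so it is never exactly zero
and is bounded below by 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sstats

from .intervals import GenomicInterval
from .variants import FounderVariant, count_variants_overlapping


@dataclass(frozen=True)
class EnrichmentResult:
    observed: int
    expected: float           # median over permutations
    ratio: Optional[float]    # None when expected == 0
    empirical_p: float        # enrichment-sided: P(null >= observed)
    empirical_p_depletion: float   # mirrored: P(null <= observed)
    n_perm: int
    seed: int
    depleted: bool            # True when observed < expected


def shuffle_matched(regions: Sequence[GenomicInterval],
                    universe: Sequence[GenomicInterval],
                    rng: np.random.Generator) -> list[GenomicInterval]:
    """Place each region's width uniformly at random inside the universe.

    A region of width w can start at any of ``len(seg) - w + 1`` positions
    of a segment with ``len(seg) >= w``; segments are drawn with
    probability proportional to their number of valid starts, so
    placement is uniform over all admissible positions.
    """
    seg_lens = np.array([len(s) for s in universe], dtype=np.int64)
    out = []
    for region in regions:
        w = len(region)
        starts_per_seg = np.maximum(seg_lens - w + 1, 0)
        total = starts_per_seg.sum()
        if total == 0:
            raise ValueError(
                f"region of width {w} does not fit in any universe segment")
        seg_idx = rng.choice(len(universe), p=starts_per_seg / total)
        seg = universe[seg_idx]
        start = seg.start + int(rng.integers(0, seg_lens[seg_idx] - w + 1))
        out.append(GenomicInterval(seg.chrom, start, start + w))
    return out


def enrichment(variants: Sequence[FounderVariant],
               regions: Sequence[GenomicInterval],
               universe: Sequence[GenomicInterval],
               n_perm: int = 1000, seed: int = 0) -> EnrichmentResult:
    """Observed/expected variant overlap with an empirical p-value.

    observed — distinct variants overlapping >= 1 real region;
    expected — median of the same count over ``n_perm`` matched shuffles;
    empirical_p — (1 + #{permutation count >= observed}) / (n_perm + 1)
    for enrichment, with the mirrored (``<=``) depletion-side p reported
    alongside; the +1 correction keeps both strictly positive.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    by_chrom = _variant_arrays(variants)
    observed = _count_overlaps(by_chrom, regions)
    null = np.empty(n_perm)
    for p in range(n_perm):
        shuffled = shuffle_matched(regions, universe, rng)
        null[p] = _count_overlaps(by_chrom, shuffled)
    expected = float(np.median(null))
    depleted = observed < expected
    p_enrich = (1 + int((null >= observed).sum())) / (n_perm + 1)
    p_deplete = (1 + int((null <= observed).sum())) / (n_perm + 1)
    ratio = observed / expected if expected > 0 else None
    return EnrichmentResult(observed=observed, expected=expected, ratio=ratio,
                            empirical_p=p_enrich,
                            empirical_p_depletion=p_deplete,
                            n_perm=n_perm, seed=seed, depleted=depleted)


def _variant_arrays(variants: Sequence[FounderVariant]
                    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (start, end) arrays of variant reference footprints."""
    grouped: dict[str, list[tuple[int, int]]] = {}
    for v in variants:
        grouped.setdefault(v.chrom, []).append((v.pos, v.pos + len(v.ref)))
    return {c: (np.array([s for s, _ in sp]), np.array([e for _, e in sp]))
            for c, sp in grouped.items()}


def _count_overlaps(by_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
                    regions: Sequence[GenomicInterval]) -> int:
    """Distinct variants overlapping >= 1 region; the regions are merged
    into a disjoint union per chromosome first, so the count is a
    vectorized stab query.  Matches ``count_variants_overlapping``."""
    reg_by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        reg_by_chrom.setdefault(r.chrom, []).append(r)
    total = 0
    for chrom, (vs, ve) in by_chrom.items():
        regs = reg_by_chrom.get(chrom)
        if not regs:
            continue
        regs = sorted(regs, key=lambda r: r.start)
        starts, ends = [], []
        for r in regs:                      # merge into disjoint union
            if ends and r.start <= ends[-1]:
                ends[-1] = max(ends[-1], r.end)
            else:
                starts.append(r.start)
                ends.append(r.end)
        s = np.asarray(starts)
        e = np.asarray(ends)
        # union interval at or left of the variant start
        idx = np.searchsorted(s, vs, side="right") - 1
        hit = np.zeros(len(vs), dtype=bool)
        ok = idx >= 0
        hit[ok] = e[idx[ok]] > vs[ok]
        # or the next union interval begins before the variant end
        nxt = idx + 1
        ok = nxt < len(s)
        hit[ok] |= s[nxt[ok]] < ve[ok]
        total += int(hit.sum())
    return total


def enrichment_ratio(observed: float, expected: float) -> float:
    """Observed/expected summary (4,463 / 1,767 -> 2.53)."""
    if expected <= 0:
        raise ValueError("expected must be positive")
    return round(observed / expected, 2)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; thin adapter over scipy."""
    res = sstats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def kolmogorov_smirnov(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample two-sided KS test; thin adapter over scipy."""
    res = sstats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
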