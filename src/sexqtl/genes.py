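"""Sex-bias classification of genes across two inbred strains.

A gene is called sex-biased in one strain when its male/female expression
ratio clears a fold-change cutoff (default 2-fold) at an FDR below 0.05.
Comparing the two strains partitions genes into:

* ``strict_shared``   — fold-change and FDR cutoffs met in both strains;
* ``standard_shared`` — FDR met in both, fold-change in only one;
* ``b6_unique`` / ``cast_unique`` — both cutoffs met in one strain while
  the other strain's FDR exceeds the cutoff (clearly not sex-biased);
* ``none``            — anything else, including the ambiguous boundary
  where the other strain's FDR equals the cutoff exactly.

Shared genes are additionally scored for concordance (same direction of
sex bias in both strains) — discordant shared genes exist and are kept,
labelled ``concordant=False``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .intervals import GeneRecord, GenomicInterval, TadMap, tss_distance

logger = logging.getLogger(__name__)

STRAINS = ("B6", "CAST")

SHARE_CLASSES = ("strict_shared", "standard_shared", "b6_unique",
                 "cast_unique", "none")


@dataclass(frozen=True)
class StrainSexStats:
    """One strain's differential-expression summary for one gene."""

    log2fc_mf: float          # signed log2(male/female)
    fdr: float                # BH-adjusted p
    fpkm_male: float = 0.0
    fpkm_female: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr must be in [0,1], got {self.fdr}")
        if self.fpkm_male < 0 or self.fpkm_female < 0:
            raise ValueError("FPKM values must be non-negative")

    @property
    def direction(self) -> str:
        if self.log2fc_mf > 0:
            return "male"
        if self.log2fc_mf < 0:
            return "female"
        return "none"


@dataclass(frozen=True)
class GeneSexStats:
    gene_id: str
    by_strain: Mapping[str, StrainSexStats]

    def __post_init__(self) -> None:
        missing = [s for s in STRAINS if s not in self.by_strain]
        if missing:
            raise ValueError(f"{self.gene_id}: missing strain record(s) {missing}")


@dataclass(frozen=True)
class GeneBiasClass:
    gene_id: str
    share_class: str
    direction: Mapping[str, str]      # per-strain {male, female, none}
    concordant: Optional[bool]        # None when not a shared class


def classify_gene(stats: GeneSexStats, fc_cutoff: float = 2.0,
                  fdr_cutoff: float = 0.05) -> GeneBiasClass:
    """Assign the strain-sharing class for one gene.

    ``fc_cutoff`` is a linear fold-change (> 1); the test is
    ``|log2fc| >= log2(fc_cutoff)``.  FDR comparisons are strict (<) for
    significance and strict (>) for the uniqueness rule, so FDR exactly
    at the cutoff never supports a unique call.
    """
    if fc_cutoff <= 1:
        raise ValueError("fc_cutoff must exceed 1")
    lfc_cut = math.log2(fc_cutoff)
    b6, cast = stats.by_strain["B6"], stats.by_strain["CAST"]

    def passes_fc(s: StrainSexStats) -> bool:
        return abs(s.log2fc_mf) >= lfc_cut

    def sig(s: StrainSexStats) -> bool:
        return s.fdr < fdr_cutoff

    full_b6 = passes_fc(b6) and sig(b6)
    full_cast = passes_fc(cast) and sig(cast)

    if sig(b6) and sig(cast):
        if full_b6 and full_cast:
            share = "strict_shared"
        elif full_b6 or full_cast:
            share = "standard_shared"
        else:
            share = "none"
    elif full_b6 and cast.fdr > fdr_cutoff:
        share = "b6_unique"
    elif full_cast and b6.fdr > fdr_cutoff:
        share = "cast_unique"
    else:
        share = "none"

    direction = {
        "B6": b6.direction if sig(b6) else "none",
        "CAST": cast.direction if sig(cast) else "none",
    }
    concordant: Optional[bool] = None
    if share in ("strict_shared", "standard_shared"):
        if "none" not in (b6.direction, cast.direction):
            concordant = b6.direction == cast.direction
    return GeneBiasClass(stats.gene_id, share, direction, concordant)


def liver_specificity_z(expr_by_tissue: Sequence[float],
                        liver_index: int = 0) -> float:
    """Z score of the liver entry against the distribution over all
    tissues (liver included), using the population (1/n) SD.  Higher
    means more liver-specific.  All-equal input is defined as Z = 0.
    """
    x = np.asarray(expr_by_tissue, dtype=float)
    if x.size == 0:
        raise ValueError("empty expression vector")
    if x.size < 3:
        raise ValueError("need >= 3 tissues for a meaningful Z score")
    sd = float(x.std(ddof=0))
    if sd == 0.0:
        return 0.0
    return float((x[liver_index] - x.mean()) / sd)


def cre_distance_class(gene: GeneRecord,
                       cres: Iterable[GenomicInterval],
                       tads: TadMap,
                       proximal_bp: int = 20_000) -> str:
    """Proximal (< 20 kb), distal (>= 20 kb but inside the gene's TAD), or
    none.  ``cres`` must already be filtered to the matching direction and
    sharing pattern; this function only does geometry.
    """
    tad = tads.assign(gene.chrom, gene.tss)
    if tad is None:
        logger.warning("gene %s TSS in no TAD; distance class 'none'",
                       gene.gene_id)
        return "none"
    best: Optional[int] = None
    best_in_tad = False
    for cre in cres:
        d = tss_distance(gene, cre)
        if d is None:
            continue
        if best is None or d < best:
            best = d
            best_in_tad = (cre.chrom == tad.interval.chrom
                           and max(cre.start, tad.interval.start)
                           < min(cre.end, tad.interval.end))
    if best is None:
        return "none"
    if best < proximal_bp:
        return "proximal"
    if best_in_tad:
        return "distal"
    # nearest CRE is far and outside the TAD; any in-TAD CRE would have won
    for cre in cres:
        if (cre.chrom == tad.interval.chrom
                and max(cre.start, tad.interval.start)
                < min(cre.end, tad.interval.end)):
            return "distal"
    return "none"


def concordance_percent(shared_pairs: int, concordant: int) -> int:
    """Percent of shared calls with matching direction, to the nearest
    integer (e.g. 431 of 441 -> 98)."""
    if shared_pairs <= 0:
        raise ValueError("shared_pairs must be positive")
    if concordant > shared_pairs:
        raise ValueError("concordant cannot exceed shared_pairs")
    return round(100.0 * concordant / shared_pairs)
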