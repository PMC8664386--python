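"""Strain-specificity classification of variants across 8 founder strains.

A variant locus is a single reference position; an allele configuration
over the 8 Diversity Outbred founder strains classifies the locus
relative to one target strain:

* ``absent``             — the target carries the reference allele;
* ``conserved_unique``   — the target differs while all seven other
  founders match the reference (a private allele);
* ``nonconserved_unique``— the target differs, at least one other founder
  also differs, but no other founder carries the target's allele
  (e.g. A->T in CAST while A->C in PWK);
* ``shared``             — at least one other founder carries the
  identical non-reference allele.

"Strain-specific" in downstream analyses means conserved_unique or
nonconserved_unique for the regulating strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval

FOUNDERS = ("AJ", "B6", "129", "NOD", "NZO", "CAST", "PWK", "WSB")

VARIANT_CLASSES = ("conserved_unique", "nonconserved_unique", "shared", "absent")

STRAIN_SPECIFIC = frozenset({"conserved_unique", "nonconserved_unique"})


@dataclass(frozen=True)
class FounderVariant:
    """One locus with alleles across the 8 founders.

    ``pos`` is 0-based; an indel's footprint is the span of its reference
    allele (``pos`` to ``pos + len(ref)``).
    """

    chrom: str
    pos: int
    ref: str
    alleles: Mapping[str, str]       # founder -> allele string
    founders: Sequence[str] = FOUNDERS

    def __post_init__(self) -> None:
        missing = [f for f in self.founders if f not in self.alleles]
        if missing:
            raise ValueError(f"malformed founder mapping; missing {missing}")
        if all(self.alleles[f] == self.ref for f in self.founders):
            raise ValueError(
                f"{self.chrom}:{self.pos} matches reference in every founder; "
                "such records are not stored")

    @property
    def kind(self) -> str:
        alts = {self.alleles[f] for f in self.founders} | {self.ref}
        return "SNP" if all(len(a) == 1 for a in alts) else "indel"

    @property
    def footprint(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + len(self.ref))


def classify_variant(v: FounderVariant, target: str) -> str:
    """Class of ``v`` relative to one target founder strain."""
    if target not in v.founders:
        raise ValueError(f"unknown target strain {target!r}")
    mine = v.alleles[target]
    if mine == v.ref:
        return "absent"
    others = [v.alleles[f] for f in v.founders if f != target]
    if any(a == mine for a in others):
        return "shared"
    if all(a == v.ref for a in others):
        return "conserved_unique"
    return "nonconserved_unique"


def classify_catalog(variants: Iterable[FounderVariant],
                     target: str) -> pd.DataFrame:
    """Tabulate a catalog's classes for one target strain."""
    rows = [{"chrom": v.chrom, "pos": v.pos, "ref": v.ref,
             "kind": v.kind, "class": classify_variant(v, target)}
            for v in variants]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "kind", "class"])


def variants_in_regions(variants: Sequence[FounderVariant],
                        regions: Sequence[GenomicInterval]) -> list[dict]:
    """Per-region overlap table (>= 1 bp of the variant's reference
    footprint).  Variants overlapping several regions appear in each."""
    out = []
    for i, region in enumerate(regions):
        hits = [j for j, v in enumerate(variants)
                if v.chrom == region.chrom
                and max(v.pos, region.start) < min(v.pos + len(v.ref), region.end)]
        out.append({"region_index": i, "region": region,
                    "count": len(hits), "variant_indices": hits})
    return out


def count_variants_overlapping(variants: Sequence[FounderVariant],
                               regions: Sequence[GenomicInterval]) -> int:
    """Number of distinct variants overlapping >= 1 region (the observed
    count used in enrichment)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    n = 0
    for v in variants:
        end = v.pos + len(v.ref)
        for r in by_chrom.get(v.chrom, ()):
            if max(v.pos, r.start) < min(end, r.end):
                n += 1
                break
    return n


def mean_variant_spacing(genome_size: float, n_variants: int) -> int:
    """Average bp per variant, rounded to the nearest integer
    (2.8e9 bp / 10,195,846 strain-specific variants -> 275)."""
    if n_variants <= 0:
        raise ValueError("n_variants must be positive")
    return round(genome_size / n_variants)
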