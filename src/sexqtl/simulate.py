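"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of the study inputs —
per-strain differential-expression summaries, differential-region and
peak tables for H3K27ac and DNase assays, an 8-founder variant catalog,
eQTL scan summaries, TAD boundaries, and a small outbred cohort — with
effects planted at comfortable margins above every threshold so that the
classification layers recover the planted labels deterministically.

Layout conventions (all seeded, all pure functions of the config):

* TADs tile 90% of each chromosome with uniform gaps.
* Each eQTL blueprint owns one TAD; its credible interval, relevant CREs
  and strain-specific variants live inside it (or, for same-chromosome /
  trans blueprints, inside an inter-TAD gap), so no other blueprint's
  features can contaminate its search interval.
* Background genes, CREs and variants are confined to the remaining TADs
  and never overlap a blueprint search interval.
* Ground truth travels in sidecar tables that only tests and drivers
  read; pipeline-facing files carry no truth columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cres import ASSAY_FC_CUTOFF, CreRecord, DiffRegion
from .eqtl import (CATEGORY_TABLE, GAIN_SIDE, LOSS_SIDE, EqtlScanRecord,
                   ScanSet)
from .genes import GeneSexStats, StrainSexStats
from .intervals import GeneRecord, GenomicInterval, TadMap, TadRecord
from .variants import FOUNDERS, FounderVariant

IMPACTS_BY_SIDE = {
    "loss": ("loss", "reversal", "retained_reduced"),
    "gain": ("gain", "reversal", "retained_enhanced"),
}

CRE_CLASSES = ("one", "multiple", "none")

#: category -> (gene bias direction, stronger sex, coefficient sign)
CATEGORY_FACTORS = {v: k for k, v in CATEGORY_TABLE.items()}


@dataclass(frozen=True)
class EqtlBlueprint:
    """Planted design of one eQTL: what the pipeline must recover."""

    gene_id: str
    category: int
    regulating_strain: str        # B6 or CAST
    impact: str
    cre_class: str                # one / multiple / none
    position_class: str = "tad"   # tad / chromosome / trans
    with_all_set: bool = False    # also emit a significant 'all' scan
    merged_pair: bool = False     # realize 'one' as overlapping DHS+K27ac

    def __post_init__(self) -> None:
        if self.category not in range(1, 9):
            raise ValueError("category must be 1..8")
        side = "loss" if self.category in LOSS_SIDE else "gain"
        if self.impact not in IMPACTS_BY_SIDE[side]:
            raise ValueError(
                f"impact {self.impact!r} inconsistent with category "
                f"{self.category} (valid: {IMPACTS_BY_SIDE[side]})")
        if self.regulating_strain not in ("B6", "CAST"):
            raise ValueError("regulating strain must be B6 or CAST")
        if self.cre_class not in CRE_CLASSES:
            raise ValueError(f"cre_class must be one of {CRE_CLASSES}")


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 20_000_000
    n_tads_per_chrom: int = 30
    tad_coverage: float = 0.9
    n_genes: int = 200
    founders: Sequence[str] = FOUNDERS
    # background gene-class fractions (blueprint genes come on top)
    gene_class_fractions: dict = field(default_factory=lambda: {
        "strict_shared": 0.15, "standard_shared": 0.10,
        "b6_unique": 0.15, "cast_unique": 0.15, "none": 0.45})
    # expression planting margins (log2 units / FDR values)
    log2fc_strong: float = 2.0       # comfortably above log2(2) = 1
    log2fc_weak: float = 0.5         # comfortably below the cutoff
    fdr_sig: float = 1e-5
    fdr_nonsig: float = 0.5
    jitter: float = 0.1              # uniform jitter half-width on log2fc
    # replicate count emission
    n_replicates: int = 5
    base_mean: float = 200.0
    nb_dispersion: float = 0.1
    # background CREs / variants
    n_background_cres: int = 60      # per assay, split across patterns
    n_background_variants: int = 10_000
    variant_class_fractions: dict = field(default_factory=lambda: {
        "conserved_unique": 0.10, "nonconserved_unique": 0.10,
        "shared": 0.30, "absent": 0.50})
    variant_target: str = "CAST"
    # DO-style cohort
    cohort_size: int = 200
    n_loci: int = 20
    interaction_effect: float = 1.0
    interaction_locus: int = 0
    additive_effect: float = 0.5
    noise_sd: float = 1.0
    blueprints: Sequence[EqtlBlueprint] = ()

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "n_tads_per_chrom",
                     "n_genes", "n_replicates", "cohort_size", "n_loci"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.blueprints:
            self.blueprints = default_blueprints()


def default_blueprints() -> tuple[EqtlBlueprint, ...]:
    """The full cross: 8 categories x 3 impact classes x 3 CRE classes
    (72 blueprints), with B6/CAST regulating strains alternating and a
    sprinkling of non-TAD positions, merged DHS/K27ac pairs, and
    multi-set scans."""
    out = []
    i = 0
    for category in range(1, 9):
        side = "loss" if category in LOSS_SIDE else "gain"
        for impact in IMPACTS_BY_SIDE[side]:
            for cre_class in CRE_CLASSES:
                pos = "tad"
                if i % 9 == 4:
                    pos = "chromosome"
                elif i % 9 == 7:
                    pos = "trans"
                out.append(EqtlBlueprint(
                    gene_id=f"gene_{i:04d}",
                    category=category,
                    regulating_strain="CAST" if i % 2 == 0 else "B6",
                    impact=impact,
                    cre_class=cre_class,
                    position_class=pos,
                    with_all_set=(i % 5 == 0 and pos == "tad"),
                    merged_pair=(cre_class == "one" and i % 3 == 0),
                ))
                i += 1
    return tuple(out)


# ---------------------------------------------------------------- genome


@dataclass
class Genome:
    genes: list[GeneRecord]
    tads: TadMap
    chrom_sizes: dict[str, int]


def generate_genome(cfg: SimConfig, rng: np.random.Generator | None = None
                    ) -> Genome:
    """Non-overlapping TADs tiling ``tad_coverage`` of each chromosome;
    blueprint genes get one private TAD each, background genes share the
    remainder.  Deterministic under the config seed."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n_bp = len(cfg.blueprints)
    n_tads = cfg.n_chromosomes * cfg.n_tads_per_chrom
    if n_tads <= n_bp:
        raise ValueError(
            f"need more TADs ({n_tads}) than blueprints ({n_bp}); "
            "increase n_chromosomes or n_tads_per_chrom")
    chrom_sizes = {f"chr{i + 1}": cfg.chrom_length
                   for i in range(cfg.n_chromosomes)}
    tads: list[TadRecord] = []
    pitch = cfg.chrom_length // cfg.n_tads_per_chrom
    tad_len = int(pitch * cfg.tad_coverage)
    for chrom in chrom_sizes:
        for j in range(cfg.n_tads_per_chrom):
            start = j * pitch
            tads.append(TadRecord(f"{chrom}_tad{j}",
                                  GenomicInterval(chrom, start, start + tad_len)))
    tad_map = TadMap(tads)
    tad_list = list(tad_map)

    genes: list[GeneRecord] = []
    # blueprint genes: one per TAD, TSS in the central third so planted
    # features on either side stay inside the TAD
    for i, bp in enumerate(cfg.blueprints):
        tad = tad_list[i]
        lo = tad.interval.start + len(tad.interval) // 3
        hi = tad.interval.start + 2 * len(tad.interval) // 3
        tss = int(rng.integers(lo, hi))
        genes.append(GeneRecord(bp.gene_id, tad.interval.chrom, tss,
                                strand="+" if rng.random() < 0.5 else "-"))
    # background genes cycle through the remaining TADs
    bg_tads = tad_list[n_bp:]
    for k in range(cfg.n_genes - n_bp):
        tad = bg_tads[k % len(bg_tads)]
        tss = int(rng.integers(tad.interval.start, tad.interval.end))
        genes.append(GeneRecord(f"gene_{n_bp + k:04d}", tad.interval.chrom,
                                tss, strand="+" if rng.random() < 0.5 else "-"))
    return Genome(genes=genes, tads=tad_map, chrom_sizes=chrom_sizes)


# ------------------------------------------------------------ expression


def _strain_stats(rng: np.random.Generator, cfg: SimConfig, lfc: float,
                  sig: bool) -> StrainSexStats:
    jit = float(rng.uniform(-cfg.jitter, cfg.jitter))
    lfc = lfc + jit if lfc != 0 else jit
    fdr = cfg.fdr_sig * float(rng.uniform(0.1, 1.0)) if sig \
        else min(1.0, cfg.fdr_nonsig * float(rng.uniform(0.5, 1.5)))
    base = float(rng.lognormal(3.0, 1.0))
    return StrainSexStats(log2fc_mf=lfc, fdr=fdr,
                          fpkm_male=base * 2 ** (lfc / 2),
                          fpkm_female=base * 2 ** (-lfc / 2))


def _blueprint_expression(bp: EqtlBlueprint, cfg: SimConfig,
                          rng: np.random.Generator
                          ) -> tuple[dict[str, StrainSexStats], str, bool]:
    """Per-strain stats consistent with the blueprint's impact; returns
    (stats, expected share_class, expected concordance)."""
    bias_dir, _, _ = CATEGORY_FACTORS[bp.category]
    sign = 1.0 if bias_dir == "male" else -1.0
    reg, non = bp.regulating_strain, \
        ("CAST" if bp.regulating_strain == "B6" else "B6")
    s: dict[str, StrainSexStats] = {}
    if bp.impact == "loss":
        s[non] = _strain_stats(rng, cfg, sign * cfg.log2fc_strong, True)
        s[reg] = _strain_stats(rng, cfg, 0.0, False)
        share = "b6_unique" if non == "B6" else "cast_unique"
        concordant = None
    elif bp.impact == "gain":
        s[reg] = _strain_stats(rng, cfg, sign * cfg.log2fc_strong, True)
        s[non] = _strain_stats(rng, cfg, 0.0, False)
        share = "b6_unique" if reg == "B6" else "cast_unique"
        concordant = None
    elif bp.impact == "reversal":
        major, minor = (non, reg) if bp.category in LOSS_SIDE else (reg, non)
        s[major] = _strain_stats(rng, cfg, sign * (cfg.log2fc_strong + 0.5), True)
        s[minor] = _strain_stats(rng, cfg, -sign * (cfg.log2fc_strong - 0.5), True)
        share, concordant = "strict_shared", False
    else:   # retained_reduced / retained_enhanced
        major, minor = (non, reg) if bp.impact == "retained_reduced" else (reg, non)
        s[major] = _strain_stats(rng, cfg, sign * (cfg.log2fc_strong + 0.5), True)
        s[minor] = _strain_stats(rng, cfg, sign * (cfg.log2fc_strong - 0.5), True)
        share, concordant = "strict_shared", True
    return s, share, concordant


def generate_expression(cfg: SimConfig, genome: Genome,
                        rng: np.random.Generator | None = None
                        ) -> tuple[list[GeneSexStats], pd.DataFrame]:
    """Per-gene per-strain sex-bias summaries plus a truth table with the
    planted share class, direction and concordance."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    by_id = {bp.gene_id: bp for bp in cfg.blueprints}
    classes = list(cfg.gene_class_fractions)
    probs = np.array([cfg.gene_class_fractions[c] for c in classes])
    probs = probs / probs.sum()

    stats_out: list[GeneSexStats] = []
    truth_rows = []
    for gene in genome.genes:
        bp = by_id.get(gene.gene_id)
        if bp is not None:
            s, share, concordant = _blueprint_expression(bp, cfg, rng)
            direction = CATEGORY_FACTORS[bp.category][0]
        else:
            share = str(rng.choice(classes, p=probs))
            direction = "male" if rng.random() < 0.5 else "female"
            sign = 1.0 if direction == "male" else -1.0
            concordant = None
            if share == "strict_shared":
                s = {"B6": _strain_stats(rng, cfg, sign * cfg.log2fc_strong, True),
                     "CAST": _strain_stats(rng, cfg, sign * cfg.log2fc_strong, True)}
                concordant = True
            elif share == "standard_shared":
                s = {"B6": _strain_stats(rng, cfg, sign * cfg.log2fc_strong, True),
                     "CAST": _strain_stats(rng, cfg, sign * cfg.log2fc_weak, True)}
                concordant = True
            elif share == "b6_unique":
                s = {"B6": _strain_stats(rng, cfg, sign * cfg.log2fc_strong, True),
                     "CAST": _strain_stats(rng, cfg, 0.0, False)}
            elif share == "cast_unique":
                s = {"B6": _strain_stats(rng, cfg, 0.0, False),
                     "CAST": _strain_stats(rng, cfg, sign * cfg.log2fc_strong, True)}
            else:
                s = {"B6": _strain_stats(rng, cfg, 0.0, False),
                     "CAST": _strain_stats(rng, cfg, 0.0, False)}
                direction = "none"
        stats_out.append(GeneSexStats(gene.gene_id, s))
        truth_rows.append({"gene_id": gene.gene_id, "share_class": share,
                           "direction": direction, "concordant": concordant})
    return stats_out, pd.DataFrame(truth_rows)


def replicate_counts(cfg: SimConfig, stats: Sequence[GeneSexStats],
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Negative-binomial replicate count matrix per gene x strain x sex,
    group means encoding the planted fold-changes.  Dispersion 0 yields
    deterministic rounded means (sanity configs)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    rows = []
    for gs in stats:
        for strain, s in gs.by_strain.items():
            mean_m = cfg.base_mean * 2 ** (s.log2fc_mf / 2)
            mean_f = cfg.base_mean * 2 ** (-s.log2fc_mf / 2)
            for sex, mu in (("male", mean_m), ("female", mean_f)):
                counts = _nb_counts(rng, mu, cfg.nb_dispersion, cfg.n_replicates)
                for r, c in enumerate(counts):
                    rows.append({"gene_id": gs.gene_id, "strain": strain,
                                 "sex": sex, "replicate": r, "count": int(c)})
    return pd.DataFrame(rows)


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float,
               n: int) -> np.ndarray:
    if dispersion <= 0:
        return np.full(n, round(mean))
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p, n)


# ------------------------------------------------------------ CRE landscape


@dataclass
class CreLandscape:
    diff_regions: dict[tuple[str, str], list[DiffRegion]]   # (strain, assay)
    peaks: dict[tuple[str, str], list[GenomicInterval]]
    truth: pd.DataFrame          # planted direction/strain/share per CRE
    relevant_variants: list[FounderVariant]   # variants planted inside CREs


def _cre_diff(interval: GenomicInterval, assay: str, strain: str,
              direction: str, cfg: SimConfig,
              rng: np.random.Generator) -> DiffRegion:
    margin = 0.5 + float(rng.uniform(0, 0.3))
    lfc = np.log2(ASSAY_FC_CUTOFF[assay]) + margin
    if direction == "female":
        lfc = -lfc
    return DiffRegion(interval=interval, assay=assay, strain=strain,
                      log2fc_mf=float(lfc), fdr=cfg.fdr_sig,
                      max_group_count=30)


def generate_cre_landscape(cfg: SimConfig, genome: Genome,
                           search_intervals: dict[str, GenomicInterval],
                           rng: np.random.Generator | None = None
                           ) -> CreLandscape:
    """Peaks + differential regions realizing every blueprint's relevant
    CREs (with decoys) plus a background of shared / unique CREs in the
    non-blueprint TADs.

    ``search_intervals`` maps blueprint gene_id to the interval the engine
    will search (prepared by :func:`generate_eqtl_scans`).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 3)
    diffs: dict[tuple[str, str], list[DiffRegion]] = {
        (s, a): [] for s in ("B6", "CAST") for a in ("K27ac", "DHS")}
    peaks: dict[tuple[str, str], list[GenomicInterval]] = {
        (s, a): [] for s in ("B6", "CAST") for a in ("K27ac", "DHS")}
    truth_rows = []
    planted_variants: list[FounderVariant] = []

    def emit(interval: GenomicInterval, assay: str, strain: str,
             direction: str, share: str, role: str) -> None:
        diffs[(strain, assay)].append(
            _cre_diff(interval, assay, strain, direction, cfg, rng))
        pad = 100
        peaks[(strain, assay)].append(GenomicInterval(
            interval.chrom, max(0, interval.start - pad), interval.end + pad))
        truth_rows.append({"chrom": interval.chrom, "start": interval.start,
                           "end": interval.end, "assay": assay,
                           "strain": strain, "direction": direction,
                           "share_class": share, "role": role})

    def plant_variant(interval: GenomicInterval, reg: str, kind: str) -> None:
        """kind: 'specific' (conserved-unique for reg) or 'irrelevant'
        (reg matches reference)."""
        pos = (interval.start + interval.end) // 2
        alleles = {f: "A" for f in cfg.founders}
        if kind == "specific":
            alleles[reg] = "T"
        else:
            other = next(f for f in cfg.founders if f not in ("B6", "CAST"))
            alleles[other] = "G"
        planted_variants.append(FounderVariant(
            chrom=interval.chrom, pos=pos, ref="A", alleles=alleles,
            founders=tuple(cfg.founders)))

    # --- blueprint-owned CREs -------------------------------------------
    for bp in cfg.blueprints:
        search = search_intervals[bp.gene_id]
        bias_dir = CATEGORY_FACTORS[bp.category][0]
        reg = bp.regulating_strain
        non = "CAST" if reg == "B6" else "B6"
        host = non if bp.category in LOSS_SIDE else reg   # strain holding the CRE
        share = "b6_unique" if host == "B6" else "cast_unique"
        w = 800
        slots = [search.start + 5_000 + k * 9_000 for k in range(6)]
        n_qual = {"one": 1, "multiple": 2, "none": 0}[bp.cre_class]
        si = 0
        for q in range(n_qual):
            start = slots[si]; si += 1
            iv = GenomicInterval(search.chrom, start, start + w)
            if q == 0 and bp.merged_pair:
                outer = GenomicInterval(search.chrom, start - 200, start + w + 400)
                emit(outer, "K27ac", host, bias_dir, share, "relevant")
                emit(iv, "DHS", host, bias_dir, share, "relevant")
            else:
                assay = "K27ac" if q % 2 == 0 else "DHS"
                emit(iv, assay, host, bias_dir, share, "relevant")
            plant_variant(iv, reg, "specific")
        # decoys: never qualify
        start = slots[si]; si += 1
        iv = GenomicInterval(search.chrom, start, start + w)
        opposite = "female" if bias_dir == "male" else "male"
        emit(iv, "K27ac", host, opposite, share, "decoy_direction")
        plant_variant(iv, reg, "specific")
        start = slots[si]; si += 1
        iv = GenomicInterval(search.chrom, start, start + w)
        emit(iv, "K27ac", "B6", bias_dir, "shared", "decoy_shared")
        emit(iv, "K27ac", "CAST", bias_dir, "shared", "decoy_shared")
        plant_variant(iv, reg, "specific")
        start = slots[si]; si += 1
        iv = GenomicInterval(search.chrom, start, start + w)
        emit(iv, "DHS", host, bias_dir, share, "decoy_no_variant")
        plant_variant(iv, reg, "irrelevant")

    # --- background CREs in non-blueprint TADs --------------------------
    bg_tads = list(genome.tads)[len(cfg.blueprints):]
    n_bg = cfg.n_background_cres
    patterns = itertools.cycle(
        ["shared_concordant", "shared_discordant", "b6_unique", "cast_unique"])
    for assay in ("K27ac", "DHS"):
        for k in range(n_bg):
            tad = bg_tads[int(rng.integers(0, len(bg_tads)))]
            start = int(rng.integers(tad.interval.start,
                                     tad.interval.end - 1_000))
            iv = GenomicInterval(tad.interval.chrom, start, start + 600)
            direction = "male" if rng.random() < 0.5 else "female"
            pattern = next(patterns)
            if pattern == "shared_concordant":
                emit(iv, assay, "B6", direction, "shared", "background")
                emit(iv, assay, "CAST", direction, "shared", "background")
            elif pattern == "shared_discordant":
                other_dir = "female" if direction == "male" else "male"
                emit(iv, assay, "B6", direction, "shared", "background")
                emit(iv, assay, "CAST", other_dir, "shared", "background")
            elif pattern == "b6_unique":
                emit(iv, assay, "B6", direction, "b6_unique", "background")
            else:
                emit(iv, assay, "CAST", direction, "cast_unique", "background")

    # sex-independent robust peaks (direction none): peak universe only
    for (strain, assay) in peaks:
        for _ in range(n_bg // 2):
            tad = bg_tads[int(rng.integers(0, len(bg_tads)))]
            start = int(rng.integers(tad.interval.start,
                                     tad.interval.end - 1_000))
            peaks[(strain, assay)].append(
                GenomicInterval(tad.interval.chrom, start, start + 600))

    return CreLandscape(diff_regions=diffs, peaks=peaks,
                        truth=pd.DataFrame(truth_rows),
                        relevant_variants=planted_variants)


# -------------------------------------------------------------- variants


def generate_variants(cfg: SimConfig, genome: Genome,
                      exclude: Sequence[GenomicInterval] = (),
                      rng: np.random.Generator | None = None
                      ) -> tuple[list[FounderVariant], pd.DataFrame]:
    """Background catalog with classes planted at the configured
    fractions for ``variant_target``; positions avoid ``exclude``
    (the blueprint search intervals)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 4)
    target = cfg.variant_target
    other = next(f for f in cfg.founders if f not in ("B6", "CAST", target))
    classes = list(cfg.variant_class_fractions)
    probs = np.array([cfg.variant_class_fractions[c] for c in classes])
    probs = probs / probs.sum()
    chroms = list(genome.chrom_sizes)
    excl_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in exclude:
        excl_by_chrom.setdefault(iv.chrom, []).append(iv)

    out: list[FounderVariant] = []
    truth_rows = []
    taken: set[tuple[str, int]] = set()
    while len(out) < cfg.n_background_variants:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(0, genome.chrom_sizes[chrom]))
        if (chrom, pos) in taken:   # one record per locus
            continue
        if any(iv.start <= pos < iv.end for iv in excl_by_chrom.get(chrom, ())):
            continue
        taken.add((chrom, pos))
        cls = str(rng.choice(classes, p=probs))
        alleles = {f: "A" for f in cfg.founders}
        if cls == "conserved_unique":
            alleles[target] = "T"
        elif cls == "nonconserved_unique":
            alleles[target] = "T"
            alleles[other] = "C"
        elif cls == "shared":
            alleles[target] = "T"
            alleles[other] = "T"
        else:   # absent for target; some other founder differs
            alleles[other] = "T"
        out.append(FounderVariant(chrom=chrom, pos=pos, ref="A",
                                  alleles=alleles, founders=tuple(cfg.founders)))
        truth_rows.append({"chrom": chrom, "pos": pos, "class": cls,
                           "target": target})
    return out, pd.DataFrame(truth_rows)


# ------------------------------------------------------------- eQTL scans


def generate_eqtl_scans(cfg: SimConfig, genome: Genome,
                        rng: np.random.Generator | None = None
                        ) -> tuple[list[EqtlScanRecord],
                                   dict[str, GenomicInterval], pd.DataFrame]:
    """Scan records inverting the category mapping: planted stronger sex,
    coefficient sign and regulating strain, credible intervals placed per
    position class.  Returns (records, search interval per gene, truth).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 5)
    tad_list = list(genome.tads)
    genes_by_id = {g.gene_id: g for g in genome.genes}
    chroms = list(genome.chrom_sizes)
    pitch = cfg.chrom_length // cfg.n_tads_per_chrom
    tad_len = int(pitch * cfg.tad_coverage)
    gap = pitch - tad_len
    # inter-TAD gaps double as homes for non-TAD eQTL intervals; each is
    # handed out once so no two blueprints' features can collide
    free_gaps: dict[str, list[int]] = {
        c: list(range(cfg.n_tads_per_chrom)) for c in chroms}

    def take_gap(chrom: str) -> GenomicInterval:
        if not free_gaps[chrom]:
            raise ValueError(f"no free inter-TAD gap left on {chrom}")
        j = free_gaps[chrom].pop(0)
        start = j * pitch + tad_len + 1_000
        return GenomicInterval(chrom, start,
                               start + min(80_000, gap - 2_000))

    records, truth_rows = [], []
    search: dict[str, GenomicInterval] = {}
    for i, bp in enumerate(cfg.blueprints):
        gene = genes_by_id[bp.gene_id]
        bias_dir, stronger_sex, coef_sign = CATEGORY_FACTORS[bp.category]
        tad = tad_list[i]

        if bp.position_class == "tad":
            # credible interval inside the gene's own TAD
            lo = tad.interval.start + 2_000
            interval = GenomicInterval(tad.interval.chrom, lo,
                                       lo + min(120_000, len(tad.interval) // 3))
        elif bp.position_class == "chromosome":
            interval = take_gap(gene.chrom)
        else:   # trans
            interval = take_gap(next(c for c in chroms if c != gene.chrom))
        search[bp.gene_id] = interval

        coef = {f: float(rng.uniform(-0.25, 0.25)) for f in cfg.founders}
        coef[bp.regulating_strain] = (1.0 if coef_sign == "+" else -1.0) \
            * float(rng.uniform(0.9, 1.1))
        weak_coef = {f: float(rng.uniform(-0.25, 0.25)) or 0.01
                     for f in cfg.founders}

        lod_strong = 10.0 + float(rng.uniform(0, 5))
        lod_weak = 1.0 + float(rng.uniform(0, 2))
        sets = {
            stronger_sex: ScanSet(significant=True, lod=lod_strong,
                                  coef=coef, interval=interval),
            ("female" if stronger_sex == "male" else "male"):
                ScanSet(significant=False, lod=lod_weak, coef=weak_coef),
        }
        if bp.with_all_set:
            wider = GenomicInterval(interval.chrom,
                                    max(0, interval.start - 20_000),
                                    interval.end + 20_000)
            sets["all"] = ScanSet(significant=True,
                                  lod=lod_strong - 1.0, coef=dict(coef),
                                  interval=wider)
        records.append(EqtlScanRecord(gene_id=bp.gene_id, sets=sets))
        truth_rows.append({
            "gene_id": bp.gene_id, "category": bp.category,
            "impact": bp.impact, "cre_class": bp.cre_class,
            "position_class": bp.position_class,
            "regulating_strain": bp.regulating_strain,
            "stronger_sex": stronger_sex, "coef_sign": coef_sign,
            "bias_direction": bias_dir})
    return records, search, pd.DataFrame(truth_rows)


# -------------------------------------------------------------- DO cohort


def generate_do_cohort(cfg: SimConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort table (sex, diet, batch covariates, biallelic dosages,
    phenotype) with one planted genotype x sex interaction locus, plus a
    truth table of per-locus effects.  ``interaction_effect=0`` yields a
    null cohort."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 6)
    n = cfg.cohort_size
    sex = (np.arange(n) % 2).astype(float)     # balanced
    diet = rng.integers(0, 2, n).astype(float)
    batch = rng.normal(size=n)
    geno = rng.binomial(2, 0.5, size=(n, cfg.n_loci)).astype(float)

    effects = np.zeros(cfg.n_loci)
    inter = np.zeros(cfg.n_loci)
    if cfg.interaction_effect != 0:
        effects[cfg.interaction_locus] = cfg.additive_effect
        inter[cfg.interaction_locus] = cfg.interaction_effect
    phenotype = (0.5 * diet + 0.3 * batch + 0.2 * sex + 0.1 * sex * diet
                 + geno @ effects + (geno * sex[:, None]) @ inter
                 + rng.normal(scale=cfg.noise_sd, size=n))
    df = pd.DataFrame({"individual_id": [f"DO_{i:04d}" for i in range(n)],
                       "sex": sex, "diet": diet, "batch": batch,
                       "sex_diet": sex * diet})
    for j in range(cfg.n_loci):
        df[f"locus_{j}"] = geno[:, j]
    df["phenotype"] = phenotype
    truth = pd.DataFrame({"locus": [f"locus_{j}" for j in range(cfg.n_loci)],
                          "additive_effect": effects,
                          "interaction_effect": inter})
    return df, truth


# ----------------------------------------------------------------- bundle


@dataclass
class SimBundle:
    """Everything one simulated study provides, truth in sidecars."""

    config: SimConfig
    genome: Genome
    gene_stats: list[GeneSexStats]
    gene_truth: pd.DataFrame
    landscape: CreLandscape
    variants: list[FounderVariant]
    variant_truth: pd.DataFrame
    scans: list[EqtlScanRecord]
    search_intervals: dict[str, GenomicInterval]
    eqtl_truth: pd.DataFrame
    cohort: pd.DataFrame
    cohort_truth: pd.DataFrame

    @property
    def all_variants(self) -> list[FounderVariant]:
        return self.variants + self.landscape.relevant_variants


def simulate(cfg: SimConfig | None = None, seed: int | None = None) -> SimBundle:
    """Run every generator off one root seed (stage-keyed sub-seeds)."""
    cfg = cfg if cfg is not None else SimConfig()
    if seed is not None:
        cfg = replace_seed(cfg, seed)
    genome = generate_genome(cfg)
    gene_stats, gene_truth = generate_expression(cfg, genome)
    scans, search, eqtl_truth = generate_eqtl_scans(cfg, genome)
    landscape = generate_cre_landscape(cfg, genome, search)
    variants, variant_truth = generate_variants(
        cfg, genome, exclude=list(search.values()))
    cohort, cohort_truth = generate_do_cohort(cfg)
    return SimBundle(config=cfg, genome=genome, gene_stats=gene_stats,
                     gene_truth=gene_truth, landscape=landscape,
                     variants=variants, variant_truth=variant_truth,
                     scans=scans, search_intervals=search,
                     eqtl_truth=eqtl_truth, cohort=cohort,
                     cohort_truth=cohort_truth)


def replace_seed(cfg: SimConfig, seed: int) -> SimConfig:
    import dataclasses
    return dataclasses.replace(cfg, seed=seed)
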