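"""eQTL mechanism annotation for sex-biased genes.

Each gene x locus association carries up to three scans (all animals,
males only, females only), each with a significance flag, a 95% credible
interval, a LOD score, and one regression coefficient per founder strain.
The engine:

1. assigns the regulating strain(s) — the founder with the largest
   |coefficient|, plus any founder within 20% of that maximum;
2. narrows the genomic search space — shortest qualifying credible
   interval, their intersection when several scans qualify, and the
   eQTL∩TAD span when the eQTL overlaps the TAD holding the gene's TSS;
3. places the eQTL relative to its gene (intra-TAD / same chromosome /
   trans);
4. maps the (gene sex-bias, stronger-sex scan, coefficient sign) cube to
   mechanism categories 1-8 — a bijection over the 8 corners;
5. calls the impact on sex-biased expression between strains
   (gain / loss / reversal / retained);
6. counts "relevant CREs" — strain-unique sex-biased regulatory regions
   inside the search interval, direction-matched to the gene, carrying a
   strain-specific variant of the regulating strain, with overlapping
   DHS/H3K27ac merged so a compound element counts once.

Category semantics: a male-biased gene gives odd-side categories
{1,3,5,7}; an eQTL stronger in males gives {1,2,5,6}; a negative
coefficient (repression in the stronger sex) gives {1,4,6,7}.
Categories 1-4 weaken or remove sex bias in the regulating strain;
5-8 create or enhance it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .cres import CreRecord
from .genes import GeneSexStats
from .intervals import (GeneRecord, GenomicInterval, TadMap, intersect,
                        overlaps)
from .variants import STRAIN_SPECIFIC, FounderVariant, classify_variant

SCAN_SETS = ("all", "male", "female")

#: (gene bias, stronger sex, coefficient sign) -> category
CATEGORY_TABLE: dict[tuple[str, str, str], int] = {
    ("male",   "male",   "-"): 1,
    ("female", "male",   "+"): 2,
    ("male",   "female", "+"): 3,
    ("female", "female", "-"): 4,
    ("male",   "male",   "+"): 5,
    ("female", "male",   "-"): 6,
    ("male",   "female", "-"): 7,
    ("female", "female", "+"): 8,
}

LOSS_SIDE = frozenset({1, 2, 3, 4})   # weaken/remove sex bias
GAIN_SIDE = frozenset({5, 6, 7, 8})   # create/enhance sex bias

UNIQUE_LABEL = {"B6": "b6_unique", "CAST": "cast_unique"}


@dataclass(frozen=True)
class ScanSet:
    """One analysis set (all / male / female) of an eQTL scan."""

    significant: bool
    lod: float
    coef: Mapping[str, float]
    interval: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if self.lod < 0:
            raise ValueError("LOD must be non-negative")
        if self.significant and self.interval is None:
            raise ValueError("significant scan set requires a credible interval")


@dataclass(frozen=True)
class EqtlScanRecord:
    gene_id: str
    sets: Mapping[str, ScanSet]   # keys from SCAN_SETS

    def __post_init__(self) -> None:
        unknown = set(self.sets) - set(SCAN_SETS)
        if unknown:
            raise ValueError(f"unknown scan sets {unknown}")


@dataclass
class EqtlAnnotation:
    gene_id: str
    regulating_strains: tuple[str, ...]
    regulating_strain: Optional[str]          # the B6/CAST member, if any
    chosen_interval: Optional[GenomicInterval]
    intersected_interval: Optional[GenomicInterval]
    tad_interval: Optional[GenomicInterval]
    position_class: Optional[str]
    category: Optional[int]
    impact: Optional[str]
    relevant_cre_class: Optional[str]
    delta_lod: Optional[float] = None
    robust: Optional[bool] = None


def assign_regulating_strains(coef: Mapping[str, float],
                              band: float = 0.20) -> tuple[str, ...]:
    """Founders ordered by |coefficient|, keeping the maximum and any
    founder within ``band`` (default 20%) of it.  Ties order
    alphabetically."""
    if all(c == 0 for c in coef.values()):
        raise ValueError("all regression coefficients are zero")
    top = max(abs(c) for c in coef.values())
    keep = [(s, c) for s, c in coef.items() if abs(c) >= (1 - band) * top]
    keep.sort(key=lambda sc: (-abs(sc[1]), sc[0]))
    return tuple(s for s, _ in keep)


def select_interval(rec: EqtlScanRecord, strain_filter: str,
                    band: float = 0.20
                    ) -> tuple[GenomicInterval, Optional[GenomicInterval]]:
    """Shortest credible interval among the scan sets that are significant
    with ``strain_filter`` as a (co-)regulating strain, plus the
    intersection of all qualifying intervals when two or more qualify and
    mutually overlap."""
    qualifying = []
    for name in SCAN_SETS:
        s = rec.sets.get(name)
        if s is None or not s.significant:
            continue
        if strain_filter in assign_regulating_strains(s.coef, band):
            qualifying.append(s.interval)
    if not qualifying:
        raise ValueError(
            f"{rec.gene_id}: no scan set significant with {strain_filter} regulating")
    chosen = min(qualifying, key=len)
    intersected: Optional[GenomicInterval] = None
    if len(qualifying) >= 2:
        acc: Optional[GenomicInterval] = qualifying[0]
        for iv in qualifying[1:]:
            if acc is None:
                break
            acc = intersect(acc, iv)
        intersected = acc
    return chosen, intersected


def position_class(eqtl_interval: GenomicInterval, gene: GeneRecord,
                   tads: TadMap
                   ) -> tuple[str, Optional[GenomicInterval]]:
    """Place the eQTL relative to its regulated gene.

    ``tad`` when the eQTL overlaps the TAD containing the gene's TSS
    (also returns the eQTL∩TAD span); ``chromosome`` for same-chromosome
    placement outside that TAD (or for genes in no TAD); ``trans`` across
    chromosomes."""
    if eqtl_interval.chrom != gene.chrom:
        return "trans", None
    tad = tads.assign(gene.chrom, gene.tss)
    if tad is not None and overlaps(eqtl_interval, tad.interval):
        return "tad", intersect(eqtl_interval, tad.interval)
    return "chromosome", None


def categorize_eqtl(gene_bias_sign: str, stronger_sex: str,
                    coef_sign: str) -> int:
    """Map the three resolved factors to a mechanism category 1-8."""
    key = (gene_bias_sign, stronger_sex, coef_sign)
    if key not in CATEGORY_TABLE:
        raise ValueError(f"unresolvable factor combination {key}")
    return CATEGORY_TABLE[key]


def classify_impact(category: int,
                    bias_regulating: tuple[str, bool],
                    bias_nonregulating: tuple[str, bool]) -> str:
    """Impact of the eQTL on between-strain sex bias.

    Each bias argument is (direction, significant) for the strain, where
    significance is FDR < 0.05 with no fold-change requirement.
    """
    if category not in range(1, 9):
        raise ValueError(f"category must be 1..8, got {category}")
    dir_reg, sig_reg = bias_regulating
    dir_non, sig_non = bias_nonregulating
    if sig_reg and sig_non:
        if dir_reg != dir_non:
            return "reversal"
        return "retained_reduced" if category in LOSS_SIDE else "retained_enhanced"
    if category in LOSS_SIDE and sig_non and not sig_reg:
        return "loss"
    if category in GAIN_SIDE and sig_reg and not sig_non:
        return "gain"
    return "none"


def merge_cre_components(cres: Sequence[CreRecord]) -> list[list[CreRecord]]:
    """Single-linkage merge of CREs by >= 1 bp overlap, across assays, so
    a DHS nested in an H3K27ac peak counts as one element."""
    n = len(cres)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if overlaps(cres[i].interval, cres[j].interval):
                parent[find(i)] = find(j)
    groups: dict[int, list[CreRecord]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(cres[i])
    return list(groups.values())


def count_relevant_cres(category: int, regulating_strain: str,
                        gene_bias_sign: str,
                        search_interval: GenomicInterval,
                        cres: Sequence[CreRecord],
                        variants: Sequence[FounderVariant]) -> str:
    """Count CREs that plausibly explain the eQTL's effect.

    A candidate CRE lies in the search interval (>= 1 bp overlap), has the
    gene's direction of sex bias, is strain-unique with the category's
    polarity (categories 1-4: present only in the NON-regulating strain,
    i.e. lost in the regulating strain; 5-8: present only in the
    regulating strain), and overlaps >= 1 strain-specific variant of the
    regulating strain.  Overlapping candidates merge before counting.
    Returns 'one', 'multiple', or 'none'.
    """
    if regulating_strain not in UNIQUE_LABEL:
        raise ValueError(f"regulating strain must be B6 or CAST, "
                         f"got {regulating_strain!r}")
    if category in LOSS_SIDE:
        other = "CAST" if regulating_strain == "B6" else "B6"
        wanted_share = UNIQUE_LABEL[other]
    else:
        wanted_share = UNIQUE_LABEL[regulating_strain]

    specific = [v for v in variants
                if classify_variant(v, regulating_strain) in STRAIN_SPECIFIC]

    def has_variant(cre: CreRecord) -> bool:
        return any(v.chrom == cre.interval.chrom
                   and max(v.pos, cre.interval.start)
                   < min(v.pos + len(v.ref), cre.interval.end)
                   for v in specific)

    candidates = [c for c in cres
                  if c.direction == gene_bias_sign
                  and c.share_class == wanted_share
                  and overlaps(c.interval, search_interval)
                  and has_variant(c)]
    n = len(merge_cre_components(candidates))
    return "none" if n == 0 else ("one" if n == 1 else "multiple")


def scan_records_to_frame(records: Sequence[EqtlScanRecord],
                          founders: Sequence[str]) -> "pd.DataFrame":
    """Wide TSV layout: one row per gene x set with 8 coefficient columns,
    LOD, significance and interval coordinates."""
    import pandas as pd
    rows = []
    for rec in records:
        for name in SCAN_SETS:
            s = rec.sets.get(name)
            if s is None:
                continue
            row = {"gene_id": rec.gene_id, "set": name,
                   "significant": s.significant, "lod": s.lod,
                   "chrom": s.interval.chrom if s.interval else "",
                   "start": s.interval.start if s.interval else -1,
                   "end": s.interval.end if s.interval else -1}
            for f in founders:
                row[f"coef_{f}"] = s.coef.get(f, 0.0)
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_scan_records(df: "pd.DataFrame",
                          founders: Sequence[str]) -> list[EqtlScanRecord]:
    """Inverse of :func:`scan_records_to_frame`."""
    records = []
    for gene_id, grp in df.groupby("gene_id", sort=False):
        sets = {}
        for _, row in grp.iterrows():
            interval = None
            if row["start"] >= 0:
                interval = GenomicInterval(str(row["chrom"]),
                                           int(row["start"]), int(row["end"]))
            sets[row["set"]] = ScanSet(
                significant=bool(row["significant"]), lod=float(row["lod"]),
                coef={f: float(row[f"coef_{f}"]) for f in founders},
                interval=interval)
        records.append(EqtlScanRecord(gene_id=str(gene_id), sets=sets))
    return records


def gene_bias_sign_from_stats(stats: GeneSexStats) -> Optional[str]:
    """Sign of the largest-|log2fc| strain among significantly sex-biased
    strains (FDR < 0.05), falling back to all strains when none are
    significant.  None when every fold-change is zero."""
    records = [s for s in stats.by_strain.values() if s.fdr < 0.05]
    if not records:
        records = list(stats.by_strain.values())
    best = max(records, key=lambda s: abs(s.log2fc_mf))
    if best.log2fc_mf == 0:
        return None
    return "male" if best.log2fc_mf > 0 else "female"


def annotate_eqtl(rec: EqtlScanRecord, gene: GeneRecord,
                  gene_stats: GeneSexStats, tads: TadMap,
                  cres: Sequence[CreRecord],
                  variants: Sequence[FounderVariant],
                  band: float = 0.20,
                  fdr_cutoff: float = 0.05) -> EqtlAnnotation:
    """Full annotation of one eQTL: regulating strain, interval funnel,
    position class, category, impact, relevant-CRE count."""
    male, female = rec.sets.get("male"), rec.sets.get("female")

    # stronger sex by LOD of the single-sex scans; exact tie -> unclassifiable
    stronger_sex: Optional[str] = None
    if male is not None and female is not None and male.lod != female.lod:
        stronger_sex = "male" if male.lod > female.lod else "female"

    # the B6/CAST (co-)regulating strain in the stronger-sex scan
    regulating: Optional[str] = None
    coef_sign: Optional[str] = None
    stronger = rec.sets.get(stronger_sex) if stronger_sex else None
    if stronger is not None and stronger.significant:
        reg_set = assign_regulating_strains(stronger.coef, band)
        for s in reg_set:
            if s in ("B6", "CAST"):
                regulating = s
                coef_sign = "+" if stronger.coef[s] > 0 else "-"
                break

    bias_sign = gene_bias_sign_from_stats(gene_stats)

    category: Optional[int] = None
    if regulating is not None and stronger_sex is not None and bias_sign is not None:
        category = categorize_eqtl(bias_sign, stronger_sex, coef_sign)

    chosen = intersected = tad_iv = None
    pos_class: Optional[str] = None
    if regulating is not None:
        chosen, intersected = select_interval(rec, regulating, band)
        pos_class, tad_iv = position_class(chosen, gene, tads)

    impact: Optional[str] = None
    cre_class: Optional[str] = None
    if category is not None:
        non_reg = "CAST" if regulating == "B6" else "B6"
        sreg = gene_stats.by_strain[regulating]
        snon = gene_stats.by_strain[non_reg]
        impact = classify_impact(
            category,
            (sreg.direction, sreg.fdr < fdr_cutoff),
            (snon.direction, snon.fdr < fdr_cutoff))
        search = tad_iv if pos_class == "tad" and tad_iv is not None else chosen
        cre_class = count_relevant_cres(
            category, regulating, bias_sign, search, cres, variants)

    reg_strains = ()
    if stronger is not None and stronger.significant:
        reg_strains = assign_regulating_strains(stronger.coef, band)

    return EqtlAnnotation(
        gene_id=rec.gene_id,
        regulating_strains=reg_strains,
        regulating_strain=regulating,
        chosen_interval=chosen,
        intersected_interval=intersected,
        tad_interval=tad_iv,
        position_class=pos_class,
        category=category,
        impact=impact,
        relevant_cre_class=cre_class,
    )
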