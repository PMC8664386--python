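"""End-to-end orchestration: simulate (or load), classify, annotate,
summarize, with a JSON manifest for reproducibility.

Stage order follows the dependency chain: gene classes -> robust CREs and
sharing -> variant classes -> eQTL annotation (category, impact, relevant
CREs) -> enrichment -> interaction scan.  All thresholds flow from a
config mapping, never from in-line constants.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .cres import CreRecord, DiffRegion, call_robust_regions, classify_cre_sharing
from .enrichment import enrichment
from .eqtl import annotate_eqtl, scan_records_to_frame
from .genes import GeneSexStats, StrainSexStats, classify_gene
from .intervals import GenomicInterval, TadMap
from .interaction import Cohort, permutation_threshold
from .simulate import SimBundle, SimConfig, simulate
from .variants import classify_catalog

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "fc_cutoff": 2.0, "fdr": 0.05, "min_count_chip": 15, "min_count_dhs": 10,
    "promoter_bp": 2500, "proximal_bp": 20000, "coef_band": 0.20,
    "n_perm": 1000, "alpha": 0.05,
}


# ------------------------------------------------------------- stage runs


def classify_genes_stage(stats: Sequence[GeneSexStats],
                         fc_cutoff: float = 2.0,
                         fdr_cutoff: float = 0.05) -> pd.DataFrame:
    rows = []
    for gs in stats:
        c = classify_gene(gs, fc_cutoff=fc_cutoff, fdr_cutoff=fdr_cutoff)
        rows.append({"gene_id": c.gene_id, "share_class": c.share_class,
                     "direction_B6": c.direction["B6"],
                     "direction_CAST": c.direction["CAST"],
                     "concordant": c.concordant})
    return pd.DataFrame(rows)


def call_cres_stage(diff_regions: Mapping[tuple[str, str], Sequence[DiffRegion]],
                    peaks: Mapping[tuple[str, str], Sequence[GenomicInterval]],
                    fdr_cutoff: float = 0.05) -> list[CreRecord]:
    """Robust CRE calling per strain/assay followed by cross-strain
    sharing classification (per assay)."""
    robust: dict[tuple[str, str], list[CreRecord]] = {}
    for (strain, assay), diffs in diff_regions.items():
        robust[(strain, assay)] = call_robust_regions(
            diffs, peaks.get((strain, assay), ()), fdr_cutoff=fdr_cutoff)
    out: list[CreRecord] = []
    for assay in ("K27ac", "DHS"):
        out.extend(classify_cre_sharing(
            robust.get(("B6", assay), []), robust.get(("CAST", assay), [])))
    return out


def annotate_eqtls_stage(bundle: SimBundle, cres: Sequence[CreRecord],
                         coef_band: float = 0.20,
                         fdr_cutoff: float = 0.05) -> pd.DataFrame:
    stats_by_id = {s.gene_id: s for s in bundle.gene_stats}
    genes_by_id = {g.gene_id: g for g in bundle.genome.genes}
    variants = bundle.all_variants
    rows = []
    for rec in bundle.scans:
        ann = annotate_eqtl(rec, genes_by_id[rec.gene_id],
                            stats_by_id[rec.gene_id], bundle.genome.tads,
                            cres, variants, band=coef_band,
                            fdr_cutoff=fdr_cutoff)
        iv = ann.chosen_interval
        rows.append({
            "gene_id": ann.gene_id,
            "regulating_strain": ann.regulating_strain,
            "regulating_strains": ",".join(ann.regulating_strains),
            "chrom": iv.chrom if iv else "",
            "start": iv.start if iv else -1,
            "end": iv.end if iv else -1,
            "position_class": ann.position_class,
            "category": ann.category,
            "impact": ann.impact,
            "relevant_cre_class": ann.relevant_cre_class,
        })
    return pd.DataFrame(rows)


def cres_to_frame(cres: Sequence[CreRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": c.interval.chrom, "start": c.interval.start,
        "end": c.interval.end, "assay": c.assay, "strain": c.strain,
        "direction": c.direction, "robust": c.robust,
        "share_class": c.share_class, "concordant": c.concordant,
        "promoter": c.promoter} for c in cres])


def summarize(gene_classes: pd.DataFrame, cres: pd.DataFrame,
              annotations: pd.DataFrame) -> pd.DataFrame:
    """Headline tallies: counts per share class, category, impact and
    relevant-CRE class."""
    rows = []
    for cls, n in gene_classes["share_class"].value_counts().items():
        rows.append({"section": "gene_share_class", "key": cls, "count": int(n)})
    if len(cres):
        for (assay, cls), n in cres.groupby(["assay", "share_class"]).size().items():
            rows.append({"section": "cre_share_class", "key": f"{assay}:{cls}",
                         "count": int(n)})
    cat = annotations["category"].dropna()
    for c, n in cat.value_counts().sort_index().items():
        rows.append({"section": "eqtl_category", "key": str(int(c)), "count": int(n)})
    for imp, n in annotations["impact"].dropna().value_counts().items():
        rows.append({"section": "eqtl_impact", "key": imp, "count": int(n)})
    for cc, n in annotations["relevant_cre_class"].dropna().value_counts().items():
        rows.append({"section": "relevant_cre_class", "key": cc, "count": int(n)})
    for pc, n in annotations["position_class"].dropna().value_counts().items():
        rows.append({"section": "position_class", "key": pc, "count": int(n)})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- run()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> tuple[SimConfig, dict]:
    """YAML config: a ``simulation`` block of SimConfig fields and a
    ``thresholds`` block overriding DEFAULT_THRESHOLDS."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    sim_raw = raw.get("simulation", {})
    unknown = set(sim_raw) - sim_fields
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    thresholds = dict(DEFAULT_THRESHOLDS)
    thr_raw = raw.get("thresholds", {})
    unknown = set(thr_raw) - set(thresholds)
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    thresholds.update(thr_raw)
    return SimConfig(**sim_raw), thresholds


def run(config_path: str | Path, outdir: str | Path,
        skip_interaction: bool = False) -> dict:
    """Execute all stages on a simulated study and write the outputs,
    summary and manifest under ``outdir``.  Returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg, thr = load_config(config_path)
    bundle = simulate(cfg)

    logger.info("stage classify-genes: %d genes in", len(bundle.gene_stats))
    gene_classes = classify_genes_stage(
        bundle.gene_stats, thr["fc_cutoff"], thr["fdr"])

    n_diffs = sum(len(v) for v in bundle.landscape.diff_regions.values())
    logger.info("stage call-cres: %d differential regions in", n_diffs)
    cres = call_cres_stage(bundle.landscape.diff_regions,
                           bundle.landscape.peaks, thr["fdr"])
    cre_frame = cres_to_frame(cres)

    logger.info("stage classify-variants: %d variants in",
                len(bundle.all_variants))
    variant_classes = classify_catalog(bundle.all_variants,
                                       bundle.config.variant_target)

    logger.info("stage annotate-eqtls: %d scans in", len(bundle.scans))
    annotations = annotate_eqtls_stage(bundle, cres,
                                       thr["coef_band"], thr["fdr"])

    logger.info("stage enrich")
    universe = [GenomicInterval(c, 0, size)
                for c, size in bundle.genome.chrom_sizes.items()]
    sex_cres = [c.interval for c in cres]
    enr = enrichment(bundle.all_variants, sex_cres, universe,
                     n_perm=min(int(thr["n_perm"]), 200), seed=cfg.seed)
    enr_frame = pd.DataFrame([{
        "feature_set": "sex_biased_cres", "observed": enr.observed,
        "expected": enr.expected, "ratio": enr.ratio,
        "empirical_p": enr.empirical_p, "n_perm": enr.n_perm,
        "seed": enr.seed}])

    interaction_frame = pd.DataFrame()
    if not skip_interaction:
        logger.info("stage scan-interaction: cohort n=%d", len(bundle.cohort))
        cohort = Cohort.from_frame(bundle.cohort,
                                   covariate_cols=["diet", "batch", "sex_diet"])
        perm = permutation_threshold(cohort, n_perm=min(int(thr["n_perm"]), 200),
                                     alpha=thr["alpha"], seed=cfg.seed)
        interaction_frame = perm.scan
        interaction_frame["threshold"] = perm.threshold

    summary = summarize(gene_classes, cre_frame, annotations)

    outputs = {
        "gene_classes.tsv": gene_classes,
        "cres.tsv": cre_frame,
        "variant_classes.tsv": variant_classes,
        "eqtl_annotations.tsv": annotations,
        "enrichment.tsv": enr_frame,
        "summary.tsv": summary,
    }
    if len(interaction_frame):
        outputs["interaction_scan.tsv"] = interaction_frame
    manifest = {"tool_version": __version__, "seed": cfg.seed,
                "thresholds": thr, "files": {}}
    for name, df in outputs.items():
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        manifest["files"][name] = {"sha256": _sha256(path), "rows": len(df)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
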