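"""Readers and writers for the plain-text dialects the pipeline exchanges.

BED3/BED6 for intervals and peaks, a GTF-lite for gene annotation
(1-based inclusive on disk, converted to 0-based half-open in memory and
back on write), header-bearing TSV for every statistics table, and a
VCF-lite for the 8-founder variant catalog.

Chromosome naming is preserved as read; mixing ``chr``-prefixed and bare
names across one run is treated as an error rather than silently
reconciled.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GenomicInterval, GeneRecord, TadRecord


class ChromNamingError(ValueError):
    """Raised when one dataset mixes 'chr1'-style and '1'-style names."""


def check_chrom_naming(names: Iterable[str]) -> None:
    names = set(names)
    prefixed = {n for n in names if n.startswith("chr")}
    if prefixed and prefixed != names:
        raise ChromNamingError(
            "mixed chromosome naming: "
            f"{sorted(prefixed)[:3]} vs {sorted(names - prefixed)[:3]}"
        )


# ---------------------------------------------------------------- BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3+ reader; extra columns beyond the first three are ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    check_chrom_naming(iv.chrom for iv in out)
    return out


def write_bed(path: str | Path, intervals: Sequence[GenomicInterval],
              names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            row = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                row.append(names[i])
            fh.write("\t".join(row) + "\n")


def read_tads(path: str | Path) -> list[TadRecord]:
    """TADs from BED; column 4 (name) is the TAD id when present."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tad_id = fields[3] if len(fields) > 3 else f"tad_{len(out)}"
            out.append(TadRecord(tad_id, GenomicInterval(
                fields[0], int(fields[1]), int(fields[2]))))
    check_chrom_naming(t.interval.chrom for t in out)
    return out


def write_tads(path: str | Path, tads: Sequence[TadRecord]) -> None:
    write_bed(path, [t.interval for t in tads], [t.tad_id for t in tads])


# ---------------------------------------------------------------- GTF-lite


def read_genes_gtf(path: str | Path) -> list[GeneRecord]:
    """GTF-lite: seqname, source, feature, start (1-based), end, score,
    strand, frame, attributes with ``gene_id`` (and optional ``biotype``).

    The TSS is the ``start`` of the feature line for + genes and its
    ``end`` for - genes, converted to a 0-based position.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            chrom, feature = f[0], f[2]
            if feature != "gene":
                continue
            start1, end1, strand = int(f[3]), int(f[4]), f[6]
            attrs = _parse_gtf_attrs(f[8])
            tss = start1 - 1 if strand == "+" else end1 - 1
            out.append(GeneRecord(
                gene_id=attrs["gene_id"], chrom=chrom, tss=tss, strand=strand,
                biotype=attrs.get("biotype", "protein_coding")))
    check_chrom_naming(g.chrom for g in out)
    return out


def write_genes_gtf(path: str | Path, genes: Sequence[GeneRecord],
                    body_length: int = 1000) -> None:
    """Back-convert to 1-based inclusive; genes are written as point-TSS
    features extended by ``body_length`` in the strand direction."""
    with open(path, "w") as fh:
        for g in genes:
            if g.strand == "+":
                start1, end1 = g.tss + 1, g.tss + body_length
            else:
                start1, end1 = max(1, g.tss + 2 - body_length), g.tss + 1
            attrs = f'gene_id "{g.gene_id}"; biotype "{g.biotype}";'
            fh.write("\t".join([g.chrom, "sexqtl", "gene", str(start1),
                                str(end1), ".", g.strand, ".", attrs]) + "\n")


def _parse_gtf_attrs(s: str) -> dict[str, str]:
    out = {}
    for chunk in s.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


# ---------------------------------------------------------------- TSV


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- VCF-lite

VCF_IGNORED_FIELDS = ("INFO", "FILTER", "QUAL", "FORMAT")


def read_vcf_lite(path: str | Path, founders: Sequence[str]) -> pd.DataFrame:
    """VCF-lite: #CHROM, POS (1-based), REF, then one allele column per
    founder ('.' or the REF string marks reference).  Heterozygous calls
    (e.g. 'A/T') are rejected: founders are inbred.  Full-VCF columns are
    ignored with a warning.  Returns a frame with 0-based ``pos``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#CHROM") or (line.startswith("#") is False):
                header = line.lstrip("#").strip().split("\t")
                break
    if header is None:
        raise ValueError(f"no header line in {path}")
    df.columns = header
    ignored = [c for c in df.columns if c.upper() in VCF_IGNORED_FIELDS]
    if ignored:
        warnings.warn(f"ignoring VCF columns {ignored}", stacklevel=2)
        df = df.drop(columns=ignored)
    missing = [f for f in founders if f not in df.columns]
    if missing:
        raise ValueError(f"founder columns missing from {path}: {missing}")
    for f in founders:
        het = df[f].str.contains("/", na=False) | df[f].str.contains("|", regex=False, na=False)
        if het.any():
            raise ValueError(
                f"heterozygous call for founder {f}; founders must be homozygous")
    out = pd.DataFrame({
        "chrom": df["CHROM"],
        "pos": df["POS"].astype(int) - 1,   # to 0-based
        "ref": df["REF"],
    })
    for f in founders:
        out[f] = df[f].where(df[f] != ".", out["ref"])
    check_chrom_naming(out["chrom"].unique())
    return out


def write_vcf_lite(path: str | Path, variants: pd.DataFrame,
                   founders: Sequence[str]) -> None:
    """Writer mirroring :func:`read_vcf_lite`; POS back to 1-based.
    Extra columns (e.g. a class column) are appended after the founders."""
    extra = [c for c in variants.columns
             if c not in {"chrom", "pos", "ref", *founders}]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(["CHROM", "POS", "REF", *founders, *extra]) + "\n")
        for _, r in variants.iterrows():
            row = [str(r["chrom"]), str(int(r["pos"]) + 1), str(r["ref"])]
            row += [str(r[f]) for f in founders]
            row += [str(r[c]) for c in extra]
            fh.write("\t".join(row) + "\n")
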