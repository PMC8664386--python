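"""Classify genes by strain-sharing of sex-biased expression.

Applies the 2-fold / FDR < 0.05 rules to both strains and reports the
strict-shared / standard-shared / strain-unique split, direction
concordance among shared genes, and agreement with the planted truth.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import get_bundle, outdir

from sexqtl import pipeline
from sexqtl.genes import concordance_percent


def run() -> None:
    bundle = get_bundle()
    classes = pipeline.classify_genes_stage(bundle.gene_stats)
    out = outdir("genes")
    classes.to_csv(out / "gene_classes.tsv", sep="\t", index=False)

    counts = classes["share_class"].value_counts()
    print("gene share classes:")
    for cls, n in counts.items():
        print(f"  {cls:16s} {n}")
    shared = classes[classes.share_class.isin(
        ["strict_shared", "standard_shared"])]
    conc = shared["concordant"].astype("boolean")
    pct = concordance_percent(len(shared), int(conc.sum()))
    print(f"shared genes with concordant sex bias: {int(conc.sum())}"
          f"/{len(shared)} = {pct}%")

    merged = classes.merge(bundle.gene_truth, on="gene_id",
                           suffixes=("", "_truth"))
    n_ok = int((merged.share_class == merged.share_class_truth).sum())
    print(f"planted-class recovery: {n_ok}/{len(merged)}")


if __name__ == "__main__":
    run()
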