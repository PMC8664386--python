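"""Call robust sex-biased CREs and classify strain sharing.

Filters differential H3K27ac/DNase regions (assay fold-change and read
count floors, FDR, peak support), labels survivors shared or
strain-unique by >= 1 bp overlap, and reports concordance among shared
CREs per assay.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import get_bundle, outdir

from sexqtl import pipeline
from sexqtl.genes import concordance_percent


def run() -> None:
    bundle = get_bundle()
    n_in = sum(len(v) for v in bundle.landscape.diff_regions.values())
    cres = pipeline.call_cres_stage(bundle.landscape.diff_regions,
                                    bundle.landscape.peaks)
    frame = pipeline.cres_to_frame(cres)
    out = outdir("cres")
    frame.to_csv(out / "cres.tsv", sep="\t", index=False)
    print(f"{n_in} differential regions in -> {len(frame)} robust CREs")

    for assay, grp in frame.groupby("assay"):
        shared = grp[grp.share_class == "shared"]
        n_conc = int(shared["concordant"].astype("boolean").sum())
        pct = concordance_percent(len(shared), n_conc) if len(shared) else 0
        uniq = grp.share_class.value_counts()
        print(f"  {assay}: shared {len(shared)} ({pct}% concordant), "
              f"B6-unique {uniq.get('b6_unique', 0)}, "
              f"CAST-unique {uniq.get('cast_unique', 0)}")

    merged = frame.merge(bundle.landscape.truth,
                         on=["chrom", "start", "end", "assay", "strain"],
                         suffixes=("", "_truth"))
    ok = int((merged.share_class == merged.share_class_truth).sum())
    print(f"planted share-class recovery: {ok}/{len(merged)}")


if __name__ == "__main__":
    run()
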