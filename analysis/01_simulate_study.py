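"""Generate the synthetic study every downstream driver analyzes.

Writes the pipeline-facing inputs (gene stats, differential regions,
peaks, variant catalog, eQTL scans, TADs, DO-style cohort) and the truth
sidecars under results/synthetic_study/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import SEED, outdir

from click.testing import CliRunner

from sexqtl.cli import main as cli


def run() -> None:
    out = outdir("synthetic_study")
    res = CliRunner().invoke(cli, ["simulate", "--seed", str(SEED),
                                   "--out", str(out)])
    if res.exit_code != 0:
        raise SystemExit(res.output)
    files = sorted(p.name for p in out.iterdir())
    print(f"simulated study (seed {SEED}) -> {out}")
    print(f"  {len(files)} files: {', '.join(files[:6])}, ...")


if __name__ == "__main__":
    run()
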