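"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

from sexqtl.simulate import SimConfig, simulate

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 0

_bundle_cache = {}


def get_bundle(seed: int = SEED):
    """The synthetic study all drivers analyze (deterministic per seed)."""
    if seed not in _bundle_cache:
        _bundle_cache[seed] = simulate(SimConfig(seed=seed))
    return _bundle_cache[seed]


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
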