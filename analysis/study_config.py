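"""Shared run configuration for the numbered analysis drivers.

The study mirrors the full design (26 populations, 2,000 neutral SNP loci,
four craniodental blocks of 37/28/24/25 variables with heritabilities
0.9/0.2/0.5/0.8 and a common climate effect) with 200 resampling
iterations per scheme so the whole analysis finishes in a few minutes on
one CPU.
"""

from pathlib import Path

from dpdg.pipeline import RunConfig
from dpdg.simulate import SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "study"


def study_run_config(seed: int = 0, outdir: Path | None = None) -> RunConfig:
    return RunConfig(
        outdir=str(outdir or RESULTS),
        seed=seed,
        simulation=SimulationConfig(seed=seed),
        n_iterations=200,
        nmds_restarts=12,
    )
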