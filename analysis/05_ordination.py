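#!/usr/bin/env python
"""Ordination diagnostics.

3D Kruskal NMDS of every distance matrix (best of several restarts) with
the stress-1 statistic, plus Procrustes superimposition of each phenotype
configuration onto the F_ST configuration.  Writes coordinates, stress and
residual tables under results/study/ordination.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import study_run_config

from dpdg.pipeline import stage_ordination


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    cfg = study_run_config(seed=args.seed)
    stage_ordination(cfg)
    stress = pd.read_csv(Path(cfg.outdir) / "ordination" / "stress.csv")
    print(stress.to_string(index=False, float_format=lambda v: f"{v:.4f}"))


if __name__ == "__main__":
    main()
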