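#!/usr/bin/env python
"""Assemble and print the run report (median r per data type and scheme,
NMDS stress with the 0.15 acceptability gate)."""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import study_run_config

from dpdg.pipeline import report


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    cfg = study_run_config(seed=args.seed)
    print(report(cfg.outdir))


if __name__ == "__main__":
    main()
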