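#!/usr/bin/env python
"""Compute all between-population distance matrices.

Weir-Cockerham F_ST from the SNPs, Mahalanobis D2 per phenotype block
(metric: geometric means + pooled covariance; nonmetric: probit thresholds
+ pooled correlation), the variable-count weighted combined D2, climate
(Euclidean over five temperature variables) and geodesic distances.
Writes labelled CSV matrices under results/study/distances.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import study_run_config

from dpdg.pipeline import stage_distances


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    counts = stage_distances(study_run_config(seed=args.seed))
    print(f"distance matrices written for {counts['n_populations']} populations")


if __name__ == "__main__":
    main()
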