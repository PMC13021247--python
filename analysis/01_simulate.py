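#!/usr/bin/env python
"""Step 1: generate synthetic datasets for both experiments.

Writes trial and ground-truth tables under results/ for downstream steps.
Desk-scale defaults (12 participants per condition cell) keep the full
pipeline run under a few minutes; pass --n-per-cell 40 for full-size cohorts.
"""

import argparse
from pathlib import Path

from ownbias import io, synth


def main():
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-per-cell", type=int, default=12)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    for exp in (1, 2):
        cfg = synth.ExperimentConfig.for_experiment(
            exp, n_per_cell=args.n_per_cell, seed=args.seed + exp
        )
        trials, truth = synth.generate_experiment(cfg)
        io.write_table(trials, args.out_dir / f"exp{exp}_trials.csv")
        io.write_table(truth, args.out_dir / f"exp{exp}_truth.csv")
        print(f"experiment {exp}: {len(truth)} participants, {len(trials)} trials")


if __name__ == "__main__":
    main()
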