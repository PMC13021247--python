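#!/usr/bin/env python
"""Step 5: regress the starting point on the standardized per-participant PSE.

A negative slope means participants with smaller (more self-ward) PSEs carry
larger starting-point biases — the individual-differences linkage between the
psychometric and process-level analyses.
"""

import argparse
from pathlib import Path

import numpy as np

from ownbias import inference, io, psychometrics


def main():
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--seed", type=int, default=4)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    for exp in (1, 2):
        trials = io.read_trials(args.out_dir / f"exp{exp}_trials.csv")
        trials, _ = psychometrics.filter_trials(trials)
        curves = psychometrics.fit_participants(trials)
        pse = {c.participant: c.alpha for c in curves}
        post = inference.regress_z_on_pse(trials, pse, seed=args.seed)
        slope = post.get("z_slope")
        p_neg = float(np.mean(slope < 0))
        bf = inference.format_bf(inference.bayes_factor(max(1 - p_neg, 1e-12)))
        io.write_table(post.summary(),
                       args.out_dir / f"exp{exp}_z_pse_regression.csv")
        print(f"experiment {exp}: slope mean={slope.mean():.3f} "
              f"P(slope<0)={p_neg:.3f} BF10={bf}")


if __name__ == "__main__":
    main()
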