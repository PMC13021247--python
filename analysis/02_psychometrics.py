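#!/usr/bin/env python
"""Step 2: psychometric analysis of the simulated experiments.

Filters fast responses, fits per-participant cumulative logistics, excludes
random responders, and tests the per-condition group PSEs against the
objective 50% midpoint plus the between-condition contrast.
"""

import argparse
from pathlib import Path

import pandas as pd

from ownbias import io, psychometrics


def main():
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    for exp in (1, 2):
        trials = io.read_trials(args.out_dir / f"exp{exp}_trials.csv")
        kept, report = psychometrics.filter_trials(trials)
        print(f"experiment {exp}: removed "
              f"{100 * report['n_excluded'].sum() / report['n_total'].sum():.2f}% "
              "fast responses")
        curves = psychometrics.fit_participants(kept)
        curves, excluded = psychometrics.exclude_random_responders(kept, curves)
        if excluded:
            print(f"  excluded random responders: {excluded}")
        tab = pd.DataFrame(
            [dict(participant=c.participant, condition=c.condition,
                  pse=c.alpha, slope=c.beta) for c in curves]
        )
        io.write_table(tab, args.out_dir / f"exp{exp}_psych_curves.csv")
        by_cond = {c: g["pse"].to_numpy() for c, g in tab.groupby("condition")}
        for name, r in psychometrics.group_tests(by_cond).items():
            print(f"  {name}: M={r.mean:.1f} t({r.df})={r.t:.2f} "
                  f"p={r.p:.3f} d={r.d:.2f}")


if __name__ == "__main__":
    main()
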