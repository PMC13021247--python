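#!/usr/bin/env python
"""Step 3: fit the three hierarchical diffusion variants and compare by DIC.

M1 fixes the starting point at 0.5, M2 frees it per condition, M3 also frees
boundary separation per condition.  Fast MCMC mode (2000 draws / 500 burn)
by default; --full switches to 10000/1000.
"""

import argparse
from pathlib import Path

import pandas as pd

from ownbias import inference, io, psychometrics
from ownbias.models import ModelSpec, build_design


def main():
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--seed", type=int, default=2)
    ap.add_argument("--full", action="store_true")
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    kw = dict(n_samples=10_000, n_burn=1000) if args.full else \
        dict(n_samples=2000, n_burn=500)

    for exp in (1, 2):
        trials = io.read_trials(args.out_dir / f"exp{exp}_trials.csv")
        trials, _ = psychometrics.filter_trials(trials)
        rows = []
        for name in ("M1", "M2", "M3"):
            design = build_design(trials, ModelSpec.from_variant(name))
            post = inference.sample_posterior(design, seed=args.seed, **kw)
            dic = inference.compute_dic(post)
            io.write_table(post.summary(),
                           args.out_dir / f"exp{exp}_posterior_{name}.csv")
            rows.append(dict(model=name, dic=dic.dic, p_d=dic.p_d))
            print(f"experiment {exp} {name}: DIC={dic.dic:.0f} p_D={dic.p_d:.1f}")
        tab = pd.DataFrame(rows).sort_values("dic")
        io.write_table(tab, args.out_dir / f"exp{exp}_dic_table.csv")
        print(f"experiment {exp} best model: {tab.iloc[0]['model']}")


if __name__ == "__main__":
    main()
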