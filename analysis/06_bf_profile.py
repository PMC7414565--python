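#!/usr/bin/env python
"""Bayes-factor profile for a single mass-extinction event.

Computes the 2 ln BF profile on the simulated event tree under the three
survival priors (5%, 25% and 75% mean survival with their stated 95%
intervals) and reports where support peaks under each.
Writes results/bf_profile_<prior>.tsv.
"""

import argparse
from pathlib import Path

from pulsetree import scan, treeio

OUT = Path(__file__).resolve().parents[1] / "results"

PRIORS = {
    "s05": (0.05, (0.01, 0.10)),
    "s25": (0.25, (0.07, 0.50)),
    "s75": (0.75, (0.48, 0.94)),
}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--tree", default=str(OUT / "tree_event.nwk"))
    ap.add_argument("--rho", type=float, default=0.74)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    bt = treeio.branching_times(treeio.read_newick(Path(args.tree).read_text()))
    rate_priors = scan.default_rate_priors(bt, args.rho)
    for tag, (mean, ci) in PRIORS.items():
        prior = scan.fit_survival_prior(mean, ci)
        prof = scan.run_bf_profile(
            bt, prior=prior, rate_priors=rate_priors, rho=args.rho,
            seed=args.seed,
        )
        peak = prof.peak_age()
        peak_bf = float(prof.table["two_ln_bf"].max())
        n_mod = int((prof.table["two_ln_bf"] > 2).sum())
        print(f"prior mean survival {mean:.2f} (CI {ci[0]}-{ci[1]}): "
              f"peak at {peak:g} Ma, 2lnBF {peak_bf:.2f} "
              f"({scan.classify_bf(peak_bf)}); {n_mod} ages with moderate+ support")
        prof.to_tsv(OUT / f"bf_profile_{tag}.tsv")
    print(f"wrote profiles under {OUT}")


if __name__ == "__main__":
    main()
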