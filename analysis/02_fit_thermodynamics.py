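#!/usr/bin/env python
"""Short-term analysis: hyperchromicity fits of the published mean-shift table
and a recovery check on synthetic data.

For each copigment (caffeic acid CAF, (+)-catechin CA, syringic acid SI) and
pH, the log-log regression of ln[(A-A0)/A0] on ln[Cp]0 yields the apparent
stoichiometry n (slope), the association constant Keq (exp intercept) and
dG0 = -RT lnKeq.  Writes the thermo table and the ln-ln / Keq-vs-pH figures,
then verifies that fitting synthetic noiseless data returns the generating
parameters.
"""

import argparse
from pathlib import Path

from copigmentation.pipeline import RunConfig, run_short_term
from copigmentation.synthetic import GeneratorConfig, generate_titration
from copigmentation.thermo import fit_copigmentation, rank_copigments


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/thermo"))
    args = ap.parse_args()

    table = run_short_term(
        RunConfig(out_dir=args.out, use_reference_fixtures=True, seed=args.seed)
    )
    cols = ["copigment", "pH", "n", "Keq", "dG0_kJ_mol", "r2"]
    print(table[cols].round(3).to_string(index=False))
    assert (table["dG0_kJ_mol"] < 0).all()
    print("\nall 12 conditions spontaneous (dG0 < 0).")

    best = table.loc[table.groupby("copigment")["Keq"].idxmax()]
    print("\nstrongest association per copigment (all at pH 3.6):")
    print(best[cols].round(2).to_string(index=False))

    at36 = table[table["pH"] == 3.6]
    order = " > ".join(at36.sort_values("Keq", ascending=False)["copigment"])
    print(f"\ncopigment ranking at pH 3.6 by Keq: {order}")

    # recovery check: noiseless synthetic titration is the fit's exact inverse
    cfg = GeneratorConfig(Keq_true=65.0, noise_sd_rel=0.0, pH_values=(3.6,),
                          seed=args.seed)
    (series,) = generate_titration(cfg)
    fit = fit_copigmentation(series)
    print(
        f"\nsynthetic check: generated Keq = {cfg.Keq_true}, "
        f"recovered Keq = {fit.Keq:.6f}, n = {fit.n:.6f}"
    )


if __name__ == "__main__":
    main()
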