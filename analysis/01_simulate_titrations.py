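#!/usr/bin/env python
"""Generate the synthetic short-term study: triplicate titration spectra for
every pH and molar ratio of the design, written as CSV fixtures.

The generator emulates the experimental template — 5e-5 M pigment, copigment
molar ratios 1:1/1:5/1:10/1:20, pH ladder 2.8-3.8, triplicates — with a
flavylium band at 523 nm whose baseline amplitude decays with pH and whose
hyperchromic enhancement follows the 1:n binding isotherm with Keq = 65 M^-1.
"""

import argparse
from pathlib import Path

import numpy as np

from copigmentation.pipeline import RunConfig, run_simulate
from copigmentation.synthetic import GeneratorConfig, generate_titration


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()

    gen = GeneratorConfig(seed=args.seed)
    paths = run_simulate(RunConfig(out_dir=args.out, seed=args.seed), gen)
    print(f"wrote {paths['spectra']} and {paths['metadata']}")

    series = generate_titration(gen)
    print("\npH   A0(523)   shifts (1:1 .. 1:20)")
    for s in series:
        shifts = "  ".join(f"{h:.4f}" for h in s.shifts)
        print(f"{s.pH:<4} {s.A0:.4f}   {shifts}")
    a0 = np.array([s.A0 for s in series])
    assert np.all(np.diff(a0) < 0), "baseline absorbance must decay with pH"
    print(
        "\nbaseline A0 decays monotonically with pH (flavylium fraction, "
        f"pKh = {gen.pKh}); shifts grow with the copigment ladder as the "
        "isotherm requires."
    )


if __name__ == "__main__":
    main()
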