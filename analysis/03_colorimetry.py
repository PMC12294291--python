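#!/usr/bin/env python
"""Long-term colour analysis: validate the published CIELab records and
convert a synthetic aged spectrum to colour.

Validation mode recomputes C* = sqrt(a*^2 + b*^2) and H* = atan2(b*, a*) from
every tabulated (a*, b*) pair and reports the discrepancies against the
instrument-printed values, plus an sRGB swatch per record.  A synthetic aged
spectrum (440 nm xanthylium-like band + 510 nm flavylium shoulder) then runs
through the full transmittance -> XYZ -> CIELab pipeline.
"""

import argparse
from pathlib import Path

from copigmentation.colorimetry import color_from_spectrum, load_observer_illuminant
from copigmentation.pipeline import RunConfig, run_long_term
from copigmentation.spectra import band_ratio
from copigmentation.synthetic import AGED_BANDS, generate_aged_spectrum


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/colour"))
    args = ap.parse_args()

    out = run_long_term(RunConfig(out_dir=args.out, validate_printed=True))
    val = out["color_validation"]
    print(
        f"{len(val)} published records: max |C* discrepancy| = "
        f"{val['C_discrepancy'].abs().max():.4f} (chroma is exactly the "
        "vector norm of (a*, b*) to print precision)"
    )
    print(
        f"hue: max |H* discrepancy| = {val['H_discrepancy'].abs().max():.3f} deg; "
        "the instrument prints H* on a coarse ~0.57 deg grid (the same value "
        "appears for distinct (a*, b*) pairs), so discrepancies up to ~0.3 deg "
        "are quantisation, not arithmetic."
    )
    worst = val.loc[val["H_discrepancy"].abs().idxmax()]
    print(
        f"worst hue row: {worst['copigment']} pH {worst['pH']} ratio "
        f"{worst['molar_ratio']}: printed {worst['H_printed']} vs recomputed "
        f"{worst['H_recomputed']:.2f}"
    )

    s = generate_aged_spectrum(AGED_BANDS, noise_sd=0.002, seed=args.seed)
    res = color_from_spectrum(s, load_observer_illuminant())
    print(
        f"\nsynthetic aged spectrum: 440/510 ratio = {band_ratio(s):.3f}, "
        f"L* = {res.L:.2f}, a* = {res.a:.2f}, b* = {res.b:.2f}, "
        f"C* = {res.C:.2f}, H* = {res.H:.2f} deg, swatch {res.srgb_hex}"
    )
    print("positive a* and b* with H* between 0 and 90 deg: the orange-ish "
          "hue the 440 nm band imposes on the red flavylium shoulder.")


if __name__ == "__main__":
    main()
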