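# copigmentation

Thermodynamic and colorimetric analysis of anthocyanin copigmentation in
model wine, for researchers in oenology and phytochemistry who quantify how
colourless polyphenols (caffeic acid, (+)-catechin, syringic acid, ...)
stabilise and shift the colour of malvidin-3-*O*-glucoside solutions.

## The model

Binding of a copigment Cp to the coloured flavylium form of an anthocyanin
enhances the absorbance at the pigment's visible maximum (523 nm). For a 1:n
association the hyperchromic shift follows a power-law isotherm, linearised
as

```
ln[(A − A₀)/A₀] = ln K_eq + n · ln [Cp]₀
```

so an ordinary least-squares fit of the log shift against the log of the
final copigment concentration gives the apparent stoichiometry **n** (slope),
the association constant **K_eq** (M⁻¹, exponential of the intercept) and the
standard Gibbs energy

```
ΔG⁰ = −R·T·ln K_eq        (R = 8.314 J mol⁻¹ K⁻¹, T = 298 K)
```

Long-term colour is characterised by CIELab coordinates (illuminant D65,
10° observer) computed from decadic transmittance spectra — lightness L*,
opponent coordinates a*, b*, chroma C* = √(a*² + b*²) and signed hue angle
H* = atan2(b*, a*) — and by the 440/510 nm absorbance ratio (yellow/red
balance of aged solutions), compared across molar ratios with one-way ANOVA
and Tukey HSD compact letter display.

## Worked example

Fit the packaged table of published mean hyperchromic shifts (three
copigments × four pH values, molar ratios 1:1–1:20 at 5×10⁻⁵ M pigment):

```python
from copigmentation.thermo import build_thermo_table, reference_series

table = build_thermo_table(reference_series())
print(table[["copigment", "pH", "n", "Keq", "dG0_kJ_mol", "r2"]].round(3))
```

which prints, among the 12 rows:

```
copigment  pH    n   Keq   dG0_kJ_mol   r2
      CAF 3.6 0.803 58.955    -10.101 0.996
       CA 3.6 0.635 24.213     -7.896 0.995
       SI 3.6 0.740 47.439     -9.562 0.990
```

Every ΔG⁰ is negative (association is spontaneous at all conditions), K_eq
peaks at pH 3.6 for every copigment, and the couples rank CAF > SI > CA in
association strength — caffeic acid's planar, conjugated structure stacks
best on the flavylium ion. Stoichiometries fall in the expected 0.5–2 window.

The numbered drivers under `analysis/` run the full narrative:
`01_simulate_titrations.py` (synthetic study design), `02_fit_thermodynamics.py`
(the table above plus figures), `03_colorimetry.py` (validation of the
published CIELab records: chroma reproduces √(a*²+b*²) to ±0.009 on all 52
records; printed hue is quantised to ~0.57° steps by the instrument), and
`04_band_ratio_anova.py` (Tukey letters `b c c a` for the 440/510 ratios at
every pH, matching the published grouping). A `copigmentation` CLI exposes
the same steps (`fit`, `color`, `stats`, `simulate`, `report`).

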