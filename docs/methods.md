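# Methods

## Association model

The package models copigmentation as a single pigment–copigment association
whose visible signature is hyperchromicity at the flavylium maximum
(λ_ref = 523 nm). With A₀ the absorbance of the pigment alone and A the
absorbance after copigment addition, the shift (A − A₀)/A₀ is assumed to
follow K_eq·[Cp]₀ⁿ, fitted in log–log form by unweighted ordinary least
squares: slope = apparent stoichiometry n, intercept = ln K_eq, and
ΔG⁰ = −RT ln K_eq with R = 8.314 J mol⁻¹ K⁻¹ and T fixed at 298 K (the
convention for standardised equilibrium reporting, regardless of storage
temperature). Natural logarithms throughout. The model deliberately excludes
hydration/self-association multi-state equilibria and any temperature
dependence (single-temperature data only).

Two conventions matter and are fixed here:

* **Concentration basis.** [Cp]₀ is the *final* copigment concentration
  after 1:1 mixing — 5×10⁻⁵ … 10⁻³ M for molar ratios 1:1 … 1:20 at
  5×10⁻⁵ M pigment. A hand refit of the published caffeic-acid pH 3.8
  shifts reproduces the published ΔG⁰ = −5.31 kJ mol⁻¹ only on this basis;
  the pre-mix basis shifts every intercept by n·ln 2. A rescaling test pins
  this property (doubling all concentrations changes ln K_eq by −n·ln 2 and
  nothing else).
* **Mean-shift fitting.** Fits run on replicate-averaged shifts. The
  published per-condition parameters are not all exactly recomputable from
  the published mean shifts (e.g. CAF pH 3.6 refits to n = 0.80 vs printed
  0.85), consistent with the original analysis having fitted replicates
  individually and averaged the parameters; replicate-level series are
  supported (`generate_titration(average_replicates=False)`) but the mean
  shifts are the only deposited data, so mean-shift fitting is the default
  and the documented ambiguity band is ±0.06 on n and ±0.4 kJ mol⁻¹ on ΔG⁰.
  Relatedly, the published K_eq = 26.6 M⁻¹ for catechin at pH 3.6 is not
  consistent with its own printed ΔG⁰ = −7.89 kJ mol⁻¹ (which implies
  ≈ 24.2 M⁻¹); both values are surfaced, neither is corrected.

Non-positive shifts have no logarithm and are dropped from the fit with an
explicit warning and a result flag, never silently; at least three positive
points are required. Slopes outside the 0.5–2 stoichiometry window expected
for anthocyanin copigmentation are flagged, not rejected.

## Spectra

Spectra live on any strictly increasing wavelength grid (the study template
is 300–700 nm at 1 nm, 1 cm path). Absorbance more negative than a
configurable baseline tolerance (−0.005 AU) rejects the spectrum as corrupt;
milder negativity is treated as instrument baseline noise and clipped only
at the transmittance stage. Savitzky–Golay smoothing defaults to a 9-point
window; the polynomial order is not specified by the source protocol and
defaults to 3 (cubic preservation keeps band curvature near maxima).
Edges are handled by refitting the polynomial on the one-sided truncated
window rather than padding, because both range edges carry real signal.
Smoothing before extracting A(523) is the default, configurable.
Interpolation for `absorbance_at` is piecewise linear (monotone, no
overshoot near sharp bands). Peak location refines the grid argmax by a
parabola through its two neighbours (exact for a noiseless parabola; ties
break toward longer wavelength); a maximum on the window edge is returned
unrefined and flagged.

## Colorimetry

Transmittance T = 10^(−A) is integrated against the CIE 1964 10° observer
and illuminant D65 by rectangular summation on a 1 nm working grid
(linear interpolation of the 5 nm tables), with k normalising Y of the
perfect transmitter to 100 over the same range as the numerators. Measured
spectra stop at 700 nm while the observer tables extend to 780 nm: the last
measured absorbance is extended as a constant (anthocyanin absorbance is at
baseline there) and data below 380 nm are ignored; both edges are
configurable, and a coverage gap with extension disabled is an error.

The packaged D65 SPD is the standard 5 nm table (2 dp). The packaged 1964
CMFs are generated from the published Wyman–Sloan–Shirley analytic
sum-of-Gaussian fits, accurate to about 1% of peak per channel — the
computed D65/10° white point is (95.84, 100, 107.74) against the official
(94.81, 100, 107.30). All colour *differences* asserted by the tests are
identities in Lab space (chroma/hue arithmetic on tabulated records) or
internal consistencies (white point, linearity, round trips), which do not
depend on that approximation; absolute tristimulus values of measured
spectra inherit the ~1% scale and the package is therefore not suitable for
standards-grade colorimetry.

CIELab uses the standard cube-root function with the linear segment below
(6/29)³. Hue is reported signed in (−180°, 180°] (the tabulated reference
records include a negative hue, confirming the signed convention). At the
neutral axis the hue is undefined and reported as 0 with a flag. sRGB
swatches go Lab → XYZ → linear RGB (IEC 61966-2-1 matrix, D65 white) →
gamma encoding, clipping out-of-gamut channels to [0, 1] with a flag —
chroma-preserving gamut mapping is deliberately out of scope.

A note on validating printed colour tables: recomputing H* from the printed
(a*, b*) pairs shows the source instrument prints hue on a coarse grid
(~0.57° steps; the same H* appears for clearly distinct coordinate pairs),
so recomputed hues deviate by up to ~0.31°. The package treats printed H*
as approximate at that quantisation level. Printed C* is exactly
√(a*² + b*²) to print precision (max deviation 0.009 over all 52 records).

## Group statistics

Levene's test uses centre = mean (the original statistic); Shapiro–Wilk runs
on pooled within-group-centred residuals (scipy's implementation of
Royston's approximation). One-way ANOVA is the classic decomposition; Tukey
HSD uses the Tukey–Kramer standard error for unbalanced groups and p-values
from scipy's numerical studentized range distribution, cross-checked in the
tests against `scipy.stats.tukey_hsd` and against a printed 5% critical-value
table (k ≤ 6, df ∈ {5, 10, 20, 30}). Compact letters follow the
insert-and-absorb algorithm: start from one set of all groups, split every
set containing a significantly different pair, absorb subsets, then letter
the sets in ascending order of their smallest group mean — so 'a' marks the
lowest-mean group, the convention of food-chemistry tables. The letter sets
regenerate the pairwise significance partition exactly (tested by
round-trip). Zero within-group variance everywhere is the degenerate
exact-separation case: flagged, F = ∞ when means differ, single shared
letter when they do not.

Power caveats found by simulation: Shapiro–Wilk's power against uniform
residuals is only ~80% at n = 50 (the assumption-check test therefore uses
n = 100, where it is ~98%); and simulating the published 440/510 design at
pH 2.8 (means 2.29/2.40/2.39/1.89, SD 0.01, n = 3) yields the published
letter pattern {b, c, c, a} in ~93% of draws — the remaining ~7% correctly
separate the two groups whose true means differ by one within-group SD.
`scipy.stats.tukey_hsd` gives the same rate, so this is a property of the
design, not of the implementation.

## Synthetic data generator

The generator emulates the study template: 5×10⁻⁵ M pigment, molar ratios
1:1/1:5/1:10/1:20, pH ladder 2.8–3.8, triplicates. Baseline absorbance
follows the flavylium fraction 10^(−pH)/(10^(−pH) + 10^(−pKh)) with an
apparent hydration constant pKh = 2.6 — a modelling knob, not a measured
value — scaled by A0_base = 1.4 AU (≈ the molar absorptivity of the pigment
at 5×10⁻⁵ M). Default true parameters are K_eq = 65 M⁻¹ (the strongest
couple of the study at pH 3.6) and n = 1 (fitted slopes near unity).

Noise is multiplicative Gaussian (σ = 2% default, triplicates averaged
before fitting) and acts on the copigmentation *enhancement* term:
A = A₀·(1 + K_eq·[Cp]ⁿ·(1 + ε)). Acting instead on the whole absorbance
reading (available as `noise_on="absorbance"`) makes the 1:1 point — a 0.3%
relative enhancement — unrecoverable at 2% noise and produces log–log fits
far noisier than the r² = 0.978–0.999 of the reference data, so the
enhancement-noise model is the one consistent with the measurement quality
the analysis assumes; it reflects that the hyperchromic shift is a
differential measurement against a stable reference. Aged spectra are sums
of Gaussian bands (440 nm xanthylium-like maximum, 510 nm flavylium
shoulder) with closed-form band values exposed so expected band ratios are
analytic; band widths (σ = 15 nm) make 440↔510 cross-talk negligible
(< 2×10⁻⁵ relative). Replicate ratio samples are drawn Normal(mean, SD),
with SD = 0 permitted (the published tables print some SDs as 0) exercising
the degenerate-statistics path.

What the generator does **not** emulate: the kinetics of the 12-month
conversion to new pigments, chemically mechanistic band shapes, copigment
self-absorbance interference, stray-light/baseline drift, or correlated
(non-white) instrument noise. Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the stated statistical
assumptions, not robustness to real-instrument artefacts.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configs and seeds give byte-identical
CSV outputs (hash-tested). Simulation sizes used by the tests and the
acceptance script: 200 seeded repetitions for noisy-recovery and
letter-pattern checks, 20 random configurations for the exact-inverse
property, 2000 simulations for the ANOVA type-I calibration, 100 seeds for
the assumption-check power properties — sizes at which the asserted
proportions are stable to a couple of percent while the whole suite runs in
well under a minute.

## Known limitations

* Single-association model only; no hydration/self-association constants,
  no van 't Hoff analysis.
* CMF tables are an analytic approximation (~1% of peak); see above.
* Shapiro–Wilk p-values are approximation-level (Royston), and the exact
  statistical software variant behind the reference analysis is unknown.
* Printed-table validation can only be as consistent as the tables
  themselves (hue quantisation; replicate-averaging ambiguity).
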