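"""Forward generators for every input the analysis pipeline consumes.

No raw spectra were deposited for this study design, so synthetic data stand
in for them with the statistical structure the analysis assumes:

* titration ladders following the exact inverse of the log-log association
  model, A = A0 * (1 + Keq * [Cp]^n), with pH-dependent baseline absorbance
  through an apparent flavylium hydration constant pKh;
* full visible spectra as Gaussian bands on the 300-700 nm grid (flavylium
  band at 523 nm, copigment UV band near 324 nm);
* "aged" spectra as sums of Gaussian bands (xanthylium-like 440 nm maximum
  plus a 510 nm flavylium shoulder) with closed-form band values exposed so
  expected 440/510 ratios are computable analytically;
* replicate 440/510 ratio samples from stated group means and SDs.

Defaults mirror the study conditions: pigment 5e-5 M final, molar ratios
1:1/1:5/1:10/1:20, pH 2.8-3.8, triplicates, 2% multiplicative noise.  All
randomness is seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .groupstats import RatioSample
from .spectra import SampleMeta, Spectrum
from .thermo import TitrationSeries

__all__ = [
    "GaussianBand",
    "GeneratorConfig",
    "flavylium_fraction",
    "generate_titration",
    "generate_titration_spectra",
    "generate_aged_spectrum",
    "aged_band_value",
    "generate_ratio_samples",
    "DEFAULT_GRID",
]

DEFAULT_GRID = np.arange(300.0, 701.0, 1.0)


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian absorbance band: A(l) = amplitude * exp(-(l-centre)^2 / 2 width^2)."""

    centre: float  # nm
    width: float  # nm (Gaussian sigma)
    amplitude: float  # AU at the band centre

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")

    def value(self, wavelength: np.ndarray | float) -> np.ndarray | float:
        wl = np.asarray(wavelength, dtype=float)
        return self.amplitude * np.exp(-0.5 * ((wl - self.centre) / self.width) ** 2)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design template for the synthetic short-term experiment.

    ``noise_on`` selects where the multiplicative noise acts: on the
    copigmentation *enhancement* (default; emulates the differential
    measurement quality of the reference fits, r2 ~ 0.98-0.999) or on the
    whole *absorbance* reading.
    """

    Keq_true: float = 65.0  # M^-1 (strongest couple of the study, pH 3.6)
    n_true: float = 1.0  # 1:1 complex; fitted slopes are near unity
    A0_base: float = 1.4  # AU of the fully flavylium pigment band
    pKh: float = 2.6  # apparent hydration constant (modelling knob)
    pH_values: tuple[float, ...] = (2.8, 3.2, 3.6, 3.8)
    molar_ratios: tuple[int, ...] = (1, 5, 10, 20)
    pigment_conc: float = 5e-5  # M, final
    bands: tuple[GaussianBand, ...] = (
        GaussianBand(centre=523.0, width=40.0, amplitude=1.0),  # flavylium
        GaussianBand(centre=324.0, width=20.0, amplitude=0.30),  # copigment UV
    )
    noise_sd_rel: float = 0.02
    noise_sd_abs: float = 0.0  # optional additive baseline noise, AU
    replicates: int = 3
    seed: int = 0
    noise_on: Literal["enhancement", "absorbance"] = "enhancement"

    def __post_init__(self) -> None:
        if self.Keq_true <= 0:
            raise ValueError("Keq_true must be positive")
        if self.noise_sd_rel < 0 or self.noise_sd_abs < 0:
            raise ValueError("noise levels must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def flavylium_fraction(pH: float | np.ndarray, pKh: float) -> float | np.ndarray:
    """Fraction of pigment in the coloured flavylium form at a given pH."""
    return 10.0 ** (-np.asarray(pH)) / (10.0 ** (-np.asarray(pH)) + 10.0**-pKh)


def _a0(config: GeneratorConfig, pH: float) -> float:
    return config.A0_base * float(flavylium_fraction(pH, config.pKh))


def _noisy_absorbance(
    config: GeneratorConfig, A0: float, conc: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One replicate of absorbance readings over the concentration ladder."""
    enh = config.Keq_true * conc**config.n_true
    eps = rng.normal(0.0, config.noise_sd_rel, size=conc.shape)
    if config.noise_on == "enhancement":
        A = A0 * (1.0 + enh * (1.0 + eps))
    else:
        A = A0 * (1.0 + enh) * (1.0 + eps)
    if config.noise_sd_abs > 0:
        A = A + rng.normal(0.0, config.noise_sd_abs, size=conc.shape)
    return A


def generate_titration(
    config: GeneratorConfig = GeneratorConfig(),
    average_replicates: bool = True,
) -> list[TitrationSeries]:
    """Synthetic titration series over the configured pH ladder.

    With ``average_replicates`` the replicate absorbance readings are averaged
    into one series per pH (the default analysis path); otherwise one series
    per (pH, replicate) is returned.
    """
    rng = np.random.default_rng(config.seed)
    conc = config.pigment_conc * np.asarray(config.molar_ratios, dtype=float)
    out: list[TitrationSeries] = []
    for pH in config.pH_values:
        A0 = _a0(config, pH)
        A_rep = np.stack(
            [_noisy_absorbance(config, A0, conc, rng) for _ in range(config.replicates)]
        )
        if average_replicates:
            out.append(
                TitrationSeries(
                    A0=A0,
                    observations=tuple(zip(conc, A_rep.mean(axis=0))),
                    copigment="synthetic",
                    pH=pH,
                )
            )
        else:
            for r in range(config.replicates):
                out.append(
                    TitrationSeries(
                        A0=A0,
                        observations=tuple(zip(conc, A_rep[r])),
                        copigment="synthetic",
                        pH=pH,
                        replicate=r + 1,
                    )
                )
    return out


def generate_titration_spectra(
    config: GeneratorConfig = GeneratorConfig(),
    grid: np.ndarray | None = None,
) -> dict[str, Spectrum]:
    """Full synthetic spectra for the titration design, plus pigment-alone
    references.

    The flavylium band scales with the copigmentation enhancement; the
    copigment UV band scales with the molar ratio.  Keys are sample ids
    ``pH<ph>_r<ratio>_rep<k>`` and ``pH<ph>_ref`` for the references.
    """
    if grid is None:
        grid = DEFAULT_GRID
    rng = np.random.default_rng(config.seed)
    flav, *other = config.bands
    out: dict[str, Spectrum] = {}
    for pH in config.pH_values:
        A0 = _a0(config, pH)
        ref_band = GaussianBand(flav.centre, flav.width, A0)
        ref = np.asarray(ref_band.value(grid))
        out[f"pH{pH}_ref"] = Spectrum(
            grid, ref, SampleMeta(pH=pH, copigment="none", timepoint="T0")
        )
        for ratio in config.molar_ratios:
            cp = ratio * config.pigment_conc
            enh = config.Keq_true * cp**config.n_true
            for rep in range(1, config.replicates + 1):
                eps = rng.normal(0.0, config.noise_sd_rel)
                if config.noise_on == "enhancement":
                    peak = A0 * (1.0 + enh * (1.0 + eps))
                else:
                    peak = A0 * (1.0 + enh) * (1.0 + eps)
                ab = np.asarray(GaussianBand(flav.centre, flav.width, peak).value(grid))
                for band in other:
                    scaled = GaussianBand(
                        band.centre, band.width, band.amplitude * ratio / 20.0
                    )
                    ab = ab + np.asarray(scaled.value(grid))
                if config.noise_sd_abs > 0:
                    ab = ab + rng.normal(0.0, config.noise_sd_abs, size=grid.shape)
                out[f"pH{pH}_r{ratio}_rep{rep}"] = Spectrum(
                    grid,
                    np.clip(ab, 0.0, None),
                    SampleMeta(
                        pH=pH,
                        copigment="synthetic",
                        molar_ratio=ratio,
                        copigment_conc=cp,
                        replicate=rep,
                        timepoint="T0",
                    ),
                )
    return out


#: Aged-solution band profile: xanthylium-like 440 nm maximum with a 510 nm
#: flavylium shoulder, widths narrow enough for negligible cross-talk.
AGED_BANDS = (
    GaussianBand(centre=440.0, width=15.0, amplitude=0.378),
    GaussianBand(centre=510.0, width=15.0, amplitude=0.200),
)


def aged_band_value(
    wavelength: float, bands: Sequence[GaussianBand] = AGED_BANDS
) -> float:
    """Closed-form noiseless absorbance of a band profile at one wavelength."""
    return float(sum(b.value(wavelength) for b in bands))


def generate_aged_spectrum(
    bands: Sequence[GaussianBand] = AGED_BANDS,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid: np.ndarray | None = None,
    meta: SampleMeta | None = None,
) -> Spectrum:
    """Sum-of-Gaussians aged spectrum on the standard grid plus seeded noise."""
    if grid is None:
        grid = DEFAULT_GRID
    rng = np.random.default_rng(seed)
    ab = np.zeros_like(grid, dtype=float)
    for b in bands:
        ab = ab + np.asarray(b.value(grid))
    if noise_sd > 0:
        ab = ab * (1.0 + rng.normal(0.0, noise_sd, size=grid.shape))
    return Spectrum(
        grid,
        ab,
        meta if meta is not None else SampleMeta(timepoint="T12", copigment="synthetic"),
        baseline_tol=-np.inf if noise_sd > 0 else -0.005,
    )


def generate_ratio_samples(
    means: Sequence[float],
    sds: Sequence[float],
    labels: Sequence[str],
    n: int = 3,
    seed: int = 0,
    pH: float | None = None,
) -> list[RatioSample]:
    """Replicate band-ratio groups drawn Normal(mean, sd); sd = 0 allowed
    (degenerate groups exercise the exact-separation path)."""
    rng = np.random.default_rng(seed)
    out = []
    for mean, sd, lab in zip(means, sds, labels, strict=True):
        vals = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, float(mean))
        out.append(RatioSample(label=str(lab), values=tuple(vals), pH=pH))
    return out
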