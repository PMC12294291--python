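"""Copigmentation thermodynamics from spectrophotometric hyperchromicity.

The association of an anthocyanin (pigment) with a colourless polyphenol
(copigment) enhances the flavylium absorbance at its visible maximum.  For a
1:n association the enhancement follows

    (A - A0)/A0 = Keq * [Cp]0^n

so that a log-log plot of the hyperchromic shift against the total copigment
concentration is a straight line with slope n (apparent stoichiometry) and
intercept ln Keq.  The standard Gibbs energy of association follows from
dG0 = -R T ln Keq.  All concentrations are molar, final after mixing; natural
logarithms throughout; Keq in M^-1, dG0 in kJ/mol.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spectra import SampleMeta, Spectrum, absorbance_at

__all__ = [
    "FitSettings",
    "TitrationSeries",
    "ThermoFitResult",
    "hyperchromic_shift",
    "fit_copigmentation",
    "gibbs_free_energy",
    "build_thermo_table",
    "rank_copigments",
    "titration_from_spectra",
    "load_reference_shifts",
    "reference_series",
    "REFERENCE_LADDER",
]

#: Expected stoichiometry window for anthocyanin copigmentation; slopes
#: outside it are flagged, not rejected.
STOICHIOMETRY_RANGE = (0.5, 2.0)


@dataclass(frozen=True)
class FitSettings:
    """Physical constants and fitting policy."""

    R: float = 8.314  # gas constant, J/(mol K)
    T: float = 298.0  # K; equilibria standardised to 25 C
    lambda_ref: float = 523.0  # nm, flavylium visible maximum
    min_points: int = 3

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class TitrationSeries:
    """Reference absorbance and (copigment concentration, absorbance) ladder.

    ``observations`` holds ([Cp]0 in mol/L final, A at lambda_ref) pairs with
    strictly increasing concentrations.  Hypochromic points (A < A0) may be
    stored; the fit excludes them with a warning.
    """

    A0: float
    observations: tuple[tuple[float, float], ...]
    lambda_ref: float = 523.0
    pigment: str = "Mv-3-O-glc"
    copigment: str = "none"
    pH: float = 3.6
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.A0 <= 0:
            raise ValueError("reference absorbance must be positive")
        obs = tuple((float(c), float(a)) for c, a in self.observations)
        object.__setattr__(self, "observations", obs)
        conc = np.array([c for c, _ in obs])
        if np.any(conc <= 0):
            raise ValueError("copigment concentrations must be positive")
        if not np.all(np.diff(conc) > 0):
            raise ValueError("copigment concentrations must be strictly increasing")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.observations])

    @property
    def absorbances(self) -> np.ndarray:
        return np.array([a for _, a in self.observations])

    @property
    def shifts(self) -> np.ndarray:
        return (self.absorbances - self.A0) / self.A0

    @classmethod
    def from_shifts(
        cls,
        shifts: Sequence[float],
        concentrations: Sequence[float],
        A0: float = 1.0,
        **kwargs,
    ) -> "TitrationSeries":
        """Build a series from hyperchromic shifts (tabulated-data entry path)."""
        obs = tuple(
            (float(c), A0 * (1.0 + float(h)))
            for c, h in zip(concentrations, shifts, strict=True)
        )
        return cls(A0=A0, observations=obs, **kwargs)


@dataclass(frozen=True)
class ThermoFitResult:
    """Log-log fit of one pigment/copigment/pH condition."""

    n: float
    lnKeq: float
    Keq: float
    delta_G0: float  # kJ/mol
    r2: float
    rmse: float  # in ln-shift units
    residuals: tuple[float, ...]
    points_used: int
    flags: tuple[str, ...] = ()
    copigment: str = "none"
    pH: float = float("nan")

    def __post_init__(self) -> None:
        assert abs(self.Keq - math.exp(self.lnKeq)) <= 1e-12 * max(1.0, self.Keq)


def hyperchromic_shift(A: float, A0: float) -> float:
    """Relative absorbance enhancement (A - A0)/A0; negative = hypochromic."""
    if A0 <= 0:
        raise ValueError("reference absorbance must be positive")
    return (A - A0) / A0


def gibbs_free_energy(lnKeq: float, settings: FitSettings = FitSettings()) -> float:
    """Standard Gibbs energy of association, -R T lnKeq, in kJ/mol."""
    if not math.isfinite(lnKeq):
        raise ValueError("lnKeq must be finite")
    return -settings.R * settings.T * lnKeq / 1000.0


def fit_copigmentation(
    series: TitrationSeries, settings: FitSettings = FitSettings()
) -> ThermoFitResult:
    """Unweighted OLS of ln(shift) on ln[Cp]0; slope n, intercept ln Keq.

    Non-positive shifts are excluded (their logarithm is undefined) with a
    warning.  Slopes outside the expected 0.5-2 stoichiometry window are
    flagged in the result.
    """
    shifts = series.shifts
    conc = series.concentrations
    pos = shifts > 0
    flags: list[str] = []
    if not np.all(pos):
        dropped = int(np.sum(~pos))
        warnings.warn(
            f"{dropped} non-positive hyperchromic shift(s) excluded from the "
            f"log-log fit ({series.copigment}, pH {series.pH})",
            stacklevel=2,
        )
        flags.append(f"dropped {dropped} non-positive shift(s)")
    if int(np.sum(pos)) < settings.min_points:
        raise ValueError(
            f"need >= {settings.min_points} positive shifts to fit, "
            f"got {int(np.sum(pos))}"
        )
    x = np.log(conc[pos])
    y = np.log(shifts[pos])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in ln[Cp]0; cannot fit")

    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    n = sxy / sxx
    lnKeq = ybar - n * xbar
    resid = y - (lnKeq + n * x)
    sst = float(np.sum((y - ybar) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    rmse = float(np.sqrt(np.mean(resid**2)))
    if not (STOICHIOMETRY_RANGE[0] <= n <= STOICHIOMETRY_RANGE[1]):
        flags.append(
            f"stoichiometry n={n:.3f} outside {STOICHIOMETRY_RANGE}"
        )
    return ThermoFitResult(
        n=n,
        lnKeq=lnKeq,
        Keq=math.exp(lnKeq),
        delta_G0=gibbs_free_energy(lnKeq, settings),
        r2=r2,
        rmse=rmse,
        residuals=tuple(float(r) for r in resid),
        points_used=int(np.sum(pos)),
        flags=tuple(flags),
        copigment=series.copigment,
        pH=series.pH,
    )


def titration_from_spectra(
    spectra: Iterable[Spectrum],
    reference: Spectrum,
    settings: FitSettings = FitSettings(),
) -> TitrationSeries:
    """Assemble a titration series by reading A(lambda_ref) off full spectra.

    ``reference`` is the pigment-alone spectrum (defines A0); each spectrum's
    metadata must carry the final copigment concentration.
    """
    A0 = absorbance_at(reference, settings.lambda_ref)
    rows = []
    cond: SampleMeta | None = None
    for s in spectra:
        if s.meta.copigment_conc is None:
            raise ValueError("spectrum metadata lacks copigment_conc")
        rows.append((s.meta.copigment_conc, absorbance_at(s, settings.lambda_ref)))
        cond = s.meta
    rows.sort(key=lambda t: t[0])
    assert cond is not None, "no spectra supplied"
    return TitrationSeries(
        A0=A0,
        observations=tuple(rows),
        lambda_ref=settings.lambda_ref,
        pigment=cond.pigment,
        copigment=cond.copigment,
        pH=cond.pH,
    )


def build_thermo_table(
    series: Iterable[TitrationSeries], settings: FitSettings = FitSettings()
) -> pd.DataFrame:
    """One row per condition: shifts per ladder point, fitted n, Keq, dG0, r2.

    Rows whose fit fails (e.g. too few positive shifts) are retained with NaN
    estimates and the failure message in ``flags`` rather than aborting the
    whole table.
    """
    rows = []
    series = list(series)
    if not series:
        warnings.warn("no titration series supplied; empty table", stacklevel=2)
    for ts in series:
        base = {
            "pigment": ts.pigment,
            "copigment": ts.copigment,
            "pH": ts.pH,
        }
        for i, h in enumerate(ts.shifts, start=1):
            base[f"shift_{i}"] = h
        try:
            fit = fit_copigmentation(ts, settings)
            base.update(
                n=fit.n,
                lnKeq=fit.lnKeq,
                Keq=fit.Keq,
                dG0_kJ_mol=fit.delta_G0,
                r2=fit.r2,
                rmse=fit.rmse,
                points_used=fit.points_used,
                flags="; ".join(fit.flags),
            )
        except ValueError as exc:
            base.update(
                n=np.nan,
                lnKeq=np.nan,
                Keq=np.nan,
                dG0_kJ_mol=np.nan,
                r2=np.nan,
                rmse=np.nan,
                points_used=0,
                flags=f"fit failed: {exc}",
            )
        rows.append(base)
    return pd.DataFrame(rows)


def rank_copigments(
    results: Iterable[ThermoFitResult], tie_tolerance: float = 1.0
) -> list[tuple[int, ThermoFitResult]]:
    """Rank fits at a shared pH by descending Keq; near-ties share a rank.

    Results whose Keq differ by less than ``tie_tolerance`` (M^-1) from the
    previous entry are reported at the same rank.
    """
    results = list(results)
    if len(results) < 1:
        raise ValueError("nothing to rank")
    phs = {r.pH for r in results}
    if len(phs) > 1:
        raise ValueError(f"results span multiple pH values: {sorted(phs)}")
    ordered = sorted(results, key=lambda r: -r.Keq)
    ranked: list[tuple[int, ThermoFitResult]] = []
    rank = 1
    for i, r in enumerate(ordered):
        if i > 0 and abs(ordered[i - 1].Keq - r.Keq) >= tie_tolerance:
            rank = i + 1
        ranked.append((rank, r))
    return ranked


# ---------------------------------------------------------------------------
# Packaged reference data

#: Final copigment concentrations (mol/L) for molar ratios 1:1, 1:5, 1:10, 1:20
#: at 5e-5 M pigment.
REFERENCE_LADDER = (5e-5, 2.5e-4, 5e-4, 1e-3)


def load_reference_shifts() -> pd.DataFrame:
    """Published mean hyperchromic shifts per copigment and pH (packaged CSV)."""
    with resources.files("copigmentation.data").joinpath(
        "table1_hyperchromic_shifts.csv"
    ).open() as f:
        return pd.read_csv(f, comment="#")


def reference_series() -> list[TitrationSeries]:
    """The 12 published mean-shift titration series on the reference ladder."""
    df = load_reference_shifts()
    out = []
    for _, row in df.iterrows():
        shifts = [row[f"shift_1_{r}"] for r in (1, 5, 10, 20)]
        out.append(
            TitrationSeries.from_shifts(
                shifts,
                REFERENCE_LADDER,
                copigment=str(row["copigment"]),
                pH=float(row["pH"]),
            )
        )
    return out
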