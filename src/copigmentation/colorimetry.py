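"""Transmittance colorimetry: CIE XYZ / CIELab under D65 and the 10-degree observer.

Absorbance spectra are inverted to decadic transmittance, integrated against
the packaged D65 spectral power distribution and 1964 10-degree colour-matching
functions, and expressed as CIELab lightness L*, opponent coordinates a*, b*,
chroma C* = sqrt(a*^2 + b*^2) and hue angle H* = atan2(b*, a*) in signed
degrees.  An sRGB hex swatch renders each record for visual tables.

Measured spectra stop at 700 nm while the observer tables extend to 780 nm;
the last measured absorbance is extended as a constant (anthocyanin absorbance
is near baseline there) and wavelengths below 380 nm are ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .spectra import Spectrum

__all__ = [
    "ObserverIlluminant",
    "ColorResult",
    "load_observer_illuminant",
    "transmittance",
    "tristimulus",
    "lab_from_xyz",
    "xyz_from_lab",
    "chroma_hue",
    "srgb_swatch",
    "color_from_spectrum",
    "load_reference_cielab",
    "SRGB_WHITE",
]

#: D65 white point of the 2-degree observer on the Y=100 scale; the reference
#: white of the sRGB standard, used only for swatch rendering.
SRGB_WHITE = (95.047, 100.0, 108.883)


@dataclass(frozen=True)
class ObserverIlluminant:
    """Colour-matching functions and illuminant SPD on a shared working grid."""

    wavelengths: np.ndarray  # nm, working grid
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray
    spd: np.ndarray  # illuminant relative power

    @property
    def white_point(self) -> tuple[float, float, float]:
        """Tristimulus of the perfect transmitter (Y normalised to 100)."""
        k = 100.0 / float(np.sum(self.spd * self.ybar))
        return (
            k * float(np.sum(self.spd * self.xbar)),
            100.0,
            k * float(np.sum(self.spd * self.zbar)),
        )


@dataclass(frozen=True)
class ColorResult:
    """Colour of one spectrum (or one tabulated Lab record)."""

    X: float
    Y: float
    Z: float
    L: float
    a: float
    b: float
    C: float
    H: float  # degrees, (-180, 180]; 0 and flagged when a = b = 0
    srgb_hex: str
    gamut_clipped: bool = False
    hue_undefined: bool = False


def load_observer_illuminant(
    lo: float = 380.0, hi: float = 780.0, step: float = 1.0
) -> ObserverIlluminant:
    """Load the packaged CIE 1964 10-degree CMFs and D65 SPD, interpolated
    linearly from their native 5 nm tables onto the working grid."""
    data = resources.files("copigmentation.data")
    with data.joinpath("cie1964_10deg_cmf.csv").open() as f:
        cmf = pd.read_csv(f, comment="#")
    with data.joinpath("illuminant_d65.csv").open() as f:
        d65 = pd.read_csv(f, comment="#")
    table_lo = max(cmf["wavelength_nm"].min(), d65["wavelength_nm"].min())
    table_hi = min(cmf["wavelength_nm"].max(), d65["wavelength_nm"].max())
    if lo < table_lo or hi > table_hi:
        raise ValueError(
            f"requested range [{lo}, {hi}] outside tabulated [{table_lo}, {table_hi}]"
        )
    wl = np.arange(lo, hi + step / 2, step)
    interp = lambda col, df: np.interp(wl, df["wavelength_nm"], df[col])
    return ObserverIlluminant(
        wavelengths=wl,
        xbar=interp("xbar", cmf),
        ybar=interp("ybar", cmf),
        zbar=interp("zbar", cmf),
        spd=interp("relative_power", d65),
    )


def transmittance(s: Spectrum) -> np.ndarray:
    """Decadic transmittance T = 10^(-A), clipped to [0, 1]."""
    return np.clip(10.0 ** (-s.absorbance), 0.0, 1.0)


def tristimulus(
    T: np.ndarray,
    wavelengths: np.ndarray,
    tables: ObserverIlluminant,
    extend: bool = True,
) -> tuple[float, float, float]:
    """CIE XYZ of a transmittance spectrum by rectangular summation.

    ``T`` is resampled onto the tables' working grid.  If the measured range
    stops short of the tables' upper edge, the last value is extended as a
    constant (``extend=True``); a gap at the lower edge is ignored the same
    way only below 380 nm by construction of the working grid, and any other
    uncovered interval raises.
    """
    wl = tables.wavelengths
    lo_m, hi_m = float(wavelengths[0]), float(wavelengths[-1])
    if not extend and (lo_m > wl[0] or hi_m < wl[-1]):
        raise ValueError(
            f"transmittance covers [{lo_m}, {hi_m}] but integration needs "
            f"[{wl[0]}, {wl[-1]}] (missing "
            f"{'below ' + str(wl[0]) if lo_m > wl[0] else ''}"
            f"{' and ' if lo_m > wl[0] and hi_m < wl[-1] else ''}"
            f"{'above ' + str(wl[-1]) if hi_m < wl[-1] else ''})"
        )
    # np.interp extends both ends as constants, the documented rule
    Tg = np.interp(wl, wavelengths, T)
    k = 100.0 / float(np.sum(tables.spd * tables.ybar))
    X = k * float(np.sum(Tg * tables.spd * tables.xbar))
    Y = k * float(np.sum(Tg * tables.spd * tables.ybar))
    Z = k * float(np.sum(Tg * tables.spd * tables.zbar))
    return X, Y, Z


_DELTA = 6.0 / 29.0


def _f(t: np.ndarray | float) -> np.ndarray | float:
    t = np.asarray(t, dtype=float)
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)


def _f_inv(u: np.ndarray | float) -> np.ndarray | float:
    u = np.asarray(u, dtype=float)
    return np.where(u > _DELTA, u**3, 3 * _DELTA**2 * (u - 4.0 / 29.0))


def lab_from_xyz(
    X: float, Y: float, Z: float, white: tuple[float, float, float]
) -> tuple[float, float, float]:
    """CIE 1976 L*a*b* with the standard cube-root/linear-segment function."""
    Xn, Yn, Zn = white
    if min(Xn, Yn, Zn) <= 0:
        raise ValueError("white point must be componentwise positive")
    fx, fy, fz = _f(X / Xn), _f(Y / Yn), _f(Z / Zn)
    return (
        float(116.0 * fy - 16.0),
        float(500.0 * (fx - fy)),
        float(200.0 * (fy - fz)),
    )


def xyz_from_lab(
    L: float, a: float, b: float, white: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Inverse CIELab transform (exact inverse of :func:`lab_from_xyz`)."""
    Xn, Yn, Zn = white
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - b / 200.0
    return float(Xn * _f_inv(fx)), float(Yn * _f_inv(fy)), float(Zn * _f_inv(fz))


def chroma_hue(a: float, b: float) -> tuple[float, float, bool]:
    """Chroma C* and signed hue angle H* (degrees) from opponent coordinates.

    Returns ``(C, H, hue_undefined)``; at the neutral axis (a = b = 0) the hue
    is undefined and reported as 0 with the flag set.
    """
    if not (math.isfinite(a) and math.isfinite(b)):
        raise ValueError("a*, b* must be finite")
    C = math.hypot(a, b)
    if a == 0.0 and b == 0.0:
        return 0.0, 0.0, True
    H = math.degrees(math.atan2(b, a))
    if H <= -180.0:  # atan2 returns (-180, 180]; normalise -180 -> 180
        H += 360.0
    return C, H, False


# sRGB (IEC 61966-2-1) XYZ -> linear RGB matrix, D65 white
_XYZ_TO_RGB = np.array(
    [
        [3.2404542, -1.5371385, -0.4985314],
        [-0.9692660, 1.8760108, 0.0415560],
        [0.0556434, -0.2040259, 1.0572252],
    ]
)


def srgb_swatch(
    L: float,
    a: float,
    b: float,
    white: tuple[float, float, float] = SRGB_WHITE,
) -> tuple[str, bool]:
    """Render a Lab record as an 8-bit sRGB hex string.

    Out-of-gamut channels are clipped to [0, 1]; the second return value flags
    whether clipping occurred.
    """
    X, Y, Z = xyz_from_lab(L, a, b, white)
    rgb_lin = _XYZ_TO_RGB @ (np.array([X, Y, Z]) / 100.0)
    # tolerance absorbs rounding of the published matrix/white-point constants
    clipped = bool(np.any(rgb_lin < -1e-4) or np.any(rgb_lin > 1 + 1e-4))
    rgb_lin = np.clip(rgb_lin, 0.0, 1.0)
    rgb = np.where(
        rgb_lin <= 0.0031308,
        12.92 * rgb_lin,
        1.055 * rgb_lin ** (1.0 / 2.4) - 0.055,
    )
    r, g, bl = (int(round(255 * v)) for v in rgb)
    return f"#{r:02X}{g:02X}{bl:02X}", clipped


def color_from_spectrum(
    s: Spectrum, tables: ObserverIlluminant | None = None
) -> ColorResult:
    """Full colour pipeline for one absorbance spectrum."""
    if tables is None:
        tables = load_observer_illuminant()
    T = transmittance(s)
    X, Y, Z = tristimulus(T, s.wavelengths, tables)
    L, a, b = lab_from_xyz(X, Y, Z, tables.white_point)
    C, H, undef = chroma_hue(a, b)
    hex_, clipped = srgb_swatch(L, a, b)
    return ColorResult(X, Y, Z, L, a, b, C, H, hex_, clipped, undef)


def color_from_lab(L: float, a: float, b: float) -> ColorResult:
    """Colour record from a tabulated Lab triple (validation path for printed
    tables: C*, H* and the swatch are recomputed from a*, b*)."""
    C, H, undef = chroma_hue(a, b)
    X, Y, Z = xyz_from_lab(L, a, b, SRGB_WHITE)
    hex_, clipped = srgb_swatch(L, a, b)
    return ColorResult(X, Y, Z, L, a, b, C, H, hex_, clipped, undef)


def load_reference_cielab() -> pd.DataFrame:
    """Published CIELab records of the aged solutions and T0 controls."""
    with resources.files("copigmentation.data").joinpath(
        "table2_cielab.csv"
    ).open() as f:
        return pd.read_csv(f, comment="#")
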