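"""Spectrum data model, CSV I/O, smoothing, interpolation and band extraction.

UV-Vis absorbance spectra of anthocyanin model-wine solutions, nominally
300-700 nm at 1 nm (1 cm path implied), though every operation accepts any
strictly increasing wavelength grid.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "SampleMeta",
    "Spectrum",
    "PeakResult",
    "read_spectra",
    "write_spectra",
    "read_metadata",
    "smooth_savitzky_golay",
    "absorbance_at",
    "find_lambda_max",
    "band_ratio",
    "DEFAULT_BASELINE_TOL",
]

#: Most negative absorbance accepted as instrument baseline noise (AU).
DEFAULT_BASELINE_TOL = -0.005

PH_RANGE = (2.0, 4.5)
KNOWN_COPIGMENTS = ("CAF", "CA", "SI", "none")


@dataclass(frozen=True)
class SampleMeta:
    """Identity and preparation conditions of one measured solution.

    ``molar_ratio`` is copigment:pigment (20 means 1:20); concentrations are
    molar, final after 1:1 mixing of pigment and copigment stock.
    """

    pigment: str = "Mv-3-O-glc"
    copigment: str = "none"
    pH: float = 3.6
    molar_ratio: int | None = None
    pigment_conc: float = 5e-5
    copigment_conc: float | None = None
    replicate: int = 1
    timepoint: str = "T0"
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (PH_RANGE[0] <= self.pH <= PH_RANGE[1]):
            raise ValueError(
                f"pH {self.pH} outside the supported range {PH_RANGE}"
            )
        if self.molar_ratio is not None and self.molar_ratio <= 0:
            raise ValueError("molar_ratio must be a positive integer")
        if self.replicate <= 0:
            raise ValueError("replicate must be a positive integer")
        if (
            self.molar_ratio is not None
            and self.copigment_conc is not None
            and abs(self.copigment_conc - self.molar_ratio * self.pigment_conc)
            > 1e-12
        ):
            raise ValueError(
                "copigment_conc inconsistent with molar_ratio x pigment_conc: "
                f"{self.copigment_conc} vs {self.molar_ratio * self.pigment_conc}"
            )

    def with_note(self, note: str) -> "SampleMeta":
        return replace(self, provenance=self.provenance + (note,))


@dataclass(frozen=True)
class Spectrum:
    """One absorbance spectrum on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    meta: SampleMeta = field(default_factory=SampleMeta)
    baseline_tol: float = DEFAULT_BASELINE_TOL

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)
        if wl.ndim != 1 or ab.ndim != 1 or wl.size != ab.size:
            raise ValueError("wavelengths and absorbance must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two grid points")
        if not np.all(np.diff(wl) > 0):
            bad = int(np.flatnonzero(np.diff(wl) <= 0)[0]) + 1
            raise ValueError(f"wavelength grid not strictly increasing at index {bad}")
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbance contains non-finite values")
        if np.min(ab) < self.baseline_tol:
            raise ValueError(
                f"absorbance below baseline tolerance {self.baseline_tol} AU "
                f"(min {np.min(ab):.4g}); corrupt spectrum?"
            )

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])


@dataclass(frozen=True)
class PeakResult:
    """Peak location with a flag telling whether parabolic refinement applied."""

    wavelength: float
    absorbance: float
    refined: bool


# ---------------------------------------------------------------------------
# I/O


def _meta_from_row(row: pd.Series) -> SampleMeta:
    ratio = row.get("molar_ratio")
    ratio = None if ratio is None or pd.isna(ratio) else int(ratio)
    cp = row.get("copigment_conc_M")
    cp = None if cp is None or pd.isna(cp) else float(cp)
    return SampleMeta(
        pigment=str(row.get("pigment", "Mv-3-O-glc")),
        copigment=str(row.get("copigment", "none")),
        pH=float(row.get("pH", 3.6)),
        molar_ratio=ratio,
        pigment_conc=float(row.get("pigment_conc_M", 5e-5)),
        copigment_conc=cp,
        replicate=int(row.get("replicate", 1)),
        timepoint=str(row.get("timepoint", "T0")),
    )


def read_metadata(source: str | Path | io.TextIOBase) -> dict[str, SampleMeta]:
    """Read a sidecar metadata CSV keyed by sample_id."""
    df = pd.read_csv(source, comment="#")
    if "sample_id" not in df.columns:
        raise ValueError("metadata CSV must have a sample_id column")
    return {str(r["sample_id"]): _meta_from_row(r) for _, r in df.iterrows()}


def read_spectra(
    source: str | Path | io.TextIOBase,
    metadata: dict[str, SampleMeta] | None = None,
    baseline_tol: float = DEFAULT_BASELINE_TOL,
) -> dict[str, Spectrum]:
    """Read spectra from a long- or wide-format CSV.

    Long format: columns ``sample_id, wavelength_nm, absorbance``.
    Wide format: ``wavelength_nm`` first, one column per sample id.
    Returns an insertion-ordered mapping sample_id -> Spectrum.
    """
    # round_trip parsing keeps write -> read bit-exact
    df = pd.read_csv(source, comment="#", float_precision="round_trip")
    cols = list(df.columns)
    out: dict[str, Spectrum] = {}
    if {"sample_id", "wavelength_nm", "absorbance"}.issubset(cols):
        for sid, grp in df.groupby("sample_id", sort=False):
            wl = grp["wavelength_nm"].to_numpy(dtype=float)
            if np.unique(wl).size != wl.size:
                raise ValueError(f"duplicate wavelength for sample {sid!r}")
            if not np.all(np.diff(wl) > 0):
                bad_pos = int(np.flatnonzero(np.diff(wl) <= 0)[0])
                row = int(grp.index[bad_pos + 1]) + 2  # 1-based incl. header
                raise ValueError(
                    f"non-monotonic wavelengths for sample {sid!r} at file row {row}"
                )
            meta = _lookup_meta(str(sid), metadata)
            out[str(sid)] = Spectrum(
                wl, grp["absorbance"].to_numpy(dtype=float), meta, baseline_tol
            )
    elif cols and cols[0] == "wavelength_nm":
        wl = df["wavelength_nm"].to_numpy(dtype=float)
        if not np.all(np.diff(wl) > 0):
            bad = int(np.flatnonzero(np.diff(wl) <= 0)[0]) + 2
            raise ValueError(f"non-monotonic wavelengths at file row {bad}")
        for sid in cols[1:]:
            meta = _lookup_meta(str(sid), metadata)
            out[str(sid)] = Spectrum(
                wl, df[sid].to_numpy(dtype=float), meta, baseline_tol
            )
    else:
        raise ValueError(
            "unrecognised spectral CSV: need long columns "
            "(sample_id, wavelength_nm, absorbance) or wide (wavelength_nm first)"
        )
    return out


def _lookup_meta(sid: str, metadata: dict[str, SampleMeta] | None) -> SampleMeta:
    if metadata is None:
        return SampleMeta()
    if sid not in metadata:
        raise ValueError(f"sample {sid!r} missing from metadata")
    return metadata[sid]


def write_spectra(
    spectra: dict[str, Spectrum], path: str | Path, fmt: str = "long"
) -> None:
    """Write spectra to CSV (inverse of :func:`read_spectra`)."""
    if fmt == "long":
        frames = [
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "wavelength_nm": s.wavelengths,
                    "absorbance": s.absorbance,
                }
            )
            for sid, s in spectra.items()
        ]
        pd.concat(frames, ignore_index=True).to_csv(
            path, index=False, float_format="%.17g"
        )
    elif fmt == "wide":
        grids = {tuple(s.wavelengths) for s in spectra.values()}
        if len(grids) != 1:
            raise ValueError("wide format requires a shared wavelength grid")
        first = next(iter(spectra.values()))
        df = pd.DataFrame({"wavelength_nm": first.wavelengths})
        for sid, s in spectra.items():
            df[sid] = s.absorbance
        # %.17g guarantees bit-exact float round-trip through the CSV
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_metadata(spectra: dict[str, Spectrum], path: str | Path) -> None:
    rows = []
    for sid, s in spectra.items():
        m = s.meta
        rows.append(
            {
                "sample_id": sid,
                "pigment": m.pigment,
                "copigment": m.copigment,
                "pH": m.pH,
                "molar_ratio": m.molar_ratio,
                "pigment_conc_M": m.pigment_conc,
                "copigment_conc_M": m.copigment_conc,
                "replicate": m.replicate,
                "timepoint": m.timepoint,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Operations


def smooth_savitzky_golay(
    s: Spectrum, window: int = 9, order: int = 3
) -> Spectrum:
    """Savitzky-Golay least-squares polynomial smoothing on the native grid.

    Interior points use the standard convolution; within half a window of
    either edge the polynomial is refit on the available one-sided truncated
    window (measured range edges carry real signal, so no padding/reflection).
    """
    n = len(s)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not (3 <= window <= n):
        raise ValueError(f"window must be in [3, {n}]")
    if not (1 <= order < window):
        raise ValueError("order must satisfy 1 <= order < window")

    y = savgol_filter(s.absorbance, window, order, mode="interp")
    half = window // 2
    x = s.wavelengths
    # one-sided truncated windows at the edges
    for i in range(half):
        for idx, lo, hi in ((i, 0, i + half + 1), (n - 1 - i, n - 1 - i - half, n)):
            xs = x[lo:hi] - x[idx]
            k = min(order, xs.size - 1)
            coeffs = np.polynomial.polynomial.polyfit(xs, s.absorbance[lo:hi], k)
            y[idx] = coeffs[0]
    return Spectrum(
        s.wavelengths,
        y,
        s.meta.with_note(f"savgol(window={window}, order={order})"),
        baseline_tol=-np.inf,  # smoothing may legitimately dip slightly
    )


def absorbance_at(s: Spectrum, wavelength: float) -> float:
    """Absorbance at an arbitrary wavelength by piecewise-linear interpolation.

    Exact grid hits return the stored value; outside the grid span is an error.
    """
    lo, hi = s.span
    if not (lo <= wavelength <= hi):
        raise ValueError(f"wavelength {wavelength} nm outside grid span [{lo}, {hi}]")
    return float(np.interp(wavelength, s.wavelengths, s.absorbance))


def find_lambda_max(
    s: Spectrum, window: tuple[float, float] | None = None
) -> PeakResult:
    """Locate the absorbance maximum inside ``window`` (default: full span).

    The grid maximum is refined by parabolic interpolation through its two
    neighbours (sub-nanometre resolution); grid ties break toward longer
    wavelength. A maximum at the window edge is returned unrefined.
    """
    lo, hi = window if window is not None else s.span
    span = s.span
    if lo < span[0] or hi > span[1]:
        raise ValueError(f"window [{lo}, {hi}] outside grid span {span}")
    mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    idx = np.flatnonzero(mask)
    if idx.size < 3:
        raise ValueError("search window must span at least 3 grid points")
    sub = s.absorbance[idx]
    # ties toward longer wavelength
    j = idx[sub.size - 1 - int(np.argmax(sub[::-1]))]
    if j == idx[0] or j == idx[-1]:
        return PeakResult(float(s.wavelengths[j]), float(s.absorbance[j]), False)
    xs = s.wavelengths[j - 1 : j + 2]
    ys = s.absorbance[j - 1 : j + 2]
    # parabola through three points on a (possibly uneven) grid
    a, b, c = np.polyfit(xs - xs[1], ys, 2)
    if a == 0:  # flat top: keep the grid point
        return PeakResult(float(xs[1]), float(ys[1]), False)
    dx = -b / (2 * a)
    return PeakResult(float(xs[1] + dx), float(a * dx * dx + b * dx + c), True)


def band_ratio(
    s: Spectrum,
    lambda_num: float = 440.0,
    lambda_den: float = 510.0,
    floor: float = 1e-4,
) -> float:
    """Absorbance ratio A(lambda_num)/A(lambda_den), the yellow/red balance index."""
    num = absorbance_at(s, lambda_num)
    den = absorbance_at(s, lambda_den)
    if den <= floor:
        raise ValueError(
            f"ratio undefined at baseline: A({lambda_den}) = {den:.2e} <= floor {floor}"
        )
    return num / den
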